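"""Pipeline configuration with study-standard defaults.

Defaults: MVAR order 5, band 0.009-0.08 Hz, 1000 surrogate realizations
at the 99th percentile, component/lesion threshold t > 3 with >10-voxel
clusters, abnormality rule z < -1, SVR gamma 0.25 with the 0.75
accuracy threshold.  Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig"]

STAGE_NAMES = ("hrv", "pica", "lesions", "tpdc", "surrogates", "compare", "svr")

#: stages that cannot run when their upstream stage is disabled
STAGE_DEPENDENCIES = {
    "lesions": "pica",
    "surrogates": "tpdc",
    "compare": "tpdc",
    "svr": "tpdc",
}

_TUPLE_FIELDS = ("grid_shape", "voxel_size", "band")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {name: True for name in STAGE_NAMES}
    )

    # synthetic cohort
    n_patients: int = 42
    n_controls: int = 20
    rr_duration_s: float = 300.0
    lf_amp_normal: float = 40.0
    lf_amp_reduced: float = 10.0
    hf_amp: float = 25.0
    rr_noise_sd: float = 20.0
    abnormal_fraction: float = 0.5
    z_abnormal: float = -1.0

    # lesion modality
    grid_shape: tuple = (12, 12, 8)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    loading_corr: float = 0.9
    lesion_noise_sd: float = 1.0
    t_thresh: float = 3.0
    min_voxels: int = 10
    connectivity: int = 26
    atlas_rois: int = 8

    # connectivity
    order: int = 5
    band: tuple = (0.009, 0.08)
    sample_rate: float = 1.0
    n_samples: int = 655
    freq_points: int = 64
    time_stride: int = 1
    coupling: float = 0.4
    tpdc_threshold: float = 0.1

    # surrogates
    surrogate: str = "shuffle"
    n_realizations: int = 1000
    percentile: float = 99.0
    window_len: int = 0  # 0 -> default of 10 * order
    surrogate_subjects: int = 1

    # validation
    svr_gamma: float = 0.25
    accuracy_threshold: float = 0.75

    def __post_init__(self) -> None:
        for name in _TUPLE_FIELDS:
            setattr(self, name, tuple(getattr(self, name)))
        unknown_stages = set(self.stages) - set(STAGE_NAMES)
        if unknown_stages:
            raise ValueError(f"unknown stage toggles: {sorted(unknown_stages)}")
        for name in STAGE_NAMES:
            self.stages.setdefault(name, True)
        if self.surrogate not in ("shuffle", "aaft"):
            raise ValueError("surrogate must be 'shuffle' or 'aaft'")

    def effective_stages(self) -> dict:
        """Stage toggles with dependency closure applied.

        Disabling a stage also disables every stage that consumes its
        output (e.g. no TPDC implies no surrogates, comparison or SVR).
        """
        eff = dict(self.stages)
        changed = True
        while changed:
            changed = False
            for stage, dep in STAGE_DEPENDENCIES.items():
                if eff[stage] and not eff[dep]:
                    eff[stage] = False
                    changed = True
        return eff

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for name in _TUPLE_FIELDS:
            out[name] = list(out[name])
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
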