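"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here:

* RR tachograms with controllable LF/HF oscillatory power (direct
  interval modulation, so the band-power ground truth is the analytic
  ``amplitude^2 / 2``),
* band-limited multichannel series from (optionally time-varying) MVAR
  models with a known directed-coupling schedule,
* a two-modality cohort (lesion volumes x scalar HRV covariate) with a
  single embedded covarying component at a specified loading
  correlation, and
* block-partition atlas label volumes, named after the seven-network
  parcellation when seven ROIs are requested.

All generators are pure functions of their spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hrv import RRISeries
from .lesions import AtlasLabels, LesionMap
from .tpdc import SEVEN_NETWORKS, MultichannelTimeSeries, TVMVARModel

__all__ = [
    "RRGenSpec",
    "CouplingSpec",
    "CohortGenSpec",
    "LesionCohort",
    "gen_rr_series",
    "gen_mvar_network",
    "gen_lesion_cohort",
    "gen_atlas",
    "companion_spectral_radius",
    "default_component_map",
]

MVAR_BURN_IN = 500  # samples discarded to remove the zero-state transient


@dataclass
class RRGenSpec:
    """Spec for a 5-minute-style resting tachogram.

    Interval modulation: ``rr(t) = mean_rr + lf_amp*sin(2*pi*lf_freq*t)
    + hf_amp*sin(2*pi*hf_freq*t) + N(0, noise_sd^2)`` evaluated at each
    beat time.  Amplitudes and ``mean_rr`` in ms, frequencies in Hz,
    duration in s.
    """

    mean_rr: float = 800.0
    lf_amp: float = 0.0
    lf_freq: float = 0.10
    hf_amp: float = 0.0
    hf_freq: float = 0.25
    noise_sd: float = 0.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be > 0")
        if not 0.04 <= self.lf_freq <= 0.14:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.14] Hz")
        if not 0.15 <= self.hf_freq <= 0.50:
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.50] Hz")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CouplingSpec:
    """Ground-truth MVAR coupling for multichannel simulation.

    ``coeff_matrices`` is either a list of ``order`` (c x c) lag
    matrices, or a time-varying schedule: a list of
    ``(start_sample, [lag matrices])`` pairs (start samples refer to the
    retained output, the first segment must start at 0).  Every segment
    must be stationary (companion spectral radius < 1).
    """

    n_channels: int
    order: int
    coeff_matrices: list
    innovation_sd: float = 1.0
    n_samples: int = 1000
    sample_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def schedule(self) -> list:
        """Normalized, sorted [(start_sample, array(order, c, c)), ...]."""
        entries = self.coeff_matrices
        if entries and not isinstance(entries[0], tuple):
            entries = [(0, entries)]
        out = []
        for start, mats in sorted(entries, key=lambda e: e[0]):
            arr = np.asarray(mats, dtype=float)
            if arr.shape != (self.order, self.n_channels, self.n_channels):
                raise ValueError(
                    "each segment needs one (c x c) matrix per lag; got "
                    f"shape {arr.shape}"
                )
            out.append((int(start), arr))
        if out[0][0] != 0:
            raise ValueError("first schedule segment must start at sample 0")
        return out


@dataclass
class CohortGenSpec:
    """Two-modality cohort: per-subject lesion maps + scalar covariate.

    Each subject's map is ``loading * component_map + noise``; the
    covariate is built from the loadings mixed with independent noise at
    the analytically required ratio so that its correlation with the
    loadings is ``loading_corr``.
    """

    n_subjects: int = 42
    grid_shape: tuple = (12, 12, 8)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    component_map: np.ndarray = None  # type: ignore[assignment]
    loading_corr: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape entries must all be >= 1")
        if abs(self.loading_corr) > 1:
            raise ValueError("|loading_corr| must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.component_map is None:
            self.component_map = default_component_map(self.grid_shape)
        self.component_map = np.asarray(self.component_map, dtype=float)
        if self.component_map.shape != tuple(self.grid_shape):
            raise ValueError("component_map shape must equal grid_shape")


@dataclass
class LesionCohort:
    """Generated cohort with its ground truth."""

    maps: list
    covariate: np.ndarray
    loadings: np.ndarray
    component_map: np.ndarray


def default_component_map(grid_shape: tuple, amplitude: float = 3.0) -> np.ndarray:
    """A central rectangular pattern covering ~1/8 of each axis extent."""
    pattern = np.zeros(grid_shape)
    sl = tuple(slice(g // 3, max(g // 3 + 1, 2 * g // 3)) for g in grid_shape)
    pattern[sl] = amplitude
    return pattern


def gen_rr_series(spec: RRGenSpec) -> RRISeries:
    """Generate a tachogram by direct interval modulation."""
    rng = np.random.default_rng(spec.seed)
    intervals = []
    t = 0.0
    while t < spec.duration:
        rr = (
            spec.mean_rr
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t)
        )
        if spec.noise_sd > 0:
            rr += rng.normal(0.0, spec.noise_sd)
        rr = max(rr, 1.0)  # guard against nonphysical nonpositive intervals
        intervals.append(rr)
        t += rr / 1000.0
    return RRISeries.from_intervals(np.array(intervals))


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of (order, c, c) coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, c, _ = coeffs.shape
    comp = np.zeros((p * c, p * c))
    comp[:c, :] = np.concatenate([coeffs[r] for r in range(p)], axis=1)
    if p > 1:
        comp[c:, :-c] = np.eye((p - 1) * c)
    return float(np.abs(np.linalg.eigvals(comp)).max())


def gen_mvar_network(spec: CouplingSpec) -> tuple:
    """Simulate a (possibly time-varying) MVAR process.

    Returns ``(MultichannelTimeSeries, TVMVARModel)`` where the model
    holds the exact coefficient schedule per retained sample.  The first
    500 samples (zero-state transient) are discarded.
    """
    schedule = spec.schedule()
    for start, mats in schedule:
        rho = companion_spectral_radius(mats)
        if rho >= 1.0:
            raise ValueError(
                f"unstable coefficients in segment starting at {start}: "
                f"companion spectral radius {rho:.3f} >= 1"
            )
    rng = np.random.default_rng(spec.seed)
    c, p = spec.n_channels, spec.order
    sd = np.broadcast_to(np.asarray(spec.innovation_sd, dtype=float), (c,))
    total = MVAR_BURN_IN + spec.n_samples
    y = np.zeros((c, total))
    eps = rng.normal(0.0, 1.0, size=(c, total)) * sd[:, None]

    starts = [s for s, _ in schedule]
    segments = [m for _, m in schedule]

    def active(t_out: int) -> np.ndarray:
        idx = int(np.searchsorted(starts, max(t_out, 0), side="right")) - 1
        return segments[idx]

    for t in range(total):
        mats = active(t - MVAR_BURN_IN)
        acc = eps[:, t].copy()
        for r in range(1, min(p, t) + 1):
            acc += mats[r - 1] @ y[:, t - r]
        y[:, t] = acc

    data = y[:, MVAR_BURN_IN:]
    true_coeffs = np.stack([active(t) for t in range(spec.n_samples)])
    ts = MultichannelTimeSeries(data=data, sample_rate=spec.sample_rate)
    model = TVMVARModel(
        order=p,
        coeffs=true_coeffs,
        innovation_cov=np.diag(sd**2),
        sample_rate=spec.sample_rate,
    )
    return ts, model


def gen_lesion_cohort(spec: CohortGenSpec) -> LesionCohort:
    """Generate lesion maps and a covariate correlated with the loadings.

    The covariate is ``rho * z(loadings) + sqrt(1 - rho^2) * e`` with
    independent standard-normal ``e``, so its population correlation
    with the loadings is exactly ``loading_corr``.
    """
    rng = np.random.default_rng(spec.seed)
    loadings = rng.normal(0.0, 1.0, size=spec.n_subjects)
    rho = spec.loading_corr
    z = (loadings - loadings.mean()) / loadings.std()
    noise = rng.normal(0.0, 1.0, size=spec.n_subjects)
    covariate = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    maps = []
    for s in range(spec.n_subjects):
        values = loadings[s] * spec.component_map
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        maps.append(LesionMap(values=values, voxel_size=spec.voxel_size))
    return LesionCohort(
        maps=maps,
        covariate=covariate,
        loadings=loadings,
        component_map=spec.component_map,
    )


def gen_atlas(grid_shape: tuple, n_rois: int, voxel_size: tuple = (1.0, 1.0, 1.0)) -> AtlasLabels:
    """Partition a grid into ``n_rois`` contiguous equal-size blocks.

    With ``n_rois == 7`` the ROIs carry the seven network names;
    otherwise they are named ``ROI_1..ROI_k``.
    """
    n_voxels = int(np.prod(grid_shape))
    if not 1 <= n_rois <= n_voxels:
        raise ValueError("n_rois must be between 1 and the number of voxels")
    flat = np.empty(n_voxels, dtype=np.int16)
    edges = np.linspace(0, n_voxels, n_rois + 1).astype(int)
    for label in range(1, n_rois + 1):
        flat[edges[label - 1] : edges[label]] = label
    labels = flat.reshape(grid_shape)
    if n_rois == 7:
        names = {k + 1: SEVEN_NETWORKS[k] for k in range(7)}
    else:
        names = {k: f"ROI_{k}" for k in range(1, n_rois + 1)}
    return AtlasLabels(labels=labels, names=names, voxel_size=voxel_size)
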