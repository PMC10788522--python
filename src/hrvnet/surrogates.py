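"""Surrogate-data null distributions for directed connectivity values.

Three complementary nulls:

* **window shuffle** — the putative *source* channel is cut into
  non-overlapping windows whose order is permuted, destroying the
  cross-channel lag structure while preserving the channel's marginal
  distribution and short-range autocorrelation; the full connectivity
  pipeline is re-evaluated per realization and the stated percentile
  (default 99th of 1000 realizations) becomes the per-connection
  significance threshold,
* **time reversal** — a second test applied to connections already
  flagged significant: a genuinely lagged directed influence should
  shrink when the series is played backwards, so a connection passes
  only if its original value strictly exceeds its time-reversed value,
* **AAFT** — amplitude-adjusted Fourier-transform surrogates per
  channel (rank-remap to Gaussian, phase randomisation, rank-remap
  back), preserving each channel's amplitude distribution exactly and
  its spectrum approximately.

Nulls are built separately for each subject's series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tpdc import MultichannelTimeSeries

__all__ = [
    "SurrogateNull",
    "window_shuffle_null",
    "time_reversal_test",
    "aaft_surrogate",
    "aaft_null",
]


@dataclass
class SurrogateNull:
    """Empirical null for a connectivity matrix.

    ``null_values`` has shape (n_realizations, c, c); entries for
    source channels that were not shuffled are NaN.  ``threshold`` is
    the per-connection percentile of the null, ``original`` the value
    on the unperturbed data and ``significant`` the elementwise
    ``original > threshold`` decision.
    """

    method: str
    n_realizations: int
    percentile: float
    null_values: np.ndarray
    threshold: np.ndarray
    original: np.ndarray
    significant: np.ndarray
    source_channels: list

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _shuffle_windows(x: np.ndarray, window_len: int, rng: np.random.Generator) -> np.ndarray:
    """Permute the order of non-overlapping windows of a 1-D series.

    Any remainder shorter than one window is left in place at the end.
    """
    n = x.size
    n_win = n // window_len
    head = x[: n_win * window_len].reshape(n_win, window_len)
    perm = rng.permutation(n_win)
    return np.concatenate([head[perm].ravel(), x[n_win * window_len :]])


def window_shuffle_null(
    ts: MultichannelTimeSeries,
    pipeline_fn,
    window_len: int = None,
    n_real: int = 1000,
    percentile: float = 99.0,
    source_channels: list = None,
    order: int = 5,
    seed: int = 0,
) -> SurrogateNull:
    """Window-shuffle bootstrap null for every connection.

    For each putative source channel j, each realization permutes the
    window order of channel j only (targets untouched) and re-runs
    ``pipeline_fn`` (the TPDC band/time average, ts -> target x source
    matrix); column j of the result feeds the null of every connection
    with source j.  ``window_len`` defaults to ``10 * order`` samples.
    """
    if window_len is None:
        window_len = 10 * order
    if window_len < order + 1:
        raise ValueError("window_len must be at least order + 1")
    n_win = ts.n_samples // window_len
    if n_win < 4:
        raise ValueError("need at least 4 windows; shorten window_len")
    c = ts.n_channels
    if source_channels is None:
        source_channels = list(range(c))
    rng = np.random.default_rng(seed)
    original = np.asarray(pipeline_fn(ts))
    null = np.full((n_real, c, c), np.nan)
    for j in source_channels:
        for r in range(n_real):
            data = ts.data.copy()
            data[j] = _shuffle_windows(ts.data[j], window_len, rng)
            surro = MultichannelTimeSeries(
                data=data,
                sample_rate=ts.sample_rate,
                channel_names=list(ts.channel_names),
            )
            null[r, :, j] = np.asarray(pipeline_fn(surro))[:, j]
    threshold = np.full((c, c), np.nan)
    for j in source_channels:
        threshold[:, j] = np.percentile(null[:, :, j], percentile, axis=0)
    with np.errstate(invalid="ignore"):
        significant = original > threshold
    return SurrogateNull(
        method="window-shuffle",
        n_realizations=n_real,
        percentile=percentile,
        null_values=null,
        threshold=threshold,
        original=original,
        significant=significant,
        source_channels=list(source_channels),
    )


def time_reversal_test(
    ts: MultichannelTimeSeries,
    pipeline_fn,
    significant: np.ndarray = None,
) -> tuple:
    """Second-stage test: original value must exceed the time-reversed one.

    Returns ``(passed, original, reversed_values)``; ``passed`` is the
    elementwise strict comparison, restricted to connections already
    flagged in ``significant`` when given (others are False).
    """
    original = np.asarray(pipeline_fn(ts))
    reversed_ts = MultichannelTimeSeries(
        data=ts.data[:, ::-1].copy(),
        sample_rate=ts.sample_rate,
        channel_names=list(ts.channel_names),
    )
    rev = np.asarray(pipeline_fn(reversed_ts))
    passed = original > rev
    if significant is not None:
        passed = passed & np.asarray(significant, dtype=bool)
    return passed, original, rev


def aaft_surrogate(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One amplitude-adjusted Fourier-transform surrogate of a 1-D series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    # rank-remap onto sorted gaussian draws
    gauss = np.sort(rng.normal(size=n))
    ranks = np.argsort(np.argsort(x))
    z = gauss[ranks]
    # phase-randomize the gaussianized series (hermitian-symmetric phases)
    spec = np.fft.rfft(z)
    phases = rng.uniform(0, 2 * np.pi, size=spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    z_pr = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)
    # rank-remap back onto the original amplitude distribution
    final_ranks = np.argsort(np.argsort(z_pr))
    return np.sort(x)[final_ranks]


def aaft_null(
    ts: MultichannelTimeSeries,
    pipeline_fn,
    n_real: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
) -> SurrogateNull:
    """AAFT null: every channel replaced by an independent surrogate."""
    if ts.n_samples < 64:
        raise ValueError("need at least 64 samples for AAFT surrogates")
    rng = np.random.default_rng(seed)
    original = np.asarray(pipeline_fn(ts))
    c = ts.n_channels
    null = np.empty((n_real, c, c))
    for r in range(n_real):
        data = np.stack([aaft_surrogate(ts.data[i], rng) for i in range(c)])
        surro = MultichannelTimeSeries(
            data=data,
            sample_rate=ts.sample_rate,
            channel_names=list(ts.channel_names),
        )
        null[r] = np.asarray(pipeline_fn(surro))
    threshold = np.percentile(null, percentile, axis=0)
    return SurrogateNull(
        method="aaft",
        n_realizations=n_real,
        percentile=percentile,
        null_values=null,
        threshold=threshold,
        original=original,
        significant=original > threshold,
        source_channels=list(range(c)),
    )
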