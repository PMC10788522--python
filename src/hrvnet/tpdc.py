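"""Time-resolved partial directed coherence (TPDC) between a seed and
seven cortical networks.

A time-varying multivariate autoregressive (MVAR) model of fixed order
(default 5, checked against the AIC) is estimated with a dual extended
Kalman filter; the Fourier transform of the time-dependent coefficients
gives, after squaring and per-source-column normalisation, a partial
directed coherence value in [0, 1] for every (time, frequency, target,
source) combination.  Averaging over the 0.009-0.08 Hz band and over
time yields one directed connectivity value per ordered channel pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from ._dekf import dekf_loop

__all__ = [
    "SEVEN_NETWORKS",
    "DEFAULT_BAND",
    "MultichannelTimeSeries",
    "TVMVARModel",
    "PDCTensor",
    "ConnectivityProfile",
    "FilterParams",
    "bandpass",
    "extract_seed_and_networks",
    "var_ls_fit",
    "select_order",
    "fit_dekf",
    "pdc_from_coeffs",
    "band_time_average",
    "tpdc_matrix",
    "connectivity_profile",
    "default_freq_grid",
]

#: The seven-network cortical parcellation used as connectivity targets.
SEVEN_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "SalienceVentralAttention",
    "Control",
    "Limbic",
    "Default",
)

#: Frequency band of interest for BOLD-like signals, in Hz.
DEFAULT_BAND = (0.009, 0.08)

DEFAULT_ORDER = 5


@dataclass
class MultichannelTimeSeries:
    """Channels x samples array with a sample rate and channel names."""

    data: np.ndarray
    sample_rate: float = 1.0
    channel_names: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch_{i + 1}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def write_csv(self, path) -> None:
        pd.DataFrame(self.data.T, columns=self.channel_names).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, sample_rate: float = 1.0) -> "MultichannelTimeSeries":
        df = pd.read_csv(path)
        return cls(
            data=df.to_numpy().T,
            sample_rate=sample_rate,
            channel_names=list(df.columns),
        )


@dataclass
class TVMVARModel:
    """Time-indexed MVAR coefficients A_r(t) of fixed order.

    ``coeffs`` has shape (T, p, c, c): ``coeffs[t, r - 1, i, j]`` is the
    influence of channel j at lag r on channel i.
    """

    order: int
    coeffs: np.ndarray
    innovation_cov: np.ndarray
    sample_rate: float = 1.0
    burn_in_dropped: int = 0
    param_cov: np.ndarray = None  # type: ignore[assignment]
    state_cov: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.coeffs.ndim != 4 or self.coeffs.shape[1] != self.order:
            raise ValueError("coeffs must have shape (T, order, c, c)")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    def time_average(self) -> np.ndarray:
        """Mean coefficient matrices, shape (order, c, c)."""
        return self.coeffs.mean(axis=0)


@dataclass
class PDCTensor:
    """Squared, normalized PDC indexed (time, frequency, target, source).

    Every entry lies in [0, 1] and, for each (time, frequency, source),
    the values sum to 1 over targets (column normalisation).
    """

    values: np.ndarray
    freqs: np.ndarray  # Hz
    channel_names: list = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("PDC tensor must be 4-D")


@dataclass
class ConnectivityProfile:
    """Band/time-averaged seed<->network directed connectivity."""

    forward: dict  # network -> seed->network value
    backward: dict  # network -> network->seed value
    band: tuple
    threshold: float
    significant_forward: dict
    significant_backward: dict
    matrix: np.ndarray  # full target x source band/time average
    subject_id: str = ""

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for net in self.forward:
            rows.append(
                {
                    "network": net,
                    "direction": "forward",
                    "value": self.forward[net],
                    "above_threshold": self.significant_forward[net],
                }
            )
            rows.append(
                {
                    "network": net,
                    "direction": "backward",
                    "value": self.backward[net],
                    "above_threshold": self.significant_backward[net],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FilterParams:
    """DEKF tuning.

    ``q_param`` is the coefficient random-walk covariance scale (the
    parameter process noise), ``q_state`` a small state-covariance
    jitter, ``r_obs_scale`` scales the observation noise relative to the
    per-channel sample variance, ``adapt_innovation`` is the exponential
    rate at which the innovation variance estimate tracks the squared
    one-step prediction errors, and ``burn_in`` is the fraction of the
    coefficient trajectory discarded before any averaging.
    """

    q_param: float = 1e-4
    q_state: float = 1e-8
    r_obs_scale: float = 1e-4
    adapt_innovation: float = 0.01
    init_param_var: float = 1.0
    burn_in: float = 0.10


def bandpass(
    ts: MultichannelTimeSeries, lo: float, hi: float, order: int = 4
) -> MultichannelTimeSeries:
    """Zero-phase Butterworth band-pass per channel."""
    nyq = ts.sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) must lie inside (0, {nyq}) Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=ts.sample_rate, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=1)
    return MultichannelTimeSeries(
        data=filtered, sample_rate=ts.sample_rate, channel_names=list(ts.channel_names)
    )


def extract_seed_and_networks(
    vol4d: np.ndarray,
    lesion_pattern,
    parcellation,
    sample_rate: float = 1.0,
) -> MultichannelTimeSeries:
    """Pool a 4-D volume into seed + seven network mean time series.

    Channel 0 is the unweighted mean over the nonzero voxels of the
    lesion pattern; channels 1-7 are the means over each network of the
    parcellation, in label order.
    """
    vol4d = np.asarray(vol4d, dtype=float)
    if vol4d.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    if vol4d.shape[:3] != lesion_pattern.values.shape:
        raise ValueError("lesion pattern grid does not match the 4-D volume")
    if vol4d.shape[:3] != parcellation.labels.shape:
        raise ValueError("parcellation grid does not match the 4-D volume")
    labels = parcellation.roi_labels
    if len(labels) != 7:
        raise ValueError("parcellation must contain exactly 7 networks")
    active = lesion_pattern.values != 0
    if not active.any():
        raise ValueError("lesion pattern has no active voxels")
    channels = [vol4d[active].mean(axis=0)]
    names = ["seed"]
    for label in labels:
        channels.append(vol4d[parcellation.labels == label].mean(axis=0))
        names.append(parcellation.names[label])
    return MultichannelTimeSeries(
        data=np.stack(channels), sample_rate=sample_rate, channel_names=names
    )


def var_ls_fit(data: np.ndarray, order: int) -> tuple:
    """Ordinary least-squares stationary VAR fit.

    Returns ``(coeffs, resid_cov, n_eff)`` with ``coeffs`` of shape
    (order, c, c) and ``resid_cov`` the MLE residual covariance.
    """
    data = np.asarray(data, dtype=float)
    c, n = data.shape
    p = order
    n_eff = n - p
    if n_eff <= p * c + 1:
        raise ValueError("too few samples for this order")
    Y = data[:, p:]  # c x n_eff
    X = np.empty((p * c, n_eff))
    for r in range(1, p + 1):
        X[(r - 1) * c : r * c] = data[:, p - r : n - r]
    B, *_ = np.linalg.lstsq(X.T, Y.T, rcond=None)  # (p*c) x c
    resid = Y - B.T @ X
    resid_cov = resid @ resid.T / n_eff
    coeffs = B.T.reshape(c, p, c).transpose(1, 0, 2)
    return coeffs, resid_cov, n_eff


def select_order(ts: MultichannelTimeSeries, candidates=range(1, 11)) -> int:
    """Minimum-AIC stationary VAR order.

    AIC(p) = n_eff * log det(residual covariance) + 2 * p * c^2, with a
    least-squares fit per candidate.  Candidates that would leave too
    few samples are dropped with a warning.
    """
    candidates = [int(p) for p in candidates if 1 <= p <= 20]
    if not candidates:
        raise ValueError("no valid candidate orders")
    c = ts.n_channels
    usable = []
    for p in candidates:
        if ts.n_samples - p > p * c + 1:
            usable.append(p)
    if len(usable) < len(candidates):
        warnings.warn("candidate orders truncated: insufficient samples", stacklevel=2)
    if not usable:
        raise ValueError("insufficient samples for any candidate order")
    aics = []
    for p in usable:
        _, resid_cov, n_eff = var_ls_fit(ts.data, p)
        sign, logdet = np.linalg.slogdet(resid_cov)
        if sign <= 0:
            logdet = -np.inf
        aics.append(n_eff * logdet + 2 * p * c * c)
    return usable[int(np.argmin(aics))]


def fit_dekf(
    ts: MultichannelTimeSeries,
    order: int = DEFAULT_ORDER,
    params: FilterParams = None,
) -> TVMVARModel:
    """Estimate a time-varying MVAR model with the dual EKF.

    The first ``params.burn_in`` fraction of the coefficient trajectory
    (transient of the zero-initialised filters) is discarded.
    """
    if params is None:
        params = FilterParams()
    c = ts.n_channels
    if ts.n_samples <= 10 * order * c:
        warnings.warn(
            "fewer than 10*order*channels samples; DEKF estimates may be noisy",
            stacklevel=2,
        )
    y = ts.data
    var0 = y.var(axis=1)
    var0 = np.maximum(var0, 1e-12)
    r_obs = params.r_obs_scale * var0
    traj, rhat, param_cov, state_cov, fail_at = dekf_loop(
        y,
        order,
        params.q_param,
        params.q_state,
        r_obs,
        var0.copy(),
        params.adapt_innovation,
        params.init_param_var,
    )
    if fail_at >= 0:
        raise FloatingPointError(f"DEKF diverged (non-finite state) at sample {fail_at}")
    n_burn = int(params.burn_in * traj.shape[0])
    kept = traj[n_burn:]
    coeffs = kept.reshape(kept.shape[0], c, order, c).transpose(0, 2, 1, 3)
    return TVMVARModel(
        order=order,
        coeffs=coeffs,
        innovation_cov=np.diag(rhat),
        sample_rate=ts.sample_rate,
        burn_in_dropped=n_burn,
        param_cov=param_cov,
        state_cov=state_cov,
    )


def default_freq_grid(n_points: int = 64) -> np.ndarray:
    """Evenly spaced normalized frequencies in (0, 0.5) cycles/sample."""
    return (np.arange(n_points) + 0.5) * 0.5 / n_points


def pdc_from_coeffs(
    model: TVMVARModel,
    freq_grid: np.ndarray = None,
    time_stride: int = 1,
) -> PDCTensor:
    """Squared, normalized PDC from time-varying MVAR coefficients.

    For each retained time point and normalized frequency f,
    ``Abar(f, t) = I - sum_r A_r(t) exp(-i 2 pi f r)`` and the squared
    PDC from source j to target i is ``|Abar_ij|^2 / sum_k |Abar_kj|^2``
    (normalisation over targets k in source column j).  ``time_stride``
    subsamples the coefficient trajectory for speed; the stored
    frequency grid is converted to Hz using the model sample rate.
    """
    if freq_grid is None:
        freq_grid = default_freq_grid()
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid < 0) or np.any(freq_grid >= 0.5):
        raise ValueError("normalized frequencies must lie in [0, 0.5)")
    coeffs = model.coeffs[::time_stride]
    p = model.order
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * freq_grid[:, None] * lags[None, :])  # F x p
    c = model.n_channels
    eye = np.eye(c)
    # Abar[t, f, i, j] = I - sum_r phase[f, r] * A_r(t)[i, j]
    abar = eye[None, None] - np.einsum("fr,trij->tfij", phase, coeffs)
    num = np.abs(abar) ** 2
    denom = num.sum(axis=2, keepdims=True)  # sum over targets, per source column
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn("zero column norm in PDC normalisation; values set to 0", stacklevel=2)
        denom = np.where(zero_cols, 1.0, denom)
        num = np.where(np.broadcast_to(zero_cols, num.shape), 0.0, num)
    values = num / denom
    return PDCTensor(values=values, freqs=freq_grid * model.sample_rate)


def band_time_average(pdc: PDCTensor, band: tuple = DEFAULT_BAND) -> np.ndarray:
    """Mean PDC over in-band frequencies, then over time (target x source)."""
    lo, hi = band
    mask = (pdc.freqs >= lo) & (pdc.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    return pdc.values[:, mask].mean(axis=1).mean(axis=0)


def tpdc_matrix(
    ts: MultichannelTimeSeries,
    order: int = DEFAULT_ORDER,
    band: tuple = DEFAULT_BAND,
    params: FilterParams = None,
    freq_grid: np.ndarray = None,
    time_stride: int = 1,
) -> np.ndarray:
    """Full TPDC stage: DEKF -> squared PDC -> band/time average.

    Returns the target x source connectivity matrix.  This is the
    ``pipeline_fn`` evaluated on every surrogate realization.
    """
    model = fit_dekf(ts, order=order, params=params)
    pdc = pdc_from_coeffs(model, freq_grid=freq_grid, time_stride=time_stride)
    return band_time_average(pdc, band=band)


def connectivity_profile(
    ts: MultichannelTimeSeries,
    order: int = DEFAULT_ORDER,
    band: tuple = DEFAULT_BAND,
    threshold: float = 0.1,
    params: FilterParams = None,
    freq_grid: np.ndarray = None,
    time_stride: int = 1,
    subject_id: str = "",
) -> ConnectivityProfile:
    """Seed->network (forward) and network->seed (backward) connectivity.

    Expects 8 channels: the pooled lesion-pattern seed followed by the
    seven networks.  Values below ``threshold`` (default 0.1) are still
    reported but flagged as not above threshold, pending the surrogate
    significance tests.
    """
    if ts.n_channels != 8:
        raise ValueError("expected 8 channels (seed + 7 networks)")
    matrix = tpdc_matrix(
        ts,
        order=order,
        band=band,
        params=params,
        freq_grid=freq_grid,
        time_stride=time_stride,
    )
    names = list(ts.channel_names[1:])
    forward = {}
    backward = {}
    sig_f = {}
    sig_b = {}
    for k, net in enumerate(names, start=1):
        forward[net] = float(matrix[k, 0])
        backward[net] = float(matrix[0, k])
        sig_f[net] = bool(matrix[k, 0] >= threshold)
        sig_b[net] = bool(matrix[0, k] >= threshold)
    return ConnectivityProfile(
        forward=forward,
        backward=backward,
        band=tuple(band),
        threshold=threshold,
        significant_forward=sig_f,
        significant_backward=sig_b,
        matrix=matrix,
        subject_id=subject_id,
    )
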