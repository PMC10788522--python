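"""Parallel ICA: joint decomposition of lesion maps and an HRV covariate.

The lesion modality (subjects x voxels) is whitened by truncated SVD and
unmixed with Infomax updates (natural-gradient entropy maximisation with
a logistic nonlinearity, symmetric re-orthogonalisation each step).  A
coupling term adds a gradient-ascent step on the squared Pearson
correlation between the currently best-matched lesion loading column
and the scalar covariate; its learning rate is halved whenever that
correlation objective decreases (adaptive adjustment).

The scalar-covariate modality is handled as a degenerate ICA whose
loading *is* the covariate, so the coupling term directly correlates
lesion loadings with the covariate.  Component count is chosen by an
information-criterion analysis of the subject-covariance eigenvalue
spectrum, stabilised over resampled runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lesions import LesionMap

__all__ = [
    "ModalityMatrix",
    "ComponentSet",
    "PicaHyper",
    "estimate_k",
    "fit_parallel_ica",
    "component_to_map",
]


@dataclass
class ModalityMatrix:
    """Subjects x features data for one modality."""

    values: np.ndarray
    feature_space: str = "voxels"  # or "scalar-covariate"
    subject_ids: list = None  # type: ignore[assignment]
    feature_shape: tuple = None  # type: ignore[assignment]
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if np.isnan(self.values).any():
            raise ValueError("missing values not allowed")
        if self.subject_ids is None:
            self.subject_ids = [f"sub_{i + 1}" for i in range(self.values.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_lesion_maps(cls, maps: list, subject_ids: list = None) -> "ModalityMatrix":
        shape = maps[0].values.shape
        values = np.stack([m.values.ravel() for m in maps])
        return cls(
            values=values,
            feature_space="voxels",
            subject_ids=subject_ids,
            feature_shape=shape,
            voxel_size=maps[0].voxel_size,
        )


@dataclass
class ComponentSet:
    """Paired components with cross-modality loading correlations."""

    loadings1: np.ndarray  # subjects x k (lesion modality)
    sources1: np.ndarray  # k x voxels
    loadings2: np.ndarray  # subjects x 1 (covariate modality)
    k: int
    cross_corr: list  # per component: (r, p)
    selected_pair: int
    converged: bool
    feature_shape: tuple = None  # type: ignore[assignment]
    voxel_size: tuple = (1.0, 1.0, 1.0)

    @property
    def selected_r(self) -> float:
        return self.cross_corr[self.selected_pair][0]


@dataclass
class PicaHyper:
    lr_ica: float = 0.02
    lr_corr: float = 0.05
    tol: float = 1e-6
    max_iters: int = 1000
    n_perms: int = 1000
    seed: int = 0


def _wax_kailath_aic(eigvals: np.ndarray, n_obs: int) -> np.ndarray:
    """AIC-style criterion over candidate component counts 1..p-2.

    Based on the arithmetic/geometric-mean ratio of the trailing
    eigenvalues of the subject covariance (the classic eigenvalue-based
    information criterion for source-number detection).  Feature-wise
    demeaning makes the smallest eigenvalue identically zero, so it is
    excluded, and near-zero eigenvalues are floored relative to the
    largest so numerical noise in a rank-deficient tail does not mimic
    structure.
    """
    eigvals = eigvals[:-1]  # exact zero from demeaning across subjects
    p = eigvals.size
    eigvals = np.maximum(eigvals, 1e-9 * eigvals[0])
    ks = np.arange(1, p)
    out = np.empty(ks.size)
    for idx, k in enumerate(ks):
        tail = eigvals[k:]
        log_g = np.mean(np.log(tail))
        log_a = np.log(np.mean(tail))
        out[idx] = -2.0 * n_obs * (p - k) * (log_g - log_a) + 2.0 * k * (2 * p - k)
    return out


def estimate_k(modality: ModalityMatrix, n_runs: int = 5, seed: int = 0) -> int:
    """Component count minimising an AIC-style eigenvalue criterion.

    Stabilised as the median over ``n_runs`` runs, the first on all
    features and the rest on random 80 % feature subsets (without
    replacement, so the independence the criterion assumes is kept).
    Degenerate covariance falls back to k = 1 with a warning.
    """
    if modality.n_subjects < 3:
        raise ValueError("need at least 3 subjects to estimate k")
    X = modality.values - modality.values.mean(axis=0, keepdims=True)
    n_feat = X.shape[1]
    rng = np.random.default_rng(seed)
    picks = []
    for run in range(n_runs):
        if run == 0:
            Xr = X
        else:
            keep = rng.permutation(n_feat)[: max(2, int(0.8 * n_feat))]
            Xr = X[:, keep]
        n_obs = Xr.shape[1]
        cov = Xr @ Xr.T / n_obs
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        if eigvals[0] <= 0 or not np.isfinite(eigvals).all():
            warnings.warn("degenerate covariance; falling back to k=1", stacklevel=2)
            return 1
        aic = _wax_kailath_aic(eigvals, n_obs)
        picks.append(int(np.argmin(aic)) + 1)
    k = int(np.median(picks))
    return min(k, modality.n_subjects - 1)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def _sym_orth(W: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation: W <- (W W^T)^(-1/2) W."""
    u, s, vt = np.linalg.svd(W, full_matrices=False)
    return u @ vt


def _perm_p(a: np.ndarray, b: np.ndarray, n_perms: int, rng: np.random.Generator) -> float:
    r_obs = abs(_corr(a, b))
    count = 0
    for _ in range(n_perms):
        if abs(_corr(a, rng.permutation(b))) >= r_obs:
            count += 1
    return (count + 1) / (n_perms + 1)


def fit_parallel_ica(
    mod1: ModalityMatrix,
    mod2: ModalityMatrix,
    k: int = None,
    hyper: PicaHyper = None,
) -> ComponentSet:
    """Joint Infomax ICA with a cross-modality correlation term.

    ``mod1`` is the voxel modality, ``mod2`` the scalar covariate (one
    feature per subject).  Significance of each component's loading
    correlation with the covariate is assessed by subject-label
    permutation; the selected pair is the significant one with the
    largest |r| (or the overall largest |r| when none reaches p < .05).
    """
    if hyper is None:
        hyper = PicaHyper()
    if mod1.n_subjects != mod2.n_subjects:
        raise ValueError("both modalities must contain the same subjects")
    if mod2.values.shape[1] != 1:
        raise ValueError("mod2 must be a single scalar covariate per subject")
    covariate = mod2.values[:, 0]
    s_count = mod1.n_subjects
    if k is None:
        k = estimate_k(mod1, seed=hyper.seed)
    if k > s_count - 1:
        raise ValueError("k must be <= subjects - 1")

    X = mod1.values - mod1.values.mean(axis=0, keepdims=True)
    n_feat = X.shape[1]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    M = U * S  # subjects x k loading basis; X = M @ Vt
    Y = Vt * np.sqrt(n_feat)  # whitened: k x voxels, unit variance rows

    rng = np.random.default_rng(hyper.seed)
    W = _sym_orth(rng.normal(size=(k, k)))
    lr_corr = hyper.lr_corr
    best_r2 = -np.inf
    converged = False

    c_cent = covariate - covariate.mean()
    c_norm = np.linalg.norm(c_cent)

    for _ in range(hyper.max_iters):
        W_old = W.copy()

        # Infomax natural-gradient step (logistic nonlinearity)
        Ssrc = W @ Y
        g = 1.0 - 2.0 / (1.0 + np.exp(-Ssrc))  # 1 - 2*sigmoid
        dW = (np.eye(k) + g @ Ssrc.T / n_feat) @ W
        W = W + hyper.lr_ica * dW

        # coupling step on the best-matched loading column
        A = M @ W.T / np.sqrt(n_feat)  # subjects x k
        rs = np.array([_corr(A[:, j], covariate) for j in range(k)])
        j_star = int(np.argmax(np.abs(rs)))
        r = rs[j_star]
        a = A[:, j_star]
        a_cent = a - a.mean()
        a_norm = np.linalg.norm(a_cent)
        if a_norm > 0 and c_norm > 0:
            dr_da = (c_cent / c_norm - r * a_cent / a_norm) / a_norm
            grad_w = 2.0 * r * (M.T @ dr_da) / np.sqrt(n_feat)
            W[j_star] = W[j_star] + lr_corr * grad_w
        r2 = r * r
        if r2 < best_r2:
            lr_corr *= 0.5  # adaptive adjustment of the correlation term
        best_r2 = max(best_r2, r2)

        W = _sym_orth(W)
        if np.max(np.abs(W - W_old)) < hyper.tol:
            converged = True
            break

    Ssrc = W @ Y
    A = M @ W.T / np.sqrt(n_feat)
    cross = []
    for j in range(k):
        r = _corr(A[:, j], covariate)
        p = _perm_p(A[:, j], covariate, hyper.n_perms, rng)
        cross.append((r, p))
    sig = [j for j in range(k) if cross[j][1] < 0.05]
    pool = sig if sig else list(range(k))
    selected = max(pool, key=lambda j: abs(cross[j][0]))
    return ComponentSet(
        loadings1=A,
        sources1=Ssrc,
        loadings2=covariate[:, None],
        k=k,
        cross_corr=cross,
        selected_pair=selected,
        converged=converged,
        feature_shape=mod1.feature_shape,
        voxel_size=mod1.voxel_size,
    )


def component_to_map(cs: ComponentSet, t_thresh: float = 3.0) -> LesionMap:
    """Selected lesion source map in z/t units, thresholded at > t_thresh.

    The source is scaled by its standard deviation; voxels at or below
    the threshold are zeroed.  The sign of the component is flipped if
    needed so that its loading correlation with the covariate is
    positive (ICA sign indeterminacy).
    """
    src = cs.sources1[cs.selected_pair].astype(float).copy()
    if cs.selected_r < 0:
        src = -src
    sd = src.std()
    if sd > 0:
        z = src / sd
    else:
        z = np.zeros_like(src)
    z[z <= t_thresh] = 0.0
    if not np.any(z):
        warnings.warn("no voxels survive the component threshold", stacklevel=2)
    shape = cs.feature_shape if cs.feature_shape is not None else (z.size, 1, 1)
    return LesionMap(values=z.reshape(shape), voxel_size=cs.voxel_size)
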