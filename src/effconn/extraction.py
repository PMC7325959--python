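"""From voxel data to labelled resting-state-network time courses.

Pipeline: nuisance regression + band-pass cleaning of the time dimension,
temporal concatenation across subjects, PCA reduction, component-number
estimation by minimum description length, group spatial ICA, dual-regression
back-reconstruction of per-subject maps and time courses, Z-scoring of
spatial maps with an |Z| > 1.5 active-voxel rule, and greedy template
matching to assign network labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

DEFAULT_Z_THRESHOLD = 1.5
DEFAULT_BAND = (0.01, 0.10)


# -- temporal cleaning -------------------------------------------------------

def preprocess_timecourses(
    series: np.ndarray,
    sampling_interval_s: float = 2.0,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    filter_order: int = 4,
) -> np.ndarray:
    """Regress out nuisance signals, then band-pass filter each column.

    ``series`` is T x N (or T x V); ``nuisance`` is T x m. The residual of
    an ordinary least-squares regression on [intercept, nuisance] is
    filtered with a zero-phase Butterworth band-pass (default 0.01-0.10 Hz,
    the standard BOLD band that removes slow scanner drift and
    high-frequency physiological noise).
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    T = Y.shape[0]
    low, high = band
    nyq = 0.5 / sampling_interval_s
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)"
        )

    X = np.ones((T, 1))
    if nuisance is not None:
        N = np.asarray(nuisance, dtype=float)
        if N.ndim == 1:
            N = N.reshape(-1, 1)
        if not np.all(np.isfinite(N)):
            raise ValueError("nuisance regressors contain non-finite values")
        X = np.hstack([X, N])
    # detect and drop rank-deficient nuisance columns via pivoted QR
    if X.shape[1] > 1:
        q, r, piv = _qr_pivot(X)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        keep = piv[np.abs(np.diag(r)) > tol]
        if len(keep) < X.shape[1]:
            dropped = sorted(set(range(X.shape[1])) - set(keep.tolist()))
            warnings.warn(
                f"nuisance design is rank deficient; dropped columns "
                f"{[d - 1 for d in dropped]} (0-based, excluding intercept)",
                UserWarning,
            )
            X = X[:, sorted(keep.tolist())]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    sos = signal.butter(
        filter_order, [low, high], btype="bandpass", fs=1.0 / sampling_interval_s,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, resid, axis=0)
    return filtered - filtered.mean(axis=0, keepdims=True)


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


# -- PCA reduction and order selection ---------------------------------------

def pca_reduce(data: np.ndarray, target_dims: int):
    """Reduce the row space of ``data`` (T_total x V) to ``target_dims``.

    Returns (reduced, basis, explained_fraction): ``reduced`` is
    target_dims x V (component rows ordered by decreasing variance),
    ``basis`` is T_total x target_dims with orthonormal columns so that
    ``basis @ reduced`` is the rank-``target_dims`` reconstruction, and
    ``explained_fraction`` is the fraction of total variance retained.
    """
    X = np.asarray(data, dtype=float)
    if target_dims < 1:
        raise ValueError("target_dims must be >= 1")
    if target_dims > min(X.shape):
        raise ValueError(
            f"target_dims={target_dims} exceeds min(data shape)={min(X.shape)}"
        )
    mean = X.mean(axis=0, keepdims=True)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    if target_dims > rank:
        raise ValueError(
            f"target_dims={target_dims} exceeds numerical rank {rank}; "
            f"the achievable maximum is {rank}"
        )
    basis = U[:, :target_dims]
    reduced = (s[:target_dims, None] * Vt[:target_dims])
    total = float(np.sum(s**2))
    explained = float(np.sum(s[:target_dims] ** 2) / total) if total > 0 else 1.0
    return reduced, basis, explained


def estimate_order_mdl(data: np.ndarray) -> int:
    """Number of components by the minimum-description-length criterion.

    Uses the classical MDL model-order estimator for signals in white
    noise: for each candidate order k it scores the log-likelihood that the
    trailing eigenvalues of the sample covariance are equal (sphericity)
    plus a parameter-count penalty, and returns the argmin. The smaller
    matrix dimension plays the role of the variable count p, the larger the
    sample count n.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    n, p = X.shape
    if p > n:
        X = X.T
        n, p = p, n
    Xc = X - X.mean(axis=0, keepdims=True)
    lam = np.linalg.eigvalsh(Xc.T @ Xc / n)[::-1]
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        raise ValueError("degenerate (zero-variance) data")
    # guard logs against exact zeros from rank deficiency
    floor = lam[0] * 1e-12
    lam = np.clip(lam, floor, None)
    mdl = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        m = p - k
        geo = float(np.mean(np.log(tail)))
        ari = float(np.log(np.mean(tail)))
        loglik = -n * m * (geo - ari)
        penalty = 0.5 * k * (2 * p - k) * np.log(n)
        mdl[k] = loglik + penalty
    return int(np.argmin(mdl))


# -- group ICA ---------------------------------------------------------------

@dataclass
class ICAResult:
    """Group spatial ICA output plus per-subject back-reconstructions."""

    group_maps: np.ndarray  # K x V
    group_timecourses: np.ndarray  # T_total x K
    z_maps: np.ndarray  # K x V, standardized over in-mask voxels
    active_masks: np.ndarray  # K x V boolean, |z| > threshold
    threshold: float
    subject_maps: list[np.ndarray] | None = None  # each K x V
    subject_timecourses: list[np.ndarray] | None = None  # each T x K
    mask: np.ndarray | None = None  # 3-D boolean voxel mask
    explained_variance: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]


def run_group_ica(
    reduced: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
    basis: np.ndarray | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> ICAResult:
    """Spatial ICA on PCA-reduced group data (``reduced`` is k x V).

    Fixed-point (FastICA) extraction in parallel/symmetric mode with a
    seeded start, so runs are deterministic. Components are sign-fixed
    (largest-|z| voxel positive) and ordered by decreasing explained
    variance. ``basis`` (T_total x k from :func:`pca_reduce`) lets the
    group time courses be expressed in the original time dimension.
    """
    R = np.asarray(reduced, dtype=float)
    k, V = R.shape
    if n_components > k:
        raise ValueError(
            f"n_components={n_components} exceeds reduced dimensionality {k}"
        )
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(R.T)  # V x K, spatially independent sources
        conv = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
    if conv:
        raise RuntimeError(
            f"ICA did not converge within {max_iter} iterations "
            f"(n_iter={ica.n_iter_}); increase max_iter or relax tol"
        )
    maps = S.T  # K x V
    mixing = ica.mixing_  # k x K: reduced = mixing @ maps (up to means)
    tc_reduced = mixing  # time course of each component in reduced space
    if basis is not None:
        tcs = np.asarray(basis) @ tc_reduced  # T_total x K
    else:
        tcs = tc_reduced

    # order components by explained variance: ||tc||^2 * ||map||^2
    power = (tcs**2).sum(axis=0) * (maps**2).sum(axis=1)
    order = np.argsort(power)[::-1]
    maps, tcs, power = maps[order], tcs[:, order], power[order]

    z_maps = np.empty_like(maps)
    for i in range(n_components):
        z, _ = zscore_and_mask(maps[i], z_threshold)
        z_maps[i] = z
    # sign convention: largest-|z| voxel positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(z_maps[i])))
        if z_maps[i][j] < 0:
            z_maps[i] = -z_maps[i]
            maps[i] = -maps[i]
            tcs[:, i] = -tcs[:, i]
    active = np.abs(z_maps) > z_threshold
    return ICAResult(
        group_maps=maps,
        group_timecourses=tcs,
        z_maps=z_maps,
        active_masks=active,
        threshold=z_threshold,
        explained_variance=power / power.sum(),
    )


def back_reconstruct(
    result: ICAResult, subject_data: list[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Dual-regression back-reconstruction.

    For each subject (data T x V on the group voxel grid): first regress
    the data on the group spatial maps to get subject time courses (T x K),
    then regress the data on those time courses to get subject maps
    (K x V).
    """
    M = result.group_maps  # K x V
    tcs_out, maps_out = [], []
    for Y in subject_data:
        Y = np.asarray(Y, dtype=float)
        if Y.shape[1] != M.shape[1]:
            raise ValueError(
                f"subject data has {Y.shape[1]} voxels; group maps have "
                f"{M.shape[1]} — grids do not match"
            )
        tc, *_ = np.linalg.lstsq(M.T, Y.T, rcond=None)  # K x T
        tc = tc.T  # T x K
        smap, *_ = np.linalg.lstsq(tc, Y, rcond=None)  # K x V
        tcs_out.append(tc)
        maps_out.append(smap)
    return tcs_out, maps_out


# -- Z-scoring, template matching, summaries ---------------------------------

def zscore_and_mask(map_values: np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD):
    """Standardize a spatial map and flag active voxels at |z| > threshold.

    The inequality is strict: a voxel at exactly |z| = threshold is not
    active.
    """
    m = np.asarray(map_values, dtype=float).ravel()
    sd = m.std()
    if sd == 0:
        raise ValueError("constant map cannot be Z-scored")
    z = (m - m.mean()) / sd
    return z, np.abs(z) > threshold


def match_templates(
    z_maps: np.ndarray, template_maps: np.ndarray, labels: list[str]
) -> dict[str, tuple[int, float]]:
    """Assign each template label the free component with the largest
    spatial (Pearson) correlation, greedily in descending correlation order.

    Returns ``{label: (component index, correlation)}``; no component
    serves two labels.
    """
    Z = np.asarray(z_maps, dtype=float)
    Tm = np.asarray(template_maps, dtype=float).reshape(len(labels), -1)
    K = Z.shape[0]
    L = len(labels)
    if K < L:
        raise ValueError(
            f"only {K} components available for {L} templates "
            f"(short by {L - K})"
        )
    corr = np.empty((L, K))
    for i in range(L):
        for j in range(K):
            corr[i, j] = _pearson(Tm[i], Z[j])
    assignment: dict[str, tuple[int, float]] = {}
    used_labels: set[int] = set()
    used_comps: set[int] = set()
    flat = [(-corr[i, j], i, j) for i in range(L) for j in range(K)]
    for negc, i, j in sorted(flat):
        if i in used_labels or j in used_comps:
            continue
        assignment[labels[i]] = (j, -negc)
        used_labels.add(i)
        used_comps.add(j)
        if len(used_labels) == L:
            break
    return assignment


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def mean_active_z(z_map: np.ndarray, active_mask: np.ndarray) -> float:
    """Mean |z| over active voxels — the per-network activation summary.

    The active set is defined by |z| exceeding the threshold on either
    tail, so the magnitude is averaged; the result always exceeds the
    threshold used to build the mask.
    """
    mask = np.asarray(active_mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("active mask is empty")
    return float(np.mean(np.abs(np.asarray(z_map, float).ravel()[mask])))


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Permutation/scale-invariant distance between an unmixing estimate W
    and the true mixing A; 0 means perfect source recovery."""
    P = np.abs(np.asarray(W) @ np.asarray(A))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1
    return float((rows.sum() + cols.sum()) / (2 * n * (n - 1)))


# -- estimator facade ---------------------------------------------------------

class GroupICA(BaseEstimator):
    """Group spatial ICA as a scikit-learn style transformer.

    ``fit`` takes a list of per-subject T x V arrays (already cleaned, on a
    shared voxel grid), concatenates them in time, reduces to ``pca_dims``
    principal components, and extracts ``n_components`` spatially
    independent maps (``n_components='mdl'`` estimates the count from the
    reduced data). ``transform`` back-reconstructs per-subject time
    courses by dual regression.

    Parameters
    ----------
    n_components : int or "mdl", default 25
    pca_dims : int, default 40
    z_threshold : float, default 1.5
        |Z| cut-off for the active-voxel masks.
    random_state : int, default 0

    Attributes
    ----------
    group_maps_ : (K, V) component spatial maps
    group_timecourses_ : (T_total, K)
    z_maps_, active_masks_ : standardized maps and |z|-threshold masks
    n_components_ : the component count actually used
    """

    def __init__(self, n_components=25, pca_dims=40,
                 z_threshold=DEFAULT_Z_THRESHOLD, random_state=0,
                 max_iter=1000, tol=1e-5):
        self.n_components = n_components
        self.pca_dims = pca_dims
        self.z_threshold = z_threshold
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        data = [np.asarray(x, dtype=float) for x in X]
        V = data[0].shape[1]
        for d in data:
            if d.shape[1] != V:
                raise ValueError("subjects must share the voxel grid")
        concat = np.vstack(data)
        dims = min(self.pca_dims, min(concat.shape))
        reduced, basis, _ = pca_reduce(concat, dims)
        if self.n_components == "mdl":
            k = max(1, estimate_order_mdl(reduced))
        else:
            k = int(self.n_components)
        res = run_group_ica(
            reduced, k, seed=self.random_state, max_iter=self.max_iter,
            tol=self.tol, basis=basis, z_threshold=self.z_threshold,
        )
        self.result_ = res
        self.group_maps_ = res.group_maps
        self.group_timecourses_ = res.group_timecourses
        self.z_maps_ = res.z_maps
        self.active_masks_ = res.active_masks
        self.n_components_ = k
        self.subject_lengths_ = [d.shape[0] for d in data]
        return self

    def transform(self, X):
        """Per-subject component time courses (list of T x K arrays)."""
        data = [np.asarray(x, dtype=float) for x in X]
        tcs, maps = back_reconstruct(self.result_, data)
        self.subject_maps_ = maps
        self.subject_timecourses_ = tcs
        return tcs

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def compute_mask(volumes: list[np.ndarray]) -> np.ndarray:
    """Boolean in-brain mask: voxels with nonzero variance across all
    subjects' 4-D volumes (grid + time in the last axis)."""
    var = None
    for v in volumes:
        vv = np.asarray(v, dtype=float).std(axis=-1)
        var = vv if var is None else np.maximum(var, vv)
    return var > 0


def flatten_volumes(volumes: list[np.ndarray], mask: np.ndarray) -> list[np.ndarray]:
    """Apply a 3-D mask to 4-D volumes, returning per-subject T x V arrays."""
    out = []
    for v in volumes:
        v = np.asarray(v, dtype=float)
        out.append(v[mask].T)  # V x T -> T x V
    return out
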