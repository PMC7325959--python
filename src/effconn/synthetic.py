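"""Synthetic multi-subject cohorts with known lag-1 causal structure.

The generator is the testbed for the whole effective-connectivity pipeline:
it runs the signed-path-coefficient VAR(1) model *forward* from a known
coefficient matrix, so every downstream stage (extraction, model fitting,
group statistics, degree metrics) can be validated against ground truth.

The default cohort emulates a three-group leukoaraiosis study design:
normal controls (NC, n=35), patients with vascular cognitive impairment
no dementia (LA-VCIND, n=32) and patients with vascular dementia
(LA-VaD, n=20), each subject contributing ~230 retained volumes sampled
at TR = 2 s across 10 resting-state networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_NODE_LABELS = (
    "PVN", "SVN", "AN", "SMN", "aDMN", "pDMN", "SN", "DAN", "lWMN", "rWMN",
)

#: study design emulated by the default cohort: group -> (n, mean age, age SD,
#: male fraction)
DEFAULT_DEMOGRAPHICS = {
    "NC": (35, 62.83, 6.98, 14 / 35),
    "LA-VCIND": (32, 64.34, 9.68, 14 / 32),
    "LA-VaD": (20, 65.70, 8.01, 6 / 20),
}

#: retained time points per subject (240 acquired volumes over ~8 min at
#: TR = 2 s, minus the 10 discarded at the start of the run)
DEFAULT_T = 230


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A stationary lag-1 causal network.

    ``A_true[j, k]`` is the signed path coefficient of node ``k`` at time
    t-1 on node ``j`` at time t; self influence is kept separately in
    ``self_coeffs`` so the off-diagonal matrix is purely cross-network.
    """

    node_labels: tuple[str, ...]
    A_true: np.ndarray
    self_coeffs: np.ndarray
    C_true: np.ndarray
    noise_sd: np.ndarray
    seed: int = 0
    rescale_factor: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_covariates(self) -> int:
        return self.C_true.shape[1]

    def companion(self) -> np.ndarray:
        """Full lag-1 transition matrix: cross paths plus the diagonal."""
        return self.A_true + np.diag(self.self_coeffs)

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def to_dict(self) -> dict:
        return {
            "node_labels": list(self.node_labels),
            "A_true": self.A_true.tolist(),
            "self_coeffs": self.self_coeffs.tolist(),
            "C_true": self.C_true.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "seed": self.seed,
            "rescale_factor": self.rescale_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthNetwork":
        return cls(
            node_labels=tuple(d["node_labels"]),
            A_true=np.asarray(d["A_true"], dtype=float),
            self_coeffs=np.asarray(d["self_coeffs"], dtype=float),
            C_true=np.asarray(d["C_true"], dtype=float),
            noise_sd=np.asarray(d["noise_sd"], dtype=float),
            seed=int(d["seed"]),
            rescale_factor=float(d["rescale_factor"]),
        )


@dataclass
class Subject:
    subject_id: str
    group: str
    age: float
    sex: int  # 0 = female, 1 = male
    timeseries: np.ndarray  # T x N
    covariate_series: np.ndarray  # T x c


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    ground_truth: dict[str, GroundTruthNetwork]
    node_labels: tuple[str, ...]
    T: int
    seed: int

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]

    @property
    def groups(self) -> list[str]:
        return list(self.ground_truth.keys())

    def covariate_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
            }
        )


def make_ground_truth(
    node_labels,
    edges,
    self_coeff=0.3,
    covariate_coeffs=None,
    noise_sd=1.0,
    seed=0,
    max_spectral_radius=0.95,
) -> GroundTruthNetwork:
    """Assemble a stationary ground-truth network from an edge list.

    Parameters
    ----------
    edges : list of (source, target, weight)
        Signed lag-1 path coefficients; source influences target one step
        later.
    self_coeff : float or sequence
        Lag-1 autoregression per node.
    covariate_coeffs : None, float or array (N,) or (N, c)
        Loading of the contemporaneous covariate(s) on each node; ``None``
        means a single covariate with zero loading.
    noise_sd : float or sequence
        Innovation standard deviation per node.

    If the requested weights make the lag-1 transition matrix non-stationary
    the whole matrix (cross paths and self terms alike) is shrunk uniformly
    until its spectral radius equals ``max_spectral_radius``; the applied
    factor is stored in ``rescale_factor``.
    """
    node_labels = tuple(node_labels)
    n = len(node_labels)
    if len(set(node_labels)) != n:
        dupes = sorted({x for x in node_labels if node_labels.count(x) > 1})
        raise ValueError(f"duplicate node labels: {dupes}")
    index = {lab: i for i, lab in enumerate(node_labels)}

    A = np.zeros((n, n))
    for source, target, weight in edges:
        if source not in index or target not in index:
            unknown = [x for x in (source, target) if x not in index]
            raise KeyError(f"edge references unknown node(s): {unknown}")
        if not np.isfinite(weight):
            raise ValueError(f"non-finite weight on edge {source}->{target}")
        if source == target:
            raise ValueError(
                f"self edge {source}->{target}: self influence belongs in self_coeff"
            )
        A[index[target], index[source]] = weight

    self_coeffs = np.broadcast_to(np.asarray(self_coeff, float), (n,)).copy()
    noise = np.broadcast_to(np.asarray(noise_sd, float), (n,)).copy()
    if np.any(noise < 0):
        raise ValueError("noise_sd must be non-negative")

    if covariate_coeffs is None:
        C = np.zeros((n, 1))
    else:
        C = np.asarray(covariate_coeffs, dtype=float)
        if C.ndim == 0:
            C = np.full((n, 1), float(C))
        elif C.ndim == 1:
            C = C.reshape(n, 1)

    companion = A + np.diag(self_coeffs)
    rho = float(np.max(np.abs(np.linalg.eigvals(companion)))) if n else 0.0
    factor = 1.0
    if rho > max_spectral_radius:
        factor = max_spectral_radius / rho
        A = A * factor
        self_coeffs = self_coeffs * factor

    return GroundTruthNetwork(
        node_labels=node_labels,
        A_true=A,
        self_coeffs=self_coeffs,
        C_true=C,
        noise_sd=noise,
        seed=seed,
        rescale_factor=factor,
    )


def default_covariate_series(T, rng, amplitude=0.1, period_s=120.0, tr_s=2.0):
    """Slow sinusoidal drift used as the contemporaneous covariate Z_t.

    One cycle every ``period_s`` seconds with a random phase per subject;
    the default amplitude is 0.1 of the unit signal SD, small enough to be
    a nuisance rather than a driver.
    """
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(T) * tr_s
    return (amplitude * np.sin(2 * np.pi * t / period_s + phase)).reshape(-1, 1)


def simulate_subject(
    gt: GroundTruthNetwork,
    T: int,
    rng: np.random.Generator,
    Z=None,
    burn_in: int = 100,
    initial_state=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the VAR(1) forward: Y_t = (A + diag(self)) Y_{t-1} + C Z_t + eps_t.

    Returns (timeseries T x N, covariate series T x c). ``burn_in`` leading
    steps are simulated and discarded so the retained stretch is
    approximately stationary.
    """
    if gt.spectral_radius() >= 1.0:
        raise ValueError(
            f"ground truth is non-stationary (spectral radius "
            f"{gt.spectral_radius():.3f}); refusing to simulate"
        )
    n = gt.n_nodes
    c = gt.n_covariates
    if Z is None:
        Z = default_covariate_series(T + burn_in, rng)
        if Z.shape[1] != c:
            Z = np.zeros((T + burn_in, c))
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] == T and burn_in > 0:
            Z = np.vstack([np.zeros((burn_in, Z.shape[1])), Z])
    M = gt.companion()
    total = T + burn_in
    eps = rng.normal(0.0, 1.0, size=(total, n)) * gt.noise_sd
    Y = np.empty((total, n))
    state = np.zeros(n) if initial_state is None else np.asarray(initial_state, float)
    for t in range(total):
        state = M @ state + gt.C_true @ Z[t] + eps[t]
        Y[t] = state
    return Y[burn_in:], Z[burn_in:]


def simulate_cohort(
    ground_truths: dict[str, GroundTruthNetwork],
    group_sizes: dict[str, int] | None = None,
    T: int = DEFAULT_T,
    demographics_spec: dict | None = None,
    seed: int = 0,
    burn_in: int = 100,
    covariate_amplitude: float = 0.1,
    age_effect=None,
) -> SyntheticCohort:
    """Simulate a multi-group cohort from per-group ground truths.

    Parameters
    ----------
    ground_truths : mapping group label -> GroundTruthNetwork
    group_sizes : mapping group label -> n subjects; defaults to the
        three-group study design (35/32/20) where labels match, else 20.
    demographics_spec : mapping group -> (age_mean, age_sd, male_fraction);
        defaults emulate the study demographics.
    age_effect : optional (source, target, slope_per_year)
        Adds ``slope * (age - 65)`` to one path coefficient per subject, for
        covariate-adjustment power studies. Off by default.
    """
    if T < 50:
        raise ValueError("T must be >= 50")
    labels = None
    for g, gt in ground_truths.items():
        if gt.spectral_radius() >= 1.0:
            raise ValueError(f"group {g!r} ground truth is non-stationary")
        if labels is None:
            labels = gt.node_labels
        elif gt.node_labels != labels:
            raise ValueError("all groups must share node labels")
    assert labels is not None

    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    for group, gt in ground_truths.items():
        if group_sizes and group in group_sizes:
            n_sub = group_sizes[group]
        elif group in DEFAULT_DEMOGRAPHICS:
            n_sub = DEFAULT_DEMOGRAPHICS[group][0]
        else:
            n_sub = 20
        if demographics_spec and group in demographics_spec:
            age_mean, age_sd, male_frac = demographics_spec[group]
        elif group in DEFAULT_DEMOGRAPHICS:
            _, age_mean, age_sd, male_frac = DEFAULT_DEMOGRAPHICS[group]
        else:
            age_mean, age_sd, male_frac = 65.0, 8.0, 0.5
        for i in range(n_sub):
            age = float(rng.normal(age_mean, age_sd))
            sex = int(rng.random() < male_frac)
            gt_i = gt
            if age_effect is not None:
                source, target, slope = age_effect
                A = gt.A_true.copy()
                si = gt.node_labels.index(source)
                ti = gt.node_labels.index(target)
                A[ti, si] += slope * (age - 65.0)
                gt_i = GroundTruthNetwork(
                    gt.node_labels, A, gt.self_coeffs, gt.C_true,
                    gt.noise_sd, gt.seed, gt.rescale_factor,
                )
            Z = default_covariate_series(T + burn_in, rng,
                                         amplitude=covariate_amplitude)
            if Z.shape[1] != gt.n_covariates:
                Z = np.zeros((T + burn_in, gt.n_covariates))
            Y, Zs = simulate_subject(gt_i, T, rng, Z=Z, burn_in=burn_in)
            subjects.append(
                Subject(
                    subject_id=f"{group}_{i + 1:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    timeseries=Y,
                    covariate_series=Zs,
                )
            )
    return SyntheticCohort(
        subjects=subjects,
        ground_truth=dict(ground_truths),
        node_labels=labels,
        T=T,
        seed=seed,
    )


# -- default study-like ground truths ---------------------------------------

#: cross-network paths shared by all groups; signs and ~0.1-0.2 magnitudes
#: mirror the strong consistently-signed connections of the control-group
#: effective-connectivity pattern (broad negative outflow from SVN, negative
#: DAN outflow, positive flow into aDMN).
_COMMON_EDGES = [
    ("SVN", "PVN", -0.16),
    ("SVN", "AN", -0.14),
    ("SVN", "SMN", -0.13),
    ("SVN", "SN", -0.15),
    ("SVN", "lWMN", -0.14),
    ("SVN", "rWMN", -0.15),
    ("PVN", "SVN", 0.12),
    ("aDMN", "SMN", 0.12),
    ("SMN", "pDMN", -0.11),
    ("DAN", "aDMN", -0.14),
    ("DAN", "SN", -0.13),
    ("DAN", "lWMN", -0.15),
    ("DAN", "rWMN", -0.15),
    ("pDMN", "rWMN", 0.12),
    ("SN", "rWMN", 0.11),
]

#: group-specific signed paths: the four connections the study reports as
#: altered across groups, at the printed group-mean coefficients.
_GROUP_EDGES = {
    "NC": [
        ("DAN", "PVN", -0.083),
        ("DAN", "pDMN", -0.147),
        ("SVN", "aDMN", -0.126),
        ("aDMN", "SVN", 0.085),
    ],
    "LA-VCIND": [
        ("DAN", "PVN", 0.012),
        ("DAN", "pDMN", -0.079),
        ("SVN", "aDMN", -0.127),
        ("aDMN", "SVN", 0.095),
    ],
    "LA-VaD": [
        ("DAN", "PVN", -0.175),
        ("DAN", "pDMN", -0.203),
        ("SVN", "aDMN", -0.021),
        ("aDMN", "SVN", -0.012),
    ],
}


def default_ground_truths(seed: int = 0) -> dict[str, GroundTruthNetwork]:
    """Three-group ground truth emulating the leukoaraiosis study.

    All groups share a common backbone of signed paths plus a lag-1
    self term of 0.3; four connections take group-specific values equal to
    the group-mean path coefficients the study reports for its altered
    edges.
    """
    out = {}
    for group, extra in _GROUP_EDGES.items():
        out[group] = make_ground_truth(
            DEFAULT_NODE_LABELS,
            _COMMON_EDGES + extra,
            self_coeff=0.3,
            covariate_coeffs=0.05,
            noise_sd=1.0,
            seed=seed,
        )
    return out


def planted_edge_ground_truths(
    source: str = "DAN",
    target: str = "PVN",
    values: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, GroundTruthNetwork]:
    """Ground truths identical across groups except for ONE planted edge.

    The shared backbone is the common edge set; only ``source -> target``
    takes group-specific values (defaults: the reported group means of the
    most altered connection). Useful for power and specificity studies:
    any other edge flagged as differing between groups is a false
    positive.
    """
    if values is None:
        values = {"NC": -0.083, "LA-VCIND": 0.012, "LA-VaD": -0.175}
    out = {}
    for group, w in values.items():
        out[group] = make_ground_truth(
            DEFAULT_NODE_LABELS,
            _COMMON_EDGES + [(source, target, w)],
            self_coeff=0.3,
            covariate_coeffs=0.05,
            noise_sd=1.0,
            seed=seed,
        )
    return out


def default_cohort(seed: int = 0, T: int = DEFAULT_T,
                   group_sizes=None) -> SyntheticCohort:
    """The default three-group synthetic cohort (NC 35, LA-VCIND 32, LA-VaD 20)."""
    return simulate_cohort(default_ground_truths(seed), group_sizes=group_sizes,
                           T=T, seed=seed)


# -- voxel-space mixing ------------------------------------------------------

@dataclass
class SpatialMixingModel:
    """Maps network time courses into a small voxel grid.

    Each component occupies a Gaussian blob at its own grid location;
    ``component_maps`` holds N signal maps followed by k pure-noise
    component maps whose time courses are drawn independently.
    """

    grid_shape: tuple[int, int, int]
    component_maps: np.ndarray  # (N + k) x X x Y x Z
    n_signal: int
    voxel_noise_sd: float = 0.1

    @property
    def n_components(self) -> int:
        return self.component_maps.shape[0]

    def flat_maps(self) -> np.ndarray:
        return self.component_maps.reshape(self.n_components, -1)


def make_mixing_model(
    grid_shape=(12, 12, 8),
    n_signal=10,
    n_noise=2,
    voxel_noise_sd=0.1,
    blob_sd=1.2,
    seed=0,
) -> SpatialMixingModel:
    """Place one Gaussian blob per component at well-separated grid sites.

    Components must be spatially distinct (pairwise correlation < 0.5),
    which bounded blobs at distinct centres guarantee as long as the grid
    is large enough to hold them.
    """
    rng = np.random.default_rng(seed)
    total = n_signal + n_noise
    gx, gy, gz = grid_shape
    # lay centres on a coarse lattice with margin, shuffled deterministically
    margin = 2
    xs = np.linspace(margin, gx - 1 - margin, max(2, int(np.ceil(total ** (1 / 2)))))
    ys = np.linspace(margin, gy - 1 - margin, max(2, int(np.ceil(total ** (1 / 2)))))
    zs = np.linspace(1, gz - 2, max(1, int(np.ceil(total / (len(xs) * len(ys))))))
    centres = [(x, y, z) for z in zs for x in xs for y in ys]
    if len(centres) < total:
        raise ValueError(
            f"grid {grid_shape} too small for {total} distinct component maps"
        )
    order = rng.permutation(len(centres))[:total]
    coords = np.stack(
        np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij"),
        axis=-1,
    ).astype(float)
    maps = np.empty((total, gx, gy, gz))
    for i, ci in enumerate(order):
        cx, cy, cz = centres[ci]
        d2 = ((coords - np.array([cx, cy, cz])) ** 2).sum(axis=-1)
        maps[i] = np.exp(-d2 / (2 * blob_sd**2))
    flat = maps.reshape(total, -1)
    corr = np.corrcoef(flat)
    off = corr[~np.eye(total, dtype=bool)]
    if np.any(np.abs(off) >= 0.5):
        raise ValueError(
            f"grid {grid_shape} too small: component maps overlap "
            f"(max pairwise correlation {np.max(np.abs(off)):.2f})"
        )
    return SpatialMixingModel(
        grid_shape=tuple(grid_shape),
        component_maps=maps,
        n_signal=n_signal,
        voxel_noise_sd=voxel_noise_sd,
    )


def simulate_voxel_volumes(
    cohort: SyntheticCohort,
    mixing: SpatialMixingModel,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Mix each subject's network time courses into 4D voxel volumes.

    voxel series = sum_i map_i * timecourse_i + Gaussian voxel noise; noise
    components get i.i.d. standard-normal time courses. Output arrays are
    shaped grid_shape + (T,).
    """
    n = len(cohort.node_labels)
    if mixing.n_signal < n:
        raise ValueError(
            f"mixing model has {mixing.n_signal} signal maps for {n} networks"
        )
    rng = np.random.default_rng(seed)
    flat = mixing.flat_maps()
    out = {}
    for sub in cohort.subjects:
        T = sub.timeseries.shape[0]
        tcs = [sub.timeseries[:, i] for i in range(n)]
        for j in range(mixing.n_signal, mixing.n_components):
            tcs.append(rng.normal(size=T))
        tc = np.column_stack(tcs)  # T x (N + k)
        vol = tc @ flat[: tc.shape[1]]  # T x V
        if mixing.voxel_noise_sd > 0:
            vol = vol + rng.normal(0.0, mixing.voxel_noise_sd, size=vol.shape)
        out[sub.subject_id] = np.moveaxis(
            vol.reshape((T,) + mixing.grid_shape), 0, -1
        )
    return out


# -- persistence -------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write a cohort to disk: per-subject time-series CSVs, a covariate
    table, and a ground-truth manifest. Returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    z_dir = out_dir / "covariate_series"
    z_dir.mkdir(exist_ok=True)
    for sub in cohort.subjects:
        df = pd.DataFrame(sub.timeseries, columns=list(cohort.node_labels))
        df.to_csv(ts_dir / f"{sub.subject_id}.csv", index=False)
        zf = pd.DataFrame(
            sub.covariate_series,
            columns=[f"Z{i}" for i in range(sub.covariate_series.shape[1])],
        )
        zf.to_csv(z_dir / f"{sub.subject_id}.csv", index=False)
    cohort.covariate_table().to_csv(out_dir / "covariates.csv", index=False)
    manifest = {
        "node_labels": list(cohort.node_labels),
        "T": cohort.T,
        "seed": cohort.seed,
        "groups": {g: gt.to_dict() for g, gt in cohort.ground_truth.items()},
        "subjects": [s.subject_id for s in cohort.subjects],
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(in_dir) -> SyntheticCohort:
    """Re-load a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    with open(in_dir / "ground_truth.json") as fh:
        manifest = json.load(fh)
    cov = pd.read_csv(in_dir / "covariates.csv")
    cov = cov.set_index("subject_id")
    subjects = []
    for sid in manifest["subjects"]:
        ts = pd.read_csv(in_dir / "timeseries" / f"{sid}.csv")
        z_path = in_dir / "covariate_series" / f"{sid}.csv"
        if z_path.exists():
            Z = pd.read_csv(z_path).to_numpy(float)
        else:
            Z = np.zeros((len(ts), 0))
        row = cov.loc[sid]
        subjects.append(
            Subject(
                subject_id=sid,
                group=str(row["group"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                timeseries=ts.to_numpy(float),
                covariate_series=Z,
            )
        )
    gts = {g: GroundTruthNetwork.from_dict(d)
           for g, d in manifest["groups"].items()}
    return SyntheticCohort(
        subjects=subjects,
        ground_truth=gts,
        node_labels=tuple(manifest["node_labels"]),
        T=int(manifest["T"]),
        seed=int(manifest["seed"]),
    )
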