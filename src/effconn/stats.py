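"""Group-level inference on path coefficients and network activation.

Two layers of inference mirror the analysis design:

* within each group, a one-sample t test per directed edge asks whether
  the group-mean signed path coefficient differs from zero; the surviving
  edges form the group's effective-connectivity pattern. Two significance
  rules are available — uncorrected p < 0.01 and Benjamini-Hochberg FDR
  q < 0.05 — because published connectivity tables are commonly built with
  either. The multiple-testing family is the N^2 - N off-diagonal edges of
  one group's matrix (90 for ten networks).
* across groups, an ANCOVA per quantity (edge coefficient or network
  mean-Z) tests the group factor with age and sex as covariates, followed
  by Bonferroni-adjusted pairwise contrasts of covariate-adjusted means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .graph import EffectiveConnectivityPattern

DEFAULT_ALPHA = 0.01
DEFAULT_FDR_Q = 0.05


def fdr_bh(p_values, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def edge_one_sample_t(
    coef_stack: np.ndarray,
    mu0: float = 0.0,
    node_labels=None,
    fdr_q: float = DEFAULT_FDR_Q,
) -> pd.DataFrame:
    """Per-edge one-sample t test on a subjects x N x N coefficient stack.

    Diagonal (self) entries are excluded; each of the N^2 - N directed
    edges gets the classical t = (mean - mu0) * sqrt(n) / SD with n - 1
    degrees of freedom and a two-sided p, plus a BH-FDR q over the edge
    family. Edges with zero SD get t = 0 when the mean equals mu0 and
    +/-inf (p = 0) otherwise.

    Returns a DataFrame with one row per directed edge: source, target,
    mean, sd, n, t, p, q, significant (q < ``fdr_q``).
    """
    stack = np.asarray(coef_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("coef_stack must be subjects x N x N")
    S, N, _ = stack.shape
    if S < 3:
        raise ValueError("need at least 3 subjects for a one-sample t test")
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(N)]

    rows = []
    for tgt in range(N):
        for src in range(N):
            if src == tgt:
                continue
            vals = stack[:, tgt, src]
            vals = vals[np.isfinite(vals)]
            n = vals.size
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            if sd > 0:
                t = (mean - mu0) * np.sqrt(n) / sd
                p = 2 * sps.t.sf(abs(t), df=n - 1)
            elif mean == mu0:
                t, p = 0.0, 1.0
            else:
                t = np.inf if mean > mu0 else -np.inf
                p = 0.0
            rows.append(
                {
                    "source": node_labels[src],
                    "target": node_labels[tgt],
                    "mean": mean,
                    "sd": sd,
                    "n": n,
                    "t": float(t),
                    "p": float(p),
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = _bh_q(table["p"].to_numpy())
    table["significant"] = table["q"] < fdr_q
    return table


def _bh_q(p: np.ndarray) -> np.ndarray:
    _, q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q


def one_sample_t_from_summary(mean: float, sd: float, n: int,
                              mu0: float = 0.0) -> tuple[float, float]:
    """t statistic and two-sided p from printed summary values."""
    t = (mean - mu0) * np.sqrt(n) / sd
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def group_pattern(
    stats_table: pd.DataFrame,
    rule: str = "p<0.01",
    node_labels=None,
    group: str = "",
) -> EffectiveConnectivityPattern:
    """Threshold an edge-statistics table into a signed binary pattern.

    ``rule`` is either ``"p<ALPHA"`` (uncorrected, default p < 0.01) or
    ``"fdr_q<Q"`` (Benjamini-Hochberg, e.g. ``"fdr_q<0.05"``). Retained
    edges carry the sign of the group-mean coefficient.
    """
    rule = rule.replace(" ", "")
    if rule.startswith("p<"):
        alpha = float(rule[2:])
        keep = stats_table["p"].to_numpy() < alpha
    elif rule.startswith("fdr_q<") or rule.startswith("q<"):
        q = float(rule.split("<")[1])
        keep = fdr_bh(stats_table["p"].to_numpy(), q=q)
    else:
        raise ValueError(
            f"unknown significance rule {rule!r}; use 'p<ALPHA' or 'fdr_q<Q'"
        )
    if node_labels is None:
        node_labels = list(
            dict.fromkeys(stats_table["target"]).keys()
        )
    edges = {}
    for row, k in zip(stats_table.itertuples(index=False), keep):
        if k:
            edges[(row.source, row.target)] = 1 if row.mean >= 0 else -1
    return EffectiveConnectivityPattern(
        node_labels=tuple(node_labels), edges=edges, group=group
    )


def pattern_from_t_matrix(
    t_frame: pd.DataFrame, n_subjects: int, alpha: float = DEFAULT_ALPHA,
    group: str = "",
) -> EffectiveConnectivityPattern:
    """Pattern from a printed t-statistic matrix (column-causes-row).

    Keeps cells with |t| above the two-tailed critical value at
    df = n_subjects - 1; the edge sign is the sign of t (the group-mean
    coefficient and its t statistic share a sign).
    """
    labels = tuple(t_frame.columns)
    crit = sps.t.ppf(1 - alpha / 2, df=n_subjects - 1)
    edges = {}
    for tgt in labels:
        for src in labels:
            if src == tgt:
                continue
            v = t_frame.loc[tgt, src]
            if pd.notna(v) and abs(float(v)) > crit:
                edges[(src, tgt)] = 1 if float(v) > 0 else -1
    return EffectiveConnectivityPattern(node_labels=labels, edges=edges,
                                        group=group)


@dataclass
class AncovaResult:
    """Covariate-adjusted group comparison of one quantity."""

    F: float
    p: float
    df_group: int
    df_resid: int
    adjusted_means: dict[str, float]
    covariate_coefs: dict[str, float]
    posthoc_p: dict[tuple[str, str], float]  # Bonferroni-adjusted


def ancova_with_covariates(values, groups, age=None, sex=None) -> AncovaResult:
    """ANCOVA: value ~ group + age + sex, partial F for the group factor.

    The group factor enters as G-1 dummies; F compares the residual sum of
    squares of the full model against the model without group dummies.
    Adjusted group means are evaluated at the covariate grand means.
    Post hoc: pairwise contrasts of adjusted means with Bonferroni
    correction (factor = number of pairs). Passing ``None`` for a
    covariate omits it; with both omitted this is a one-way ANOVA.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cov_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    for name, col in (("age", age), ("sex", sex)):
        if col is not None:
            col = np.asarray(col, dtype=float)
            if not np.all(np.isfinite(col)):
                raise ValueError(f"covariate {name!r} must be finite")
            cov_cols.append(col)
            cov_names.append(name)
    labels = list(dict.fromkeys(groups.tolist()))
    G = len(labels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    for lab in labels:
        if np.sum(groups == lab) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 subjects")
    n = y.size
    dummies = np.column_stack([(groups == lab).astype(float)
                               for lab in labels[1:]])
    covs = (np.column_stack(cov_cols) if cov_cols
            else np.empty((n, 0)))
    X_full = np.column_stack([np.ones(n), dummies, covs])
    X_red = np.column_stack([np.ones(n), covs])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design is collinear (group dummies vs covariates)")

    beta_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid_full = y - X_full @ beta_full
    sse_full = float(resid_full @ resid_full)
    beta_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    resid_red = y - X_red @ beta_red
    sse_red = float(resid_red @ resid_red)

    df_group = G - 1
    df_resid = n - G - covs.shape[1]
    F = ((sse_red - sse_full) / df_group) / (sse_full / df_resid)
    F = max(F, 0.0)
    p = float(sps.f.sf(F, df_group, df_resid))

    # adjusted means at covariate grand means
    grand = covs.mean(axis=0) if covs.shape[1] else np.empty(0)
    adj = {}
    base = float(beta_full[0] + beta_full[G:] @ grand)
    adj[labels[0]] = base
    for i, lab in enumerate(labels[1:]):
        adj[lab] = base + float(beta_full[1 + i])

    sigma2 = sse_full / df_resid
    XtX_inv = np.linalg.inv(X_full.T @ X_full)
    n_pairs = G * (G - 1) // 2
    posthoc = {}
    for i in range(G):
        for j in range(i + 1, G):
            contrast = np.zeros(X_full.shape[1])
            if i > 0:
                contrast[i] = 1.0
            if j > 0:
                contrast[j] -= 1.0
            diff = adj[labels[i]] - adj[labels[j]]
            se = np.sqrt(sigma2 * contrast @ XtX_inv @ contrast)
            t = diff / se
            p_pair = 2 * sps.t.sf(abs(t), df=df_resid)
            posthoc[(labels[i], labels[j])] = float(min(1.0, p_pair * n_pairs))

    return AncovaResult(
        F=float(F), p=p, df_group=df_group, df_resid=df_resid,
        adjusted_means=adj,
        covariate_coefs={name: float(beta_full[G + i])
                         for i, name in enumerate(cov_names)},
        posthoc_p=posthoc,
    )


def ancova_edge_table(
    stacks: dict[str, np.ndarray],
    ages: dict[str, np.ndarray],
    sexes: dict[str, np.ndarray],
    node_labels,
    fdr_q: float = DEFAULT_FDR_Q,
) -> pd.DataFrame:
    """Edge-wise ANCOVA across groups, FDR-corrected over the edge family.

    ``stacks`` maps group -> subjects x N x N coefficient stack. Returns a
    table shaped like the published group-difference tables: per edge the
    group means +/- SD, F, p, FDR q and Bonferroni pairwise p values.
    """
    labels = list(stacks.keys())
    N = len(node_labels)
    y_all, g_all, a_all, s_all = [], [], [], []
    for g in labels:
        S = stacks[g].shape[0]
        y_all.append(stacks[g])
        g_all.append(np.repeat(g, S))
        a_all.append(np.asarray(ages[g], float))
        s_all.append(np.asarray(sexes[g], float))
    groups = np.concatenate(g_all)
    age = np.concatenate(a_all)
    sex = np.concatenate(s_all)
    coefs = np.concatenate(y_all, axis=0)

    rows = []
    for tgt in range(N):
        for src in range(N):
            if src == tgt:
                continue
            res = ancova_with_covariates(coefs[:, tgt, src], groups, age, sex)
            row = {
                "source": node_labels[src],
                "target": node_labels[tgt],
                "F": res.F,
                "p": res.p,
            }
            for g in labels:
                vals = stacks[g][:, tgt, src]
                row[f"mean_{g}"] = float(np.mean(vals))
                row[f"sd_{g}"] = float(np.std(vals, ddof=1))
            for (g1, g2), pv in res.posthoc_p.items():
                row[f"posthoc_{g1}_vs_{g2}"] = pv
            rows.append(row)
    table = pd.DataFrame(rows)
    table["q"] = _bh_q(table["p"].to_numpy())
    table["significant"] = table["q"] < fdr_q
    return table


def ancova_value_table(
    values: dict[str, np.ndarray],
    ages: dict[str, np.ndarray],
    sexes: dict[str, np.ndarray],
    names,
) -> pd.DataFrame:
    """ANCOVA per named quantity (e.g. per-network mean-Z values).

    ``values`` maps group -> subjects x len(names) array. Output rows carry
    group means +/- SD, F, p and pairwise Bonferroni p values — the layout
    of the published network-activation comparison.
    """
    labels = list(values.keys())
    groups = np.concatenate([np.repeat(g, values[g].shape[0]) for g in labels])
    age = np.concatenate([np.asarray(ages[g], float) for g in labels])
    sex = np.concatenate([np.asarray(sexes[g], float) for g in labels])
    stacked = np.concatenate([values[g] for g in labels], axis=0)
    rows = []
    for i, name in enumerate(names):
        res = ancova_with_covariates(stacked[:, i], groups, age, sex)
        row = {"name": name, "F": res.F, "p": res.p}
        for g in labels:
            v = values[g][:, i]
            row[f"mean_{g}"] = float(np.mean(v))
            row[f"sd_{g}"] = float(np.std(v, ddof=1))
        for (g1, g2), pv in res.posthoc_p.items():
            row[f"posthoc_{g1}_vs_{g2}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
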