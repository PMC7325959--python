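"""Causal-flow degree metrics on effective-connectivity patterns.

A pattern is the directed signed graph of edges whose group-mean path
coefficient is significantly nonzero. Degrees count those edges: in-degree
is the number of causal connections *into* a node (central targets have
many), out-degree the number *out of* it (central sources), and a hub is a
node whose in+out degree is at least one standard deviation above the mean
across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EffectiveConnectivityPattern:
    """Directed signed binary graph over the network nodes.

    ``edges`` maps (source, target) -> sign in {-1, +1}; self edges are
    disallowed.
    """

    node_labels: tuple[str, ...]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    group: str = ""

    def __post_init__(self):
        self.node_labels = tuple(self.node_labels)
        labels = set(self.node_labels)
        for (src, tgt), sign in self.edges.items():
            if src == tgt:
                raise ValueError(f"self edge {src}->{tgt} not allowed")
            if src not in labels or tgt not in labels:
                raise ValueError(f"edge {src}->{tgt} uses unknown node(s)")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be -1 or +1, got {sign}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sign_matrix(self) -> pd.DataFrame:
        """{-1, 0, +1} matrix in the column-causes-row orientation."""
        n = len(self.node_labels)
        M = np.zeros((n, n), dtype=int)
        idx = {lab: i for i, lab in enumerate(self.node_labels)}
        for (src, tgt), sign in self.edges.items():
            M[idx[tgt], idx[src]] = sign
        return pd.DataFrame(M, index=self.node_labels, columns=self.node_labels)

    @classmethod
    def from_sign_matrix(cls, frame: pd.DataFrame,
                         group: str = "") -> "EffectiveConnectivityPattern":
        labels = tuple(frame.columns)
        edges = {}
        for tgt in labels:
            for src in labels:
                v = int(frame.loc[tgt, src])
                if v != 0 and src != tgt:
                    edges[(src, tgt)] = 1 if v > 0 else -1
        return cls(node_labels=labels, edges=edges, group=group)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        for (src, tgt), sign in self.edges.items():
            g.add_edge(src, tgt, sign=sign)
        return g


@dataclass
class DegreeProfile:
    """Per-node causal-flow degrees plus node-role classification."""

    node_labels: tuple[str, ...]
    in_degree: np.ndarray
    out_degree: np.ndarray
    mean_in_plus_out: float
    sd_in_plus_out: float
    hubs: list[str]
    central_sources: list[str]
    central_targets: list[str]
    degenerate: bool = False

    @property
    def in_plus_out(self) -> np.ndarray:
        return self.in_degree + self.out_degree

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.node_labels),
                "in_degree": self.in_degree,
                "out_degree": self.out_degree,
                "in_plus_out": self.in_plus_out,
                "hub": [lab in self.hubs for lab in self.node_labels],
                "central_source": [lab in self.central_sources
                                   for lab in self.node_labels],
                "central_target": [lab in self.central_targets
                                   for lab in self.node_labels],
            }
        )


def degree_profile(pattern: EffectiveConnectivityPattern) -> DegreeProfile:
    """Count in/out/in+out degrees and classify hubs, sources and targets.

    The spread of in+out degree is the sample standard deviation (divisor
    N-1) across the N nodes. An empty pattern is legal and yields all-zero
    degrees.
    """
    labels = pattern.node_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    ind = np.zeros(n, dtype=int)
    outd = np.zeros(n, dtype=int)
    for (src, tgt) in pattern.edges:
        outd[idx[src]] += 1
        ind[idx[tgt]] += 1
    total = ind + outd
    mean = float(total.mean()) if n else 0.0
    sd = float(total.std(ddof=1)) if n > 1 else 0.0
    profile = DegreeProfile(
        node_labels=labels,
        in_degree=ind,
        out_degree=outd,
        mean_in_plus_out=mean,
        sd_in_plus_out=sd,
        hubs=[], central_sources=[], central_targets=[],
    )
    hubs, sources, targets, degenerate = classify_nodes(profile)
    profile.hubs = hubs
    profile.central_sources = sources
    profile.central_targets = targets
    profile.degenerate = degenerate
    return profile


def classify_nodes(profile: DegreeProfile):
    """Hubs, central sources and central targets from a degree profile.

    Hubs: in+out degree >= mean + 1 SD ("at least one SD above average").
    Central sources: node(s) with maximal out-degree; central targets:
    maximal in-degree; ties keep all tied nodes. When the SD is zero every
    node trivially meets the hub rule; the profile is flagged degenerate.

    Returns (hubs, central_sources, central_targets, degenerate).
    """
    labels = profile.node_labels
    total = profile.in_degree + profile.out_degree
    cut = profile.mean_in_plus_out + profile.sd_in_plus_out
    hubs = [lab for lab, t in zip(labels, total) if t >= cut]
    if total.sum() == 0:
        hubs = []  # an empty graph has no hubs, whatever the rule says
    max_out = profile.out_degree.max() if len(labels) else 0
    max_in = profile.in_degree.max() if len(labels) else 0
    sources = [lab for lab, d in zip(labels, profile.out_degree)
               if d == max_out and max_out > 0]
    targets = [lab for lab, d in zip(labels, profile.in_degree)
               if d == max_in and max_in > 0]
    degenerate = bool(profile.sd_in_plus_out == 0 and total.sum() > 0)
    return hubs, sources, targets, degenerate


def degree_table(profiles: dict[str, DegreeProfile]) -> pd.DataFrame:
    """Stack per-group degree profiles into one long table (the bar-chart
    layout: in, out and in+out per node per group)."""
    frames = []
    for group, prof in profiles.items():
        f = prof.to_frame()
        f.insert(0, "group", group)
        f["mean_in_plus_out"] = prof.mean_in_plus_out
        f["sd_in_plus_out"] = prof.sd_in_plus_out
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
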