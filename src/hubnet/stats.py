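"""Group-level statistics on thresholded connectivity networks.

Three analyses:

* **Degree-centrality comparison** — per region and per density, a one-tailed
  two-sample t-test of group A > group B on degree centrality (the number of
  edges at a node in binary mode, or the summed |z| weight in weighted mode),
  at uncorrected alpha 0.05 across a band of low densities (1–12% by
  default).  An exploratory variant reports both tails.
* **Group connectivity** — for a node of interest (NOI), the fraction of each
  group's subjects whose binary network contains the edge to every other
  region: the inter-subject consistency of a connection.
* **Edge–behavior regression** — per group, the Pearson correlation between a
  designated edge's continuous |z| weight (pre-thresholding) and a
  per-subject behavioural score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .network import ConnectivityMatrix, ThresholdedNetwork

__all__ = [
    "DegreePanel",
    "GroupStatsResult",
    "GroupConnectivityMap",
    "degree_centrality",
    "build_degree_panel",
    "compare_groups_dc",
    "group_connectivity",
    "edge_behavior_regression",
]


def degree_centrality(net: ThresholdedNetwork) -> np.ndarray:
    """Per-region degree centrality of one network.

    Binary mode counts incident edges; weighted mode sums incident retained
    |z| weights.
    """
    dc = np.zeros(net.n_regions)
    if net.mode == "binary" or net.weights_retained is None:
        for i, j in net.edges:
            dc[i] += 1
            dc[j] += 1
    else:
        for (i, j), w in net.weights_retained.items():
            dc[i] += w
            dc[j] += w
    return dc


@dataclass
class DegreePanel:
    """Subjects × regions × densities table of degree centrality."""

    values: np.ndarray  # (n_subjects, n_regions, n_densities)
    subject_ids: list[str]
    group_labels: np.ndarray  # array of "A"/"B", one per subject
    region_labels: list[str]
    densities: list[float]
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        s, r, d = self.values.shape
        if s != len(self.subject_ids) or s != len(self.group_labels):
            raise ValueError("subject dimension mismatch")
        if r != len(self.region_labels) or d != len(self.densities):
            raise ValueError("region/density dimension mismatch")
        if self.mode == "binary" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("binary-mode degrees must be integers")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject, group, region, density, dc."""
        s, r, d = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subject_ids, self.region_labels, self.densities],
            names=["subject", "region", "density"],
        )
        frame = pd.DataFrame({"dc": self.values.reshape(-1)}, index=idx).reset_index()
        groups = dict(zip(self.subject_ids, self.group_labels))
        frame.insert(1, "group", frame["subject"].map(groups))
        return frame


def build_degree_panel(
    networks: Mapping[str, Sequence[ThresholdedNetwork]],
    group_labels: Mapping[str, str],
    mode: str = "binary",
    region_labels: Sequence[str] | None = None,
) -> DegreePanel:
    """Assemble a DegreePanel from per-subject density sweeps.

    ``networks`` maps subject id → list of ThresholdedNetwork (same densities
    for every subject).  Binary degrees are computed on the edge sets
    regardless of the stored mode; weighted degrees use retained weights.
    """
    from .network import binarize

    subject_ids = list(networks)
    first = networks[subject_ids[0]]
    densities = [net.density for net in first]
    values = np.zeros((len(subject_ids), first[0].n_regions, len(densities)))
    for si, sid in enumerate(subject_ids):
        sweep = networks[sid]
        if [n.density for n in sweep] != densities:
            raise ValueError(f"subject {sid} has a different density grid")
        for di, net in enumerate(sweep):
            use = binarize(net) if (mode == "binary" and net.mode != "binary") else net
            values[si, :, di] = degree_centrality(use)
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(first[0].n_regions)]
    return DegreePanel(
        values=values,
        subject_ids=subject_ids,
        group_labels=np.array([group_labels[s] for s in subject_ids]),
        region_labels=list(region_labels),
        densities=densities,
        mode=mode,
    )


@dataclass
class GroupStatsResult:
    """Per-(region, density) t statistics for the group DC comparison."""

    table: pd.DataFrame  # region, density, t, p_greater, p_less, flags
    alpha: float = 0.05
    tail: str = "greater"
    noi_labels: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        col = "sig_greater" if self.tail != "less" else "sig_less"
        return self.table[self.table[col]]


def compare_groups_dc(
    panel: DegreePanel,
    densities: Sequence[float] | None = None,
    regions: Sequence[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    fdr: bool = False,
) -> GroupStatsResult:
    """Two-sample t-tests of degree centrality, group A versus group B.

    The confirmatory direction is one-tailed A > B (``p_greater``); the
    opposite tail (``p_less``) is reported alongside for exploratory use.
    Pooled-variance Student's t by default; ``equal_var=False`` switches to
    Welch.  ``fdr=True`` adds Benjamini–Hochberg-adjusted columns (off by
    default: the analysis is uncorrected across nodes and densities).
    """
    a_mask = panel.group_labels == "A"
    b_mask = panel.group_labels == "B"
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    dens = list(densities) if densities is not None else panel.densities
    regs = list(regions) if regions is not None else panel.region_labels
    d_idx = [panel.densities.index(d) for d in dens]
    r_idx = [panel.region_labels.index(r) for r in regs]

    sub = panel.values[np.ix_(np.arange(len(panel.subject_ids)), r_idx, d_idx)]
    a, b = sub[a_mask], sub[b_mask]
    with warnings.catch_warnings():
        # near-constant degree vectors (e.g. backbone-only densities) trip a
        # precision warning inside scipy; the degenerate cells are repaired below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sst.ttest_ind(a, b, axis=0, equal_var=equal_var, alternative="greater")
    t, p_greater = np.asarray(res.statistic), np.asarray(res.pvalue)
    # zero pooled variance with equal means: no evidence either way
    degenerate = ~np.isfinite(t)
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    t = np.where(degenerate & (mean_diff == 0), 0.0, t)
    p_greater = np.where(degenerate & (mean_diff == 0), 0.5, p_greater)
    p_less = 1.0 - p_greater

    rows = []
    for ri, r in enumerate(regs):
        for di, d in enumerate(dens):
            rows.append((r, d, t[ri, di], p_greater[ri, di], p_less[ri, di]))
    table = pd.DataFrame(rows, columns=["region", "density", "t", "p_greater", "p_less"])
    table["sig_greater"] = table["p_greater"] < alpha
    table["sig_less"] = table["p_less"] < alpha
    if fdr:
        table["q_greater"] = sst.false_discovery_control(table["p_greater"])
        table["sig_greater_fdr"] = table["q_greater"] < alpha
    return GroupStatsResult(table=table, alpha=alpha, noi_labels=regs)


@dataclass
class GroupConnectivityMap:
    """Inter-subject edge consistency with one node of interest."""

    noi: str
    table: pd.DataFrame  # region, group, fraction, count, n
    density_used: float
    display_threshold: float = 0.10

    def displayed(self) -> pd.DataFrame:
        """Rows passing the display filter (group connectivity > 10%)."""
        return self.table[self.table["fraction"] > self.display_threshold]


def group_connectivity(
    networks: Mapping[str, ThresholdedNetwork],
    noi: str,
    group_labels: Mapping[str, str],
    region_labels: Sequence[str],
    density: float | None = None,
) -> GroupConnectivityMap:
    """Fraction of subjects, per group, whose binary network has each NOI edge.

    All networks must share one density and be binary (or are counted on
    their edge sets, which is the binary reading).  Fractions are exact
    rationals count/n; per-group panels plus a pooled "all" panel are
    emitted, since the inter-subject consistency can be read either way.
    """
    ids = list(networks)
    dens = {round(networks[s].density, 6) for s in ids}
    if len(dens) != 1:
        raise ValueError(f"networks mix densities: {sorted(dens)}")
    density = density if density is not None else networks[ids[0]].density
    labels = list(region_labels)
    noi_idx = labels.index(noi)
    n_regions = networks[ids[0]].n_regions

    counts: dict[str, np.ndarray] = {
        "A": np.zeros(n_regions, dtype=int),
        "B": np.zeros(n_regions, dtype=int),
        "all": np.zeros(n_regions, dtype=int),
    }
    sizes = {"A": 0, "B": 0, "all": 0}
    for sid in ids:
        g = group_labels[sid]
        sizes[g] += 1
        sizes["all"] += 1
        for i, j in networks[sid].edges:
            other = j if i == noi_idx else (i if j == noi_idx else None)
            if other is not None:
                counts[g][other] += 1
                counts["all"][other] += 1
    rows = []
    for g in ("A", "B", "all"):
        n = sizes[g]
        for r in range(n_regions):
            if r == noi_idx:
                continue
            rows.append((labels[r], g, counts[g][r] / n if n else np.nan, counts[g][r], n))
    table = pd.DataFrame(rows, columns=["region", "group", "fraction", "count", "n"])
    return GroupConnectivityMap(noi=noi, table=table, density_used=density)


def edge_behavior_regression(
    cms: Mapping[str, ConnectivityMatrix],
    edges: Sequence[tuple[str, str]],
    scores: Mapping[str, float],
    group_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Pearson correlation of continuous edge weight against behaviour score.

    Operates on the pre-threshold |z| weights, per group and per edge;
    two-sided p-values, the sign of r carrying the direction.  Raises if any
    subject lacks a score.
    """
    ids = list(cms)
    missing = [s for s in ids if s not in scores]
    if missing:
        raise KeyError(f"missing behaviour scores for subjects: {missing}")
    labels = cms[ids[0]].region_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    rows = []
    for la, lb in edges:
        a, b = idx[la], idx[lb]
        for g in sorted(set(group_labels[s] for s in ids)):
            members = [s for s in ids if group_labels[s] == g]
            if len(members) < 3:
                raise ValueError(f"group {g} has fewer than 3 subjects")
            w = np.array([cms[s].edge_weight(a, b) for s in members])
            y = np.array([scores[s] for s in members])
            r, p = sst.pearsonr(w, y)
            rows.append((f"{la}-{lb}", g, float(r), float(p), len(members)))
    return pd.DataFrame(rows, columns=["edge", "group", "r", "p", "n"])
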