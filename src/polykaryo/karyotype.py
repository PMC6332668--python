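"""High-resolution molecular karyotyping from pairwise marker association.

Every pair of single-dose marker alleles is tested for deviation from the
1:1:1:1 joint presence/absence ratio expected of independently segregating
simplex alleles, with a two-sided Fisher exact test.  Marker pairs in
*coupling* (odds ratio > 1) sit on the same homolog; pairs in *repulsion*
(odds ratio < 1) sit on different homologs of the same chromosome, whose
alleles are anti-transmitted through shared bivalents.  Aggregating the
tiered significance pattern over linkage-group pairs yields a molecular
karyotype: homolog groups, per-chromosome homolog counts (aneuploidy when
the count deviates from the expected copy number), and detection of
preferentially pairing homolog pairs (subgenome differentiation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

COUPLING = "coupling"
REPULSION = "repulsion"
NONE = "none"

COUPLED = "coupled"
REPULSED = "repulsed"
NEUTRAL = "neutral"

PREFERENTIAL = "preferential"
RANDOM = "random"
UNTESTABLE = "untestable"


@dataclass
class KaryotypeConfig:
    #: strictly decreasing significance tiers (light, medium, dark)
    tiers: Tuple[float, float, float] = (0.05, 0.001, 1e-5)
    #: fraction of marker pairs that must be significant for a group-pair call
    majority_fraction: float = 0.5
    lod_threshold: float = 7.0
    min_complete: int = 10
    min_markers_per_group: int = 2
    #: group pairs with fewer marker pairs than this stay neutral (a single
    #: significant marker pair is not evidence about two whole groups)
    min_pairs_for_call: int = 4

    def __post_init__(self) -> None:
        if not all(a > b for a, b in zip(self.tiers, self.tiers[1:])):
            raise ValueError("significance tiers must be strictly decreasing")


@lru_cache(maxsize=None)
def _fisher_p_canonical(key: Tuple[int, int, int, int]) -> float:
    a, b, c, d = key
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_p(n11: int, n10: int, n01: int, n00: int) -> float:
    """Two-sided Fisher exact p for a 2x2 presence/absence table (cached;
    the p-value is invariant under the table's row/column symmetries)."""
    a, b, c, d = int(n11), int(n10), int(n01), int(n00)
    key = min(
        (a, b, c, d), (b, a, d, c), (c, d, a, b), (d, c, b, a),
        (a, c, b, d), (c, a, d, b), (b, d, a, c), (d, b, c, a),
    )
    return _fisher_p_canonical(key)


@dataclass
class PairCounts:
    """2x2 joint presence/absence contingency for one marker pair."""

    n11: int
    n10: int
    n01: int
    n00: int
    fisher_p: float
    direction: str  #: coupling / repulsion / none

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def _direction(n11: int, n10: int, n01: int, n00: int) -> str:
    # Haldane-Anscombe 0.5 offset handles zero cells, for direction only
    num = (n11 + 0.5) * (n00 + 0.5)
    den = (n10 + 0.5) * (n01 + 0.5)
    if num > den:
        return COUPLING
    if num < den:
        return REPULSION
    return NONE


def pairwise_association(
    presence_a: np.ndarray,
    presence_b: np.ndarray,
    min_complete: int = 10,
) -> Optional[PairCounts]:
    """Fisher exact association of two presence vectors (1/0, -1 missing)
    over pairwise-complete individuals; ``None`` when fewer than
    ``min_complete`` complete cases are available."""
    a = np.asarray(presence_a)
    b = np.asarray(presence_b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size < min_complete:
        return None
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    return PairCounts(n11, n10, n01, n00,
                      fisher_p=fisher_p(n11, n10, n01, n00),
                      direction=_direction(n11, n10, n01, n00))


def joint_counts(presence: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs 2x2 cell counts for a (markers, individuals) presence matrix."""
    p = np.atleast_2d(presence)
    x1 = (p == 1).astype(np.float64)
    x0 = (p == 0).astype(np.float64)
    n11 = x1 @ x1.T
    n10 = x1 @ x0.T
    n01 = x0 @ x1.T
    n00 = x0 @ x0.T
    return (n11.astype(np.int64), n10.astype(np.int64),
            n01.astype(np.int64), n00.astype(np.int64))


# ---------------------------------------------------------------------------
# Two-point coupling-phase grouping
# ---------------------------------------------------------------------------

def pair_lod(n11: int, n10: int, n01: int, n00: int) -> Tuple[float, float]:
    """Coupling-phase two-point LOD and recombination estimate for dominant
    markers: r_hat = discordant fraction, LOD = (n11 + n00) log10 2(1-r) +
    (n10 + n01) log10 2r, with r_hat clipped to [1e-6, 0.5]."""
    n = n11 + n10 + n01 + n00
    if n == 0:
        return 0.0, 0.5
    r_hat = float(np.clip((n10 + n01) / n, 1e-6, 0.5))
    lod = (n11 + n00) * np.log10(2 * (1 - r_hat)) + (n10 + n01) * np.log10(2 * r_hat)
    return float(lod), r_hat


def two_point_grouping(
    presence: np.ndarray,
    config: Optional[KaryotypeConfig] = None,
) -> np.ndarray:
    """Single-linkage coupling-phase linkage groups at the LOD threshold.

    Returns an integer group label per marker.  Only coupling-direction
    edges are used; repulsion-phase linkage is deliberately ignored because
    its expectation depends on the (unknown) inheritance model.
    """
    config = config or KaryotypeConfig()
    n11, n10, n01, n00 = joint_counts(presence)
    n = n11 + n10 + n01 + n00
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.clip(np.divide(n10 + n01, n, out=np.full(n.shape, 0.5),
                                  where=n > 0), 1e-6, 0.5)
    lod = (n11 + n00) * np.log10(2 * (1 - r_hat)) + (n10 + n01) * np.log10(2 * r_hat)
    coupling = (n11 + 0.5) * (n00 + 0.5) > (n10 + 0.5) * (n01 + 0.5)
    adj = (lod >= config.lod_threshold) & coupling & (n >= config.min_complete)
    np.fill_diagonal(adj, False)
    from scipy.sparse import csgraph, csr_matrix
    n_comp, labels = csgraph.connected_components(csr_matrix(adj), directed=False)
    return labels


# ---------------------------------------------------------------------------
# Karyotype aggregation
# ---------------------------------------------------------------------------

@dataclass
class GroupPairStats:
    """Tiered Fisher-test summary over all marker pairs of two linkage groups."""

    group_a: Hashable
    group_b: Hashable
    n_marker_pairs: int
    n_skipped: int
    #: fraction of marker pairs significant at each tier, by direction
    frac_coupling: Tuple[float, ...]
    frac_repulsion: Tuple[float, ...]
    median_p: float
    call: str  #: coupled / repulsed / neutral


@dataclass
class KaryotypeReport:
    group_ids: List[Hashable]
    group_sizes: Dict[Hashable, int]
    pair_stats: Dict[Tuple[Hashable, Hashable], GroupPairStats]
    marker_groups: np.ndarray
    signed_p: np.ndarray  #: (m, m) +p coupling / -p repulsion / nan skipped
    config: KaryotypeConfig

    def stats(self, ga: Hashable, gb: Hashable) -> GroupPairStats:
        key = (ga, gb) if (ga, gb) in self.pair_stats else (gb, ga)
        return self.pair_stats[key]

    def to_json_dict(self) -> dict:
        return {
            "tiers": list(self.config.tiers),
            "groups": [
                {"id": str(g), "n_markers": int(self.group_sizes[g])}
                for g in self.group_ids
            ],
            "group_pairs": [
                {
                    "group_a": str(s.group_a),
                    "group_b": str(s.group_b),
                    "n_marker_pairs": s.n_marker_pairs,
                    "n_skipped": s.n_skipped,
                    "frac_coupling": list(s.frac_coupling),
                    "frac_repulsion": list(s.frac_repulsion),
                    "median_p": s.median_p,
                    "call": s.call,
                }
                for s in self.pair_stats.values()
            ],
        }


def aggregate_karyotype(
    presence: np.ndarray,
    group_labels: Sequence[Hashable],
    config: Optional[KaryotypeConfig] = None,
) -> KaryotypeReport:
    """Tier every marker-pair Fisher test and call each linkage-group pair.

    A group pair is called coupled (or repulsed) when more than
    ``majority_fraction`` of its marker pairs are significant at the
    outermost tier in that direction; otherwise neutral.  Self pairs are
    included (a group against itself is expected coupled).
    """
    config = config or KaryotypeConfig()
    p = np.atleast_2d(presence)
    labels = np.asarray(group_labels)
    m = p.shape[0]
    if labels.shape[0] != m:
        raise ValueError("one group label per marker required")
    n11, n10, n01, n00 = joint_counts(p)
    n = n11 + n10 + n01 + n00
    signed = np.full((m, m), np.nan)
    for i in range(m):
        signed[i, i] = fisher_p(int(n11[i, i]), 0, 0, int(n00[i, i]))
        for j in range(i + 1, m):
            if n[i, j] < config.min_complete:
                continue
            pv = fisher_p(int(n11[i, j]), int(n10[i, j]), int(n01[i, j]), int(n00[i, j]))
            d = _direction(int(n11[i, j]), int(n10[i, j]), int(n01[i, j]), int(n00[i, j]))
            signed[i, j] = signed[j, i] = -pv if d == REPULSION else pv

    group_ids = list(dict.fromkeys(labels.tolist()))
    sizes = {g: int((labels == g).sum()) for g in group_ids}
    tiers = config.tiers
    pair_stats: Dict[Tuple[Hashable, Hashable], GroupPairStats] = {}
    for ai, ga in enumerate(group_ids):
        ia = np.where(labels == ga)[0]
        for gb in group_ids[ai:]:
            ib = np.where(labels == gb)[0]
            block = signed[np.ix_(ia, ib)]
            if ga == gb:
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            finite = vals[np.isfinite(vals)]
            n_pairs = finite.size
            n_skipped = vals.size - n_pairs
            if n_pairs:
                absp = np.abs(finite)
                coup = finite > 0
                frac_c = tuple(float(((absp < t) & coup).mean()) for t in tiers)
                frac_r = tuple(float(((absp < t) & ~coup).mean()) for t in tiers)
                median_p = float(np.median(absp))
            else:
                frac_c = frac_r = (0.0,) * len(tiers)
                median_p = float("nan")
            maj = config.majority_fraction
            enough = n_pairs >= config.min_pairs_for_call
            if enough and frac_c[0] > maj and frac_c[0] >= frac_r[0]:
                call = COUPLED
            elif enough and frac_r[0] > maj:
                call = REPULSED
            else:
                call = NEUTRAL
            pair_stats[(ga, gb)] = GroupPairStats(
                group_a=ga, group_b=gb, n_marker_pairs=n_pairs,
                n_skipped=int(n_skipped), frac_coupling=frac_c,
                frac_repulsion=frac_r, median_p=median_p, call=call,
            )
    return KaryotypeReport(group_ids=group_ids, group_sizes=sizes,
                           pair_stats=pair_stats, marker_groups=labels,
                           signed_p=signed, config=config)


# ---------------------------------------------------------------------------
# Homolog clustering and pairing classification
# ---------------------------------------------------------------------------

@dataclass
class HomologComponent:
    groups: List[Hashable]
    homolog_count: int
    singleton: bool = False  #: group with no edges; flagged


def cluster_homologs(
    report: KaryotypeReport,
    dda_shared: Optional[Mapping[Tuple[Hashable, Hashable], int]] = None,
    min_shared_dda: int = 2,
) -> List[HomologComponent]:
    """Connected components over repulsion and shared-DDA edges = chromosomes.

    Nodes are linkage groups; edges join group pairs repulsed at the middle
    significance tier plus group pairs sharing at least ``min_shared_dda``
    duplex markers.  (Outer-tier repulsion is too easily reached by one
    chance correlation between two blocks of mutually linked markers, while
    homologs that genuinely anti-transmit -- preferential pairs,
    near-complete coupling groups -- repulse at the middle tier.)  Each
    component collects the homologs of one base chromosome, so the
    component size is the chromosome's homolog count (aneuploidy when it
    deviates from the expected copy number).
    """
    cfg = report.config
    g = nx.Graph()
    g.add_nodes_from(report.group_ids)
    for (ga, gb), s in report.pair_stats.items():
        if (ga != gb and s.n_marker_pairs >= cfg.min_pairs_for_call
                and s.frac_repulsion[1] > cfg.majority_fraction):
            g.add_edge(ga, gb)
    if dda_shared:
        for (ga, gb), count in dda_shared.items():
            if ga != gb and count >= min_shared_dda:
                g.add_edge(ga, gb)
    comps = []
    for nodes in nx.connected_components(g):
        ordered = sorted(nodes, key=lambda x: report.group_ids.index(x))
        comps.append(HomologComponent(groups=ordered, homolog_count=len(ordered),
                                      singleton=len(ordered) == 1))
    comps.sort(key=lambda c: report.group_ids.index(c.groups[0]))
    return comps


def dda_pair_counts(assignments: Sequence) -> Dict[Tuple[Hashable, Hashable], int]:
    """Tally unambiguous DDA assignments per linkage-group pair."""
    counts: Dict[Tuple[Hashable, Hashable], int] = {}
    for a in assignments:
        if a.pair is not None:
            counts[a.pair] = counts.get(a.pair, 0) + 1
    return counts


def classify_pairing(
    component: Sequence[Hashable],
    report: KaryotypeReport,
    config: Optional[KaryotypeConfig] = None,
) -> Dict[Tuple[Hashable, Hashable], str]:
    """Classify each homolog pair of one chromosome as random or preferential.

    A pair is preferential when it is repulsed at the middle significance
    tier (majority of marker pairs with p below the middle tier in
    repulsion) while each member shows no middle-tier repulsion against any
    other member of the component -- the signature of two homologs that
    preferentially form a bivalent with each other.  Pairs involving a
    group with fewer markers than ``min_markers_per_group`` are untestable.
    """
    config = config or report.config
    groups = list(component)
    if len(groups) < 2:
        return {}
    maj = config.majority_fraction

    def middle_repulsed(ga: Hashable, gb: Hashable) -> bool:
        s = report.stats(ga, gb)
        return (s.n_marker_pairs >= config.min_pairs_for_call
                and s.frac_repulsion[1] > maj)

    out: Dict[Tuple[Hashable, Hashable], str] = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            key = (ga, gb)
            if (report.group_sizes[ga] < config.min_markers_per_group
                    or report.group_sizes[gb] < config.min_markers_per_group):
                out[key] = UNTESTABLE
                continue
            if not middle_repulsed(ga, gb):
                out[key] = RANDOM
                continue
            clean = all(
                not middle_repulsed(g, other)
                for g in (ga, gb)
                for other in groups
                if other not in (ga, gb)
            )
            out[key] = PREFERENTIAL if clean else RANDOM
    return out


def plot_heat_matrix(report: KaryotypeReport, path: str) -> None:
    """Render the signed-p marker matrix as the conventional tiered heatmap
    (blues = repulsion/segregation, warm colours = coupling/linkage)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    t1, t2, t3 = report.config.tiers
    signed = report.signed_p
    # encode: -3..-1 repulsion tiers, 0 neutral, 1..3 coupling tiers
    code = np.zeros(signed.shape)
    absp = np.abs(signed)
    for level, t in enumerate((t1, t2, t3), start=1):
        code[(absp < t) & (signed > 0)] = level
        code[(absp < t) & (signed < 0)] = -level
    code[~np.isfinite(signed)] = np.nan
    cmap = ListedColormap(
        ["#08306b", "#2171b5", "#9ecae1", "#f7f7f7", "#ffff66", "#ff9933", "#cc0000"])
    norm = BoundaryNorm(np.arange(-3.5, 4.0), cmap.N)
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(code, cmap=cmap, norm=norm, interpolation="nearest")
    fig.colorbar(im, ax=ax, ticks=range(-3, 4),
                 label="repulsion tier  <-  ->  coupling tier")
    ax.set_xlabel("marker index (grouped)")
    ax.set_ylabel("marker index (grouped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
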