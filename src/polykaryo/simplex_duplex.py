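"""Simplex-duplex (SDA-DDA) coupling model for polysomic inheritance.

A single-dose allele (SDA, simplex) sits on one homolog of a polysomic
parent; a double-dose allele (DDA, duplex) sits on two.  When an SDA marker
``A`` and a DDA marker ``B`` are linked in coupling (``A`` on one of the two
``B``-carrier homologs), the F1 progeny fall into four observable classes --
both alleles present (AB), only the SDA (A), only the DDA (B), or neither
(0) -- whose expected frequencies are closed-form functions of the
recombination fraction ``r`` and of the inheritance model:

====== ===================== =====================
class  tetrasomic (4 homol.) hexasomic (6 homol.)
====== ===================== =====================
AB     1/2 - r/6             1/2 - r/5
A      r/6                   r/5
B      1/3 + r/6             3/10 + r/5
0      1/6 - r/6             1/5 - r/5
====== ===================== =====================

This module provides those closed forms, an exhaustive enumeration oracle
over bivalent pairings that reproduces them, a Pearson independence test
against the ``r = 0.5`` expectations, maximum-likelihood estimation of
``r``, assignment of DDA markers to homolog-group pairs, and the
subgenome-uniformity test for detecting differentiated subgenomes from the
distribution of DDA linkages over homolog pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

Model = str  # "tetrasomic" | "hexasomic"

_MODELS = ("tetrasomic", "hexasomic")

#: number of homologous chromosomes assumed by each inheritance model
MODEL_PLOIDY = {"tetrasomic": 4, "hexasomic": 6}


def _check_model(model: Model) -> None:
    if model not in _MODELS:
        raise ValueError(f"unknown inheritance model {model!r}; expected one of {_MODELS}")


def _check_r(r: float) -> None:
    if not (0.0 <= r <= 0.5):
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {r}")


def expected_class_freqs(r: float, model: Model) -> Tuple[float, float, float, float]:
    """Closed-form class probabilities (P_AB, P_A, P_B, P_0) for a coupling
    SDA-DDA pair at recombination fraction ``r``.

    Parameters
    ----------
    r : float
        Recombination fraction between the SDA and DDA loci, in [0, 0.5].
    model : {"tetrasomic", "hexasomic"}
        Random bivalent assortment among 4 or 6 homologs.
    """
    _check_model(model)
    _check_r(r)
    if model == "tetrasomic":
        return (0.5 - r / 6, r / 6, 1 / 3 + r / 6, 1 / 6 - r / 6)
    return (0.5 - r / 5, r / 5, 0.3 + r / 5, 0.2 - r / 5)


def class_prob_matrix(r: np.ndarray, model: Model) -> np.ndarray:
    """Vectorised ``expected_class_freqs``: shape ``(len(r), 4)``."""
    _check_model(model)
    r = np.asarray(r, dtype=float)
    if model == "tetrasomic":
        cols = [0.5 - r / 6, r / 6, 1 / 3 + r / 6, 1 / 6 - r / 6]
    else:
        cols = [0.5 - r / 5, r / 5, 0.3 + r / 5, 0.2 - r / 5]
    return np.stack(cols, axis=-1)


def perfect_matchings(items: Sequence[Hashable]) -> List[List[Tuple[Hashable, Hashable]]]:
    """All perfect matchings of an even-length sequence (15 for 6 items)."""
    items = list(items)
    if len(items) % 2:
        raise ValueError("perfect matchings require an even number of items")
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for i, partner in enumerate(rest):
        remaining = rest[:i] + rest[i + 1:]
        for sub in perfect_matchings(remaining):
            out.append([(first, partner)] + sub)
    return out


def enumerate_class_freqs(r: float, model: Model) -> Tuple[float, float, float, float]:
    """Exact enumeration oracle for :func:`expected_class_freqs`.

    Construction: homolog 0 carries the SDA allele A and the DDA allele B,
    homolog 1 carries B only, the remaining homologs are null.  Bivalent
    matchings are uniform; each bivalent transmits a single strand that
    starts from either member with probability 1/2 and switches member
    between the A and B loci with probability ``r``.  The four class
    probabilities are accumulated exactly over all matchings and strand
    outcomes.
    """
    _check_model(model)
    _check_r(r)
    k = MODEL_PLOIDY[model]
    matchings = perfect_matchings(range(k))
    p_match = 1.0 / len(matchings)
    # strand outcomes for a bivalent (i, j): (source at A locus, source at B locus)
    freqs = np.zeros(4)  # AB, A, B, 0
    for matching in matchings:
        active = [bv for bv in matching if bv[0] in (0, 1) or bv[1] in (0, 1)]
        outcome_sets = []
        for (i, j) in active:
            outcome_sets.append(
                [((i, i), (1 - r) / 2), ((i, j), r / 2),
                 ((j, j), (1 - r) / 2), ((j, i), r / 2)]
            )
        for combo in itertools.product(*outcome_sets):
            p = p_match
            a_present = False
            b_present = False
            for (src_a, src_b), pr in combo:
                p *= pr
                if src_a == 0:
                    a_present = True
                if src_b in (0, 1):
                    b_present = True
            idx = 0 if (a_present and b_present) else 1 if a_present else 2 if b_present else 3
            freqs[idx] += p
    return tuple(freqs)


def enumerate_presence_ratio(
    n_homologs: int, dose: int, gamete_size: int
) -> Tuple[int, int, float]:
    """Exhaustively enumerate gamete homolog subsets and count allele presence.

    An allele placed on ``dose`` of ``n_homologs`` homologs is transmitted
    whenever the gamete's ``gamete_size``-subset of homologs contains at
    least one carrier.  Returns ``(n_present, n_absent, ratio)`` where the
    ratio is ``n_present / n_absent``.  Under random bivalent assortment the
    gamete subset is uniform over all subsets, so this reproduces the
    textbook dosage ratios: simplex 1:1, duplex 5:1 (tetrasomic, 2-of-4)
    and 4:1 (hexasomic, 3-of-6).
    """
    if not (0 < dose <= n_homologs):
        raise ValueError("dose must be in 1..n_homologs")
    carriers = set(range(dose))
    present = absent = 0
    for subset in itertools.combinations(range(n_homologs), gamete_size):
        if carriers & set(subset):
            present += 1
        else:
            absent += 1
    return present, absent, math.inf if absent == 0 else present / absent


@dataclass
class ContingencyAB:
    """Observed 4-class counts (AB, A, B, 0) for one SDA-DDA marker pair."""

    n_ab: int
    n_a: int
    n_b: int
    n_0: int
    model: Model = "hexasomic"

    def __post_init__(self) -> None:
        _check_model(self.model)
        if min(self.n_ab, self.n_a, self.n_b, self.n_0) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_ab, self.n_a, self.n_b, self.n_0], dtype=float)

    @property
    def n(self) -> int:
        return self.n_ab + self.n_a + self.n_b + self.n_0


@dataclass
class IndependenceResult:
    chi2: float
    df: int
    p_value: float
    linked: bool  #: significant with AB excess (coupling-phase linkage)
    expected: np.ndarray
    small_expected: bool = False


def independence_test(table: ContingencyAB, alpha: float = 0.05) -> IndependenceResult:
    """Pearson goodness-of-fit of the 4 classes against independent
    segregation (expected frequencies at ``r = 0.5``), df = 3.

    Linkage in coupling is declared when ``P < alpha`` *and* the AB class
    exceeds its independence expectation (one-directional, since the model
    covers coupling phase only).
    """
    n = table.n
    if n <= 0:
        raise ValueError("empty contingency table")
    expected = n * np.array(expected_class_freqs(0.5, table.model))
    chi2 = float(((table.counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=3))
    linked = p < alpha and table.n_ab > expected[0]
    return IndependenceResult(
        chi2=chi2, df=3, p_value=p, linked=linked, expected=expected,
        small_expected=bool((expected < 1).any()),
    )


@dataclass
class REstimate:
    r: float
    log_likelihood: float
    at_boundary: bool
    degenerate: bool = False


_R_LOWER = 1e-6


def _multinomial_loglik(r: np.ndarray, counts: np.ndarray, model: Model) -> np.ndarray:
    probs = class_prob_matrix(np.asarray(r), model)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(probs)
    # classes with zero counts contribute 0 even when the probability is 0
    terms = np.where(counts == 0, 0.0, terms)
    return terms.sum(axis=-1)


def estimate_r_ml(table: ContingencyAB) -> REstimate:
    """Maximum-likelihood recombination fraction for a coupling SDA-DDA pair.

    Maximises the multinomial log-likelihood of the observed class counts
    under :func:`expected_class_freqs` over ``r`` in ``[1e-6, 0.5]`` by
    bounded 1-D optimisation.
    """
    if table.n <= 0:
        raise ValueError("empty contingency table")
    counts = table.counts
    degenerate = (counts > 0).sum() <= 1
    res = optimize.minimize_scalar(
        lambda r: -_multinomial_loglik(np.array(r), counts, table.model),
        bounds=(_R_LOWER, 0.5),
        method="bounded",
        options={"xatol": 1e-8},
    )
    r_hat = float(res.x)
    ll = float(-res.fun)
    # the bounded optimiser never returns the exact bound; compare endpoints
    for bound in (_R_LOWER, 0.5):
        ll_b = float(_multinomial_loglik(np.array(bound), counts, table.model))
        if ll_b > ll:
            r_hat, ll = bound, ll_b
    at_boundary = r_hat <= _R_LOWER * 1.01 or r_hat >= 0.5 - 1e-6
    return REstimate(r=r_hat, log_likelihood=ll, at_boundary=at_boundary,
                     degenerate=degenerate)


def estimate_r_grid(table: ContingencyAB, step: float = 1e-4) -> float:
    """Grid-search oracle for :func:`estimate_r_ml` (step ``1e-4`` default)."""
    grid = np.arange(0.0, 0.5 + step / 2, step)
    grid[0] = _R_LOWER
    ll = _multinomial_loglik(grid, table.counts, table.model)
    return float(grid[int(np.argmax(ll))])


# ---------------------------------------------------------------------------
# DDA-to-homolog-pair assignment
# ---------------------------------------------------------------------------

@dataclass
class DdaAssignment:
    """Result of testing one DDA marker against SDA homolog groups."""

    dda_id: Hashable
    group_scores: Dict[Hashable, float]  #: median signed chi2 per group
    passing: List[Hashable]
    pair: Optional[Tuple[Hashable, Hashable]]
    ambiguous: bool


def _class_counts(dda: np.ndarray, sda: np.ndarray) -> Tuple[int, int, int, int]:
    ok = (dda >= 0) & (sda >= 0)
    d, s = dda[ok], sda[ok]
    n_ab = int(((d == 1) & (s == 1)).sum())
    n_a = int(((d == 0) & (s == 1)).sum())
    n_b = int(((d == 1) & (s == 0)).sum())
    n_0 = int(((d == 0) & (s == 0)).sum())
    return n_ab, n_a, n_b, n_0


def assign_dda(
    dda_presence: np.ndarray,
    sda_groups: Mapping[Hashable, np.ndarray],
    model: Model = "hexasomic",
    alpha: float = 0.05,
    dda_id: Hashable = None,
) -> DdaAssignment:
    """Assign a duplex marker to the pair of homolog groups it couples with.

    For each homolog group the coupling score is the largest, over the
    group's SDA markers, of the independence-test chi-square signed by
    direction (+ for AB excess): a duplex allele couples with the SDA
    markers *near* it on the shared homolog, so the best marker carries the
    evidence while distant markers of the same group are uninformative.
    The critical value is the ``alpha`` chi-square quantile (df 3)
    Bonferroni-corrected for the number of groups tested (the group is the
    decision unit; markers within a group are strongly correlated).  The
    marker is assigned to the top two passing groups and flagged ambiguous
    when the number of passing groups differs from two.

    Parameters
    ----------
    dda_presence : presence/absence vector over individuals (1/0, -1 missing)
    sda_groups : mapping from group id to an (n_markers, n_individuals)
        presence matrix of that group's SDA markers
    """
    crit = float(stats.chi2.isf(alpha / max(1, len(sda_groups)), df=3))
    exp_freqs = np.array(expected_class_freqs(0.5, model))
    scores: Dict[Hashable, float] = {}
    for gid, mat in sda_groups.items():
        mat = np.atleast_2d(mat)
        signed = []
        for row in mat:
            n_ab, n_a, n_b, n_0 = _class_counts(dda_presence, row)
            n = n_ab + n_a + n_b + n_0
            if n == 0:
                continue
            expected = n * exp_freqs
            obs = np.array([n_ab, n_a, n_b, n_0], dtype=float)
            chi2 = float(((obs - expected) ** 2 / expected).sum())
            signed.append(chi2 if n_ab > expected[0] else -chi2)
        scores[gid] = float(np.max(signed)) if signed else float("nan")
    passing = [g for g, s in scores.items() if np.isfinite(s) and s > crit]
    passing.sort(key=lambda g: -scores[g])
    if len(passing) == 2:
        pair = tuple(sorted(passing))
        ambiguous = False
    else:
        pair = None
        ambiguous = True
    return DdaAssignment(dda_id=dda_id, group_scores=scores, passing=passing,
                         pair=pair, ambiguous=ambiguous)


def assign_dda_bulk(
    dda_presence: np.ndarray,
    dda_models: Sequence[Model],
    sda_presence: np.ndarray,
    sda_group_labels: Sequence[Hashable],
    dda_ids: Optional[Sequence[Hashable]] = None,
    alpha: float = 0.05,
) -> List[DdaAssignment]:
    """Vectorised :func:`assign_dda` for many DDA markers at once.

    ``dda_presence`` is ``(n_dda, n_ind)`` and ``sda_presence`` is
    ``(n_sda, n_ind)``; both use codes 1/0 with -1 for missing.
    """
    dda_presence = np.atleast_2d(dda_presence)
    sda_presence = np.atleast_2d(sda_presence)
    if dda_ids is None:
        dda_ids = list(range(dda_presence.shape[0]))
    d1 = (dda_presence == 1).astype(np.float64)
    d0 = (dda_presence == 0).astype(np.float64)
    s1 = (sda_presence == 1).astype(np.float64)
    s0 = (sda_presence == 0).astype(np.float64)
    n_ab = d1 @ s1.T
    n_a = d0 @ s1.T
    n_b = d1 @ s0.T
    n_0 = d0 @ s0.T
    n = n_ab + n_a + n_b + n_0
    labels = np.asarray(sda_group_labels)
    group_ids = list(dict.fromkeys(sda_group_labels))
    crit = float(stats.chi2.isf(alpha / max(1, len(group_ids)), df=3))
    out: List[DdaAssignment] = []
    freqs_by_model = {m: np.array(expected_class_freqs(0.5, m)) for m in set(dda_models)}
    obs = np.stack([n_ab, n_a, n_b, n_0], axis=-1)  # (D, S, 4)
    for i, (did, model) in enumerate(zip(dda_ids, dda_models)):
        expected = n[i][:, None] * freqs_by_model[model][None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(n[i][:, None] > 0, (obs[i] - expected) ** 2 / expected, 0.0).sum(axis=1)
        signed = np.where(n_ab[i] > expected[:, 0], chi2, -chi2)
        signed = np.where(n[i] > 0, signed, np.nan)
        scores = {}
        for gid in group_ids:
            vals = signed[labels == gid]
            vals = vals[np.isfinite(vals)]
            scores[gid] = float(np.max(vals)) if vals.size else float("nan")
        passing = [g for g, s in scores.items() if np.isfinite(s) and s > crit]
        passing.sort(key=lambda g: -scores[g])
        if len(passing) == 2:
            pair: Optional[Tuple[Hashable, Hashable]] = tuple(sorted(passing))
            ambiguous = False
        else:
            pair, ambiguous = None, True
        out.append(DdaAssignment(dda_id=did, group_scores=scores, passing=passing,
                                 pair=pair, ambiguous=ambiguous))
    return out


# ---------------------------------------------------------------------------
# Subgenome-uniformity test
# ---------------------------------------------------------------------------

@dataclass
class UniformityResult:
    chi2: float
    df: int
    p_value: float
    total: int
    n_pairs: int
    small_sample: bool


def subgenome_uniformity_test(pair_counts: Sequence[int]) -> UniformityResult:
    """Test whether DDA linkages are distributed uniformly over homolog pairs.

    Under no subgenome differentiation, the duplex alleles of a chromosome
    are expected to be shared uniformly across all possible homolog pairs
    (15 pairs for 6 homologs, 10 for 5, 21 for 7).  Pearson chi-square
    against the uniform expectation ``total / k`` with ``k - 1`` df; a
    significant excess on a subset of pairs is the signature of
    differentiated (preferentially pairing) subgenomes.
    """
    counts = np.asarray(pair_counts, dtype=float)
    k = counts.size
    total = int(counts.sum())
    if total < 1:
        raise ValueError("at least one DDA linkage is required")
    chi2, p = stats.chisquare(counts)
    return UniformityResult(chi2=float(chi2), df=k - 1, p_value=float(p),
                            total=total, n_pairs=k, small_sample=total < k)


def n_homolog_pairs(n_homologs: int) -> int:
    return n_homologs * (n_homologs - 1) // 2
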