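"""Read-count genotype calling, marker filtering and parental imputation.

Presence/absence genotype calls from biallelic read counts with depth
thresholds appropriate for multisomic polyploids: a heterozygote requires
at least ``t_het`` reads of each allele and a minor-allele read fraction
above ``maf_min``; a homozygote requires ``t_hom`` or more reads of a
single allele with the heterozygote condition failing; anything else is
missing.  No dosage beyond the presence/absence classes is called.

Also provides the supporting population-hygiene steps: exclusion of
markers with excess missing data, imputation of a dead parent's genotype
from selfed progeny, and screening of progeny whose heterozygote-call
fraction is so inflated that sample mixing is the likely cause.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

GENOTYPE_LABELS = {MISSING: "NA", HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}


@dataclass
class CallerConfig:
    """Depth thresholds for presence/absence genotype calling.

    ``t_hom=11`` is the autotetraploid-style default; ``t_hom=17`` is the
    strict autohexaploid setting.
    """

    t_hom: int = 11
    t_het: int = 2
    maf_min: float = 0.10

    def __post_init__(self) -> None:
        if not (self.t_hom >= self.t_het >= 1):
            raise ValueError("need t_hom >= t_het >= 1")
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")


@dataclass
class FilterConfig:
    max_missing_fraction: float = 0.20
    outlier_alpha: float = 1e-10

    def __post_init__(self) -> None:
        for v in (self.max_missing_fraction, self.outlier_alpha):
            if not (0.0 < v < 1.0):
                raise ValueError("filter thresholds must lie in (0, 1)")


def call_genotypes(
    ref_reads: np.ndarray,
    alt_reads: np.ndarray,
    config: Optional[CallerConfig] = None,
) -> np.ndarray:
    """Vectorised genotype calling; returns int8 codes (MISSING/HOM_REF/HET/HOM_ALT).

    Heterozygote: both alleles with >= ``t_het`` reads and minor-allele read
    fraction > ``maf_min``.  Otherwise homozygote for the majority allele if
    it has >= ``t_hom`` reads.  Otherwise missing.
    """
    config = config or CallerConfig()
    ref = np.asarray(ref_reads)
    alt = np.asarray(alt_reads)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be nonnegative")
    total = ref + alt
    minor = np.minimum(ref, alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.divide(minor, total, out=np.zeros(total.shape, dtype=float),
                               where=total > 0)
    het = (ref >= config.t_het) & (alt >= config.t_het) & (minor_frac > config.maf_min)
    out = np.full(ref.shape, MISSING, dtype=np.int8)
    out[het] = HET
    hom_ref = ~het & (ref >= config.t_hom) & (ref >= alt)
    hom_alt = ~het & (alt >= config.t_hom) & (alt > ref)
    out[hom_ref] = HOM_REF
    out[hom_alt] = HOM_ALT
    return out


def call_genotype(ref_reads: int, alt_reads: int,
                  config: Optional[CallerConfig] = None) -> int:
    """Scalar convenience wrapper around :func:`call_genotypes`."""
    return int(call_genotypes(np.array([ref_reads]), np.array([alt_reads]), config)[0])


def filter_markers(
    genotypes: np.ndarray,
    config: Optional[FilterConfig] = None,
) -> np.ndarray:
    """Boolean retention mask: keep markers whose missing fraction is at
    most ``max_missing_fraction`` (strictly greater is excluded)."""
    config = config or FilterConfig()
    genotypes = np.atleast_2d(genotypes)
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    missing_frac = (genotypes == MISSING).mean(axis=1)
    return missing_frac <= config.max_missing_fraction


def impute_parent_from_selfs(self_genotypes: Sequence[int]) -> int:
    """Impute a parent genotype at one marker from its selfed progeny.

    Homozygous (in that state) iff all non-missing selfs are homozygous and
    identical; heterozygous iff the selfs are all heterozygous or
    segregating (mixed states); missing iff every self is missing.
    """
    calls = [g for g in self_genotypes if g != MISSING]
    if not calls:
        return MISSING
    states = set(calls)
    if states == {HOM_REF}:
        return HOM_REF
    if states == {HOM_ALT}:
        return HOM_ALT
    return HET


def impute_parent_matrix(self_genotypes: np.ndarray) -> np.ndarray:
    """Row-wise :func:`impute_parent_from_selfs` over a (markers, selfs) matrix."""
    mat = np.atleast_2d(self_genotypes)
    return np.array([impute_parent_from_selfs(row) for row in mat], dtype=np.int8)


@dataclass
class OutlierScreenResult:
    p_values: np.ndarray
    het_fraction: np.ndarray
    n_informative: np.ndarray
    excluded: np.ndarray  #: boolean mask of individuals to drop
    untestable: np.ndarray  #: too few informative markers; retained


def screen_outlier_progeny(
    sda_genotypes: np.ndarray,
    config: Optional[FilterConfig] = None,
    min_informative: int = 30,
) -> OutlierScreenResult:
    """Flag progeny with an extreme excess of heterozygote calls.

    For each individual, a two-sided exact binomial test of its
    heterozygote count against the 0.5 expectation over non-missing
    single-dose (SDA) calls; exclusion requires ``p < outlier_alpha`` *and*
    an observed heterozygote fraction above 0.5 (the direction expected
    from sample mixing).  Individuals with fewer than ``min_informative``
    calls are flagged untestable and retained.
    """
    config = config or FilterConfig()
    mat = np.atleast_2d(sda_genotypes)
    n_ind = mat.shape[1]
    p_values = np.ones(n_ind)
    het_frac = np.full(n_ind, np.nan)
    n_inf = np.zeros(n_ind, dtype=int)
    untestable = np.zeros(n_ind, dtype=bool)
    excluded = np.zeros(n_ind, dtype=bool)
    for i in range(n_ind):
        col = mat[:, i]
        calls = col[col != MISSING]
        n = calls.size
        n_inf[i] = n
        if n < min_informative:
            untestable[i] = True
            continue
        k = int((calls == HET).sum())
        het_frac[i] = k / n
        p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        p_values[i] = p
        if p < config.outlier_alpha and het_frac[i] > 0.5:
            excluded[i] = True
    return OutlierScreenResult(p_values=p_values, het_fraction=het_frac,
                               n_informative=n_inf, excluded=excluded,
                               untestable=untestable)


def presence_from_genotypes(genotypes: np.ndarray) -> np.ndarray:
    """Allele presence (1), absence (0) or missing (-1) from genotype codes."""
    geno = np.asarray(genotypes)
    out = np.full(geno.shape, -1, dtype=np.int8)
    out[(geno == HET) | (geno == HOM_ALT)] = 1
    out[geno == HOM_REF] = 0
    return out
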