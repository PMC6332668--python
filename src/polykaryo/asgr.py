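"""Reproductive-mode phenotyping and ASGR cosegregation mapping.

Apospory in Paniceae grasses is controlled by a single dominant locus, the
apospory-specific genomic region (ASGR).  Reproductive mode is scored from
cleared-pistil observations: progeny showing only reduced (Polygonum-type,
8-nucleate) embryo sacs are sexual, while any pistil with aposporous
evidence -- an unreduced Panicum-type (4-nucleate) sac or enlarged
vacuolated nucellar cells, folded into a single aposporous category here --
marks the plant apomictic.  At least ten normally developed pistils are
required for a call.  The expected 1:1 segregation of a dominant
monogenic factor is tested by chi-square, and the locus is mapped by
scanning paternal single-dose markers for perfect cosegregation with the
apomictic state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

SEXUAL = "sexual"
APOMICTIC = "apomictic"
UNDETERMINED = "undetermined"

MIN_NORMAL_PISTILS = 10


@dataclass
class PistilRecord:
    """Pistil counts for one individual.

    ``panicum`` counts pistils with any aposporous evidence (Panicum-type
    embryo sacs or enlarged vacuolated nucellar cells); ``abnormal`` counts
    degenerated/ruptured pistils, which are excluded from the evidence.
    """

    individual: object
    polygonum: int = 0
    panicum: int = 0
    multiple_sac: int = 0
    abnormal: int = 0

    def __post_init__(self) -> None:
        if min(self.polygonum, self.panicum, self.multiple_sac, self.abnormal) < 0:
            raise ValueError("pistil counts must be nonnegative")


@dataclass
class ModeCall:
    individual: object
    mode: str
    n_normal_pistils: int
    panicum_fraction: float
    abnormal_fraction: float


def classify_mode(record: PistilRecord,
                  min_normal: int = MIN_NORMAL_PISTILS) -> ModeCall:
    """Call reproductive mode from one individual's pistil record.

    Undetermined when fewer than ``min_normal`` normally developed pistils
    were scored; apomictic on any aposporous pistil; sexual otherwise.
    """
    n_normal = record.polygonum + record.panicum
    total = n_normal + record.abnormal
    if total == 0:
        raise ValueError("empty pistil record")
    panicum_frac = record.panicum / n_normal if n_normal else 0.0
    abnormal_frac = record.abnormal / total
    if n_normal < min_normal:
        mode = UNDETERMINED
    elif record.panicum > 0:
        mode = APOMICTIC
    else:
        mode = SEXUAL
    return ModeCall(individual=record.individual, mode=mode,
                    n_normal_pistils=n_normal, panicum_fraction=panicum_frac,
                    abnormal_fraction=abnormal_frac)


def test_monogenic_segregation(n_sexual: int, n_apomictic: int) -> Tuple[float, float]:
    """Chi-square goodness of fit of mode counts against the 1:1 ratio
    expected for a single dominant factor (df 1, no continuity correction)."""
    n = n_sexual + n_apomictic
    if n <= 0:
        raise ValueError("no phenotyped individuals")
    expected = n / 2.0
    chi2 = (n_sexual - expected) ** 2 / expected + (n_apomictic - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class MarkerCoseg:
    marker: object
    recombinant_count: int
    informative_n: int


@dataclass
class CosegResult:
    per_marker: List[MarkerCoseg]
    perfect_set: List[object]
    flanking: Optional[Dict[str, MarkerCoseg]] = None

    def recombinants(self, marker) -> int:
        for m in self.per_marker:
            if m.marker == marker:
                return m.recombinant_count
        raise KeyError(marker)


def cosegregation_scan(
    modes: Sequence[str],
    presence: np.ndarray,
    marker_ids: Optional[Sequence] = None,
    marker_positions: Optional[Sequence[float]] = None,
    asgr_position: Optional[float] = None,
    min_informative: int = 50,
) -> CosegResult:
    """Scan markers for cosegregation with the apomictic state.

    For each marker the recombinant count is the number of mismatches
    between allele presence and apomixis over phenotyped individuals with a
    non-missing call; undetermined individuals are excluded.  The perfect-
    linkage set collects markers with zero recombinants and at least
    ``min_informative`` informative individuals.  When map positions and an
    ASGR position are supplied, the nearest flanking minimal-recombinant
    markers on either side are reported.
    """
    modes = np.asarray(modes, dtype=object)
    pres = np.atleast_2d(presence)
    if marker_ids is None:
        marker_ids = list(range(pres.shape[0]))
    phenotyped = modes != UNDETERMINED
    if not phenotyped.any():
        raise ValueError("no phenotyped individuals")
    apo = (modes == APOMICTIC).astype(np.int8)
    per_marker: List[MarkerCoseg] = []
    perfect: List[object] = []
    for mid, row in zip(marker_ids, pres):
        informative = phenotyped & (row >= 0)
        n = int(informative.sum())
        rec = int((row[informative] != apo[informative]).sum())
        per_marker.append(MarkerCoseg(marker=mid, recombinant_count=rec,
                                      informative_n=n))
        if rec == 0 and n >= min_informative:
            perfect.append(mid)
    flanking = None
    if marker_positions is not None and asgr_position is not None:
        positions = np.asarray(marker_positions, dtype=float)
        flanking = {}
        for side, mask in (("proximal", positions < asgr_position),
                           ("distal", positions > asgr_position)):
            candidates = [(m, positions[i]) for i, m in enumerate(per_marker) if mask[i]]
            if candidates:
                best = min(candidates,
                           key=lambda t: (t[0].recombinant_count, abs(t[1] - asgr_position)))
                flanking[side] = best[0]
        flanking = flanking or None
    return CosegResult(per_marker=per_marker, perfect_set=perfect, flanking=flanking)
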