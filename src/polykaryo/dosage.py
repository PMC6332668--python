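"""Single-dose / double-dose marker classification from F1 segregation.

In a polysomic pseudo-testcross a marker heterozygous in exactly one
parent segregates by its allele dosage in that parent: a simplex marker
(single-dose allele, SDA) gives a 1:1 ratio of heterozygous to homozygous
progeny regardless of the inheritance model, while a duplex marker
(double-dose allele, DDA) gives 5:1 under tetrasomic (2-of-4 homolog
sampling) and 4:1 under hexasomic (3-of-6) inheritance.  Markers are
classified SDA when the het:hom ratio falls strictly inside the 2:1 band
around 1:1, and DDA when a chi-square goodness-of-fit (df 1, no continuity
correction) accepts 5:1 or 4:1 at the configured alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from polykaryo import calling

SDA = "SDA"
DDA_TETRASOMIC = "DDA_tetrasomic"
DDA_HEXASOMIC = "DDA_hexasomic"
UNCLASSIFIED = "unclassified"


@dataclass
class DosageConfig:
    sda_max_ratio: float = 2.0  #: het:hom (and hom:het) strictly less than this
    dda_ratios: Dict[str, float] = field(
        default_factory=lambda: {DDA_TETRASOMIC: 5.0, DDA_HEXASOMIC: 4.0})
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class MarkerClassification:
    marker: object
    informative_parent: str  #: maternal / paternal / both / neither
    dosage_class: str
    het_count: int
    hom_count: int
    ratio_tests: Dict[str, Dict[str, float]] = field(default_factory=dict)
    ambiguous: bool = False  #: both DDA ratios fit; larger P chosen


def _ratio_chi2(het: int, hom: int, ratio: float) -> Dict[str, float]:
    n = het + hom
    exp_het = n * ratio / (ratio + 1.0)
    exp_hom = n / (ratio + 1.0)
    chi2 = (het - exp_het) ** 2 / exp_het + (hom - exp_hom) ** 2 / exp_hom
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, df=1))}


def classify_dosage(
    het_count: int,
    hom_count: int,
    config: Optional[DosageConfig] = None,
    marker: object = None,
    informative_parent: str = "maternal",
) -> MarkerClassification:
    """Classify one marker from its heterozygote/homozygote progeny counts.

    SDA iff both het:hom and hom:het are strictly below ``sda_max_ratio``
    (symmetric band around 1:1); otherwise the DDA ratios are tested by
    chi-square goodness of fit and the best-fitting accepted ratio (larger
    P) wins; otherwise unclassified.
    """
    config = config or DosageConfig()
    if het_count + hom_count <= 0:
        raise ValueError("needs at least one non-missing call")
    tests: Dict[str, Dict[str, float]] = {}
    band = config.sda_max_ratio
    is_sda = het_count < band * hom_count and hom_count < band * het_count
    if is_sda:
        return MarkerClassification(marker, informative_parent, SDA,
                                    het_count, hom_count, tests)
    fitting: List[str] = []
    for cls, ratio in config.dda_ratios.items():
        tests[cls] = _ratio_chi2(het_count, hom_count, ratio)
        if tests[cls]["p"] > config.alpha:
            fitting.append(cls)
    if fitting:
        best = max(fitting, key=lambda c: tests[c]["p"])
        return MarkerClassification(marker, informative_parent, best,
                                    het_count, hom_count, tests,
                                    ambiguous=len(fitting) > 1)
    return MarkerClassification(marker, informative_parent, UNCLASSIFIED,
                                het_count, hom_count, tests)


def classify_markers(
    genotypes: np.ndarray,
    maternal_genotype: Sequence[int],
    paternal_genotype: Sequence[int],
    config: Optional[DosageConfig] = None,
    marker_ids: Optional[Sequence] = None,
) -> List[MarkerClassification]:
    """Classify every marker of a genotype matrix.

    Markers heterozygous in both or neither parent are reported with that
    informative-parent status and left unclassified (the pseudo-testcross
    dosage model applies only to single-parent markers).
    """
    mat = np.atleast_2d(genotypes)
    if marker_ids is None:
        marker_ids = list(range(mat.shape[0]))
    out: List[MarkerClassification] = []
    for row, mid, gm, gp in zip(mat, marker_ids, maternal_genotype, paternal_genotype):
        mat_het = gm == calling.HET
        pat_het = gp == calling.HET
        if mat_het and pat_het:
            parent = "both"
        elif mat_het:
            parent = "maternal"
        elif pat_het:
            parent = "paternal"
        else:
            parent = "neither"
        het = int((row == calling.HET).sum())
        hom = int(((row == calling.HOM_REF) | (row == calling.HOM_ALT)).sum())
        if parent in ("both", "neither") or het + hom == 0:
            out.append(MarkerClassification(mid, parent, UNCLASSIFIED, het, hom))
            continue
        out.append(classify_dosage(het, hom, config, marker=mid,
                                   informative_parent=parent))
    return out


def summarize_dosage(classifications: Sequence[MarkerClassification]) -> pd.DataFrame:
    """Tabulate dosage classes per informative parent, with fractions."""
    if not classifications:
        return pd.DataFrame(columns=["informative_parent", "dosage_class",
                                     "count", "fraction"])
    rows = [(c.informative_parent, c.dosage_class) for c in classifications]
    df = pd.DataFrame(rows, columns=["informative_parent", "dosage_class"])
    counts = (df.value_counts().rename("count").reset_index()
              .sort_values(["informative_parent", "dosage_class"]))
    counts["fraction"] = counts["count"] / len(classifications)
    return counts.reset_index(drop=True)
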