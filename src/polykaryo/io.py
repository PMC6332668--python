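"""Delimited-text and VCF input/output for the pipeline stages.

Canonical interchange is comma-delimited text.  The genotype matrix schema
is one row per marker with columns ``marker, chromosome, cM`` followed by
one column per individual holding the codes ``0`` (hom_ref), ``1`` (het),
``2`` (hom_alt) or ``NA`` (missing); read counts travel in long form
(``marker, individual, ref_reads, alt_reads``).  A biallelic VCF with AD
fields can be imported as a read-count matrix (convenience adapter only).
Comment lines starting with ``#`` document the schema inside each file.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from polykaryo import calling

META_COLUMNS = ["marker", "chromosome", "cM"]


class FormatError(ValueError):
    """Malformed input file (message carries file and line context)."""


def write_genotype_matrix(
    path: str,
    marker_ids: Sequence,
    chromosomes: Sequence[str],
    positions: Sequence[float],
    genotypes: np.ndarray,
    individual_ids: Sequence[str],
) -> None:
    """Write a genotype matrix (codes 0/1/2/NA) as delimited text."""
    geno = np.atleast_2d(genotypes)
    df = pd.DataFrame({
        "marker": list(marker_ids),
        "chromosome": list(chromosomes),
        "cM": list(positions),
    })
    codes = geno.astype(object)
    codes[geno == calling.MISSING] = "NA"
    for j, ind in enumerate(individual_ids):
        df[str(ind)] = codes[:, j]
    with open(path, "w") as fh:
        fh.write("# genotype matrix: 0=hom_ref 1=het 2=hom_alt NA=missing; "
                 "positions in cM\n")
        df.to_csv(fh, index=False)


def read_genotype_matrix(path: str) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Read a genotype matrix; returns (marker metadata, codes, individuals).

    Raises :class:`FormatError` on a missing header or duplicate marker ids.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    if list(df.columns[:3]) != META_COLUMNS:
        raise FormatError(
            f"{path}: line 1: expected header starting with {','.join(META_COLUMNS)}, "
            f"got {','.join(map(str, df.columns[:3]))}")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        line = int(df.index[df["marker"] == dup][1]) + 2
        raise FormatError(f"{path}: line {line}: duplicate marker id {dup!r}")
    individuals = [str(c) for c in df.columns[3:]]
    geno_raw = df[df.columns[3:]].to_numpy(dtype=object)
    geno = np.full(geno_raw.shape, calling.MISSING, dtype=np.int8)
    valid = {0, 1, 2}
    for idx, val in np.ndenumerate(geno_raw):
        if isinstance(val, str) and val.strip().upper() in ("NA", ""):
            continue
        if pd.isna(val):
            continue
        try:
            code = int(val)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {idx[0] + 2}: invalid genotype code {val!r}") from None
        if code not in valid:
            raise FormatError(f"{path}: line {idx[0] + 2}: invalid genotype code {val!r}")
        geno[idx] = code
    return df[META_COLUMNS].copy(), geno, individuals


def write_read_counts(
    path: str,
    marker_ids: Sequence,
    individual_ids: Sequence[str],
    ref: np.ndarray,
    alt: np.ndarray,
) -> None:
    """Write long-form read counts (marker, individual, ref_reads, alt_reads)."""
    m, n = np.atleast_2d(ref).shape
    rows = {
        "marker": np.repeat(list(marker_ids), n),
        "individual": np.tile([str(i) for i in individual_ids], m),
        "ref_reads": np.asarray(ref).ravel(),
        "alt_reads": np.asarray(alt).ravel(),
    }
    with open(path, "w") as fh:
        fh.write("# long-form biallelic read counts per marker and individual\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_read_counts(path: str) -> Tuple[List, List[str], np.ndarray, np.ndarray]:
    """Read long-form read counts into (markers, individuals, ref, alt)."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as delimited text ({exc})") from exc
    required = {"marker", "individual", "ref_reads", "alt_reads"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: line 1: expected columns {sorted(required)}")
    ref_w = df.pivot_table(index="marker", columns="individual", values="ref_reads",
                           sort=False)
    alt_w = df.pivot_table(index="marker", columns="individual", values="alt_reads",
                           sort=False)
    if ref_w.isna().any().any():
        raise FormatError(f"{path}: incomplete marker x individual grid")
    markers = ref_w.index.tolist()
    individuals = [str(c) for c in ref_w.columns]
    return markers, individuals, ref_w.to_numpy(dtype=np.int64), alt_w.to_numpy(dtype=np.int64)


def read_vcf_read_counts(path: str) -> Tuple[List[str], List[str], np.ndarray, np.ndarray]:
    """Import a biallelic VCF with AD fields as a read-count matrix.

    Multi-allelic records are rejected; marker ids are the VCF ID field or
    ``CHROM_POS`` when missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    markers: List[str] = []
    refs: List[np.ndarray] = []
    alts: List[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise FormatError(f"{path}: {variant.CHROM}:{variant.POS}: not biallelic")
        ad = variant.format("AD")
        if ad is None:
            raise FormatError(f"{path}: {variant.CHROM}:{variant.POS}: missing AD field")
        ad = np.asarray(ad)
        markers.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        ref = ad[:, 0].astype(np.int64)
        alt = ad[:, 1].astype(np.int64)
        ref[ref < 0] = 0
        alt[alt < 0] = 0
        refs.append(ref)
        alts.append(alt)
    if len(set(markers)) != len(markers):
        raise FormatError(f"{path}: duplicate marker ids")
    return markers, individuals, np.vstack(refs), np.vstack(alts)


def write_heat_matrix(path: str, marker_ids: Sequence, signed_p: np.ndarray) -> None:
    """Numeric sidecar of the karyotype heatmap: signed Fisher p per marker
    pair (+coupling / -repulsion, empty = skipped), lossless round trip."""
    df = pd.DataFrame(signed_p, index=list(marker_ids), columns=list(marker_ids))
    with open(path, "w") as fh:
        fh.write("# signed Fisher exact p per marker pair: +p coupling, "
                 "-p repulsion, empty cell skipped\n")
        df.to_csv(fh, float_format="%.17g")


def read_heat_matrix(path: str) -> Tuple[List[str], np.ndarray]:
    df = pd.read_csv(path, comment="#", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def write_json(path: str, payload: Dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
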