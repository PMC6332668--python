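"""End-to-end pipeline: simulate -> call -> classify -> karyotype -> DDA -> ASGR.

Binds the analysis stages into one reproducible run driven by a single
configuration (one mandatory seed; per-stage generators are derived
substreams of it).  Each stage function operates on in-memory objects so
the command-line interface stays a thin file adapter around this module.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from polykaryo import asgr as asgr_mod
from polykaryo import calling, dosage, karyotype, meiosis, simplex_duplex


@dataclass
class SimulateConfig:
    #: total individuals genotyped; the selfs among them serve only to impute
    #: the maternal parent, so the default leaves 102 analysable hybrids
    n_progeny: int = 114
    n_selfs: int = 12
    n_chromosomes: int = 6
    chrom_length_cm: float = 100.0
    sda_per_homolog: int = 12
    dda_per_chromosome: int = 60
    asgr_block_markers: int = 5
    maternal_copy_numbers: Optional[List[int]] = None
    paternal_copy_numbers: Optional[List[int]] = None
    #: paternal preferential pairs: {chrom: [[i, j, affinity], ...]}
    preferential_pairs: Dict[str, List[List[float]]] = field(default_factory=dict)
    #: restrict paternal duplex placements to this homolog subset (allopolyploid)
    dda_subgenome: Optional[List[int]] = None
    asgr: Optional[Dict] = field(
        default_factory=lambda: {"chromosome": "chr1", "position": 55.8, "carrier": 0})
    undetermined_rate: float = 25 / 102
    read_depth: float = 60.0
    depth_family: str = "poisson"
    depth_dispersion: Optional[float] = None
    #: GBS tags conserved on 4 of the 6 homologous copies, matching the
    #: heterozygous read-frequency peak near 0.25 seen in real data; set
    #: None to draw reads from every copy
    read_tag_copies: Optional[int] = 4
    #: the parent library is sequenced deeper than the progeny; at progeny
    #: depth a 1-of-6-dose heterozygote sits near the minor-allele-frequency
    #: threshold and would be miscalled homozygous ~10% of the time
    father_depth_factor: float = 4.0


@dataclass
class RunConfig:
    seed: int
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    caller: calling.CallerConfig = field(default_factory=calling.CallerConfig)
    filter: calling.FilterConfig = field(default_factory=calling.FilterConfig)
    dosage: dosage.DosageConfig = field(default_factory=dosage.DosageConfig)
    karyotype: karyotype.KaryotypeConfig = field(default_factory=karyotype.KaryotypeConfig)
    min_informative_coseg: int = 50

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ValueError("config requires a mandatory 'seed'")
        known = {f.name for f in fields(cls)} | {"asgr_scan"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: Dict = {"seed": int(raw["seed"])}
        sections = {
            "simulate": SimulateConfig,
            "caller": calling.CallerConfig,
            "filter": calling.FilterConfig,
            "dosage": dosage.DosageConfig,
            "karyotype": karyotype.KaryotypeConfig,
        }
        for key, klass in sections.items():
            if key in raw:
                section = dict(raw[key])
                valid = {f.name for f in fields(klass)}
                bad = set(section) - valid
                if bad:
                    raise ValueError(f"unknown keys in '{key}': {sorted(bad)}")
                if key == "karyotype" and "tiers" in section:
                    section["tiers"] = tuple(section["tiers"])
                kwargs[key] = klass(**section)
        if "asgr_scan" in raw:
            section = dict(raw["asgr_scan"])
            bad = set(section) - {"min_informative"}
            if bad:
                raise ValueError(f"unknown keys in 'asgr_scan': {sorted(bad)}")
            kwargs["min_informative_coseg"] = int(section.get("min_informative", 50))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def build_cross(
    cfg: SimulateConfig, rng: np.random.Generator
) -> Tuple[meiosis.ParentalGenome, meiosis.ParentalGenome,
           meiosis.PairingModel, meiosis.PairingModel]:
    """Construct the two parental genomes and pairing models of a run."""
    n = cfg.n_chromosomes
    mat_copies = cfg.maternal_copy_numbers or [6] * n
    pat_copies = cfg.paternal_copy_numbers or [6] * n
    chrom_names = [f"chr{i + 1}" for i in range(n)]
    maternal = meiosis.build_parent(
        "M", n_chromosomes=n, copy_numbers=mat_copies,
        chrom_length_cm=cfg.chrom_length_cm, sda_per_homolog=cfg.sda_per_homolog,
        dda_per_chromosome=cfg.dda_per_chromosome, chrom_names=chrom_names, rng=rng)
    dda_pairs = None
    if cfg.dda_subgenome is not None:
        dda_pairs = {
            name: meiosis.subgenome_pairs(k, [h for h in cfg.dda_subgenome if h < k])
            for name, k in zip(chrom_names, pat_copies)
        }
    asgr_locus = None
    if cfg.asgr:
        asgr_locus = meiosis.AsgrLocus(
            chromosome=cfg.asgr["chromosome"],
            position=float(cfg.asgr["position"]),
            carrier=int(cfg.asgr["carrier"]),
        )
    paternal = meiosis.build_parent(
        "P", n_chromosomes=n, copy_numbers=pat_copies,
        chrom_length_cm=cfg.chrom_length_cm, sda_per_homolog=cfg.sda_per_homolog,
        dda_per_chromosome=cfg.dda_per_chromosome, dda_pairs=dda_pairs,
        asgr=asgr_locus, asgr_block_markers=cfg.asgr_block_markers,
        chrom_names=chrom_names, rng=rng)
    maternal_pairing = meiosis.PairingModel()
    paternal_pairing = meiosis.PairingModel(preferential={
        chrom: [((int(i), int(j)), float(p)) for i, j, p in prefs]
        for chrom, prefs in cfg.preferential_pairs.items()
    })
    return maternal, paternal, maternal_pairing, paternal_pairing


def simulate_stage(config: RunConfig) -> Dict:
    """Simulate the cross and GBS reads; returns population, reads, truth."""
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_genome, rng_cross, rng_reads = (np.random.default_rng(s) for s in streams)
    cfg = config.simulate
    maternal, paternal, mat_pairing, pat_pairing = build_cross(cfg, rng_genome)
    population = meiosis.simulate_cross(
        maternal, paternal, n_progeny=cfg.n_progeny, n_selfs=cfg.n_selfs,
        maternal_pairing=mat_pairing, paternal_pairing=pat_pairing,
        undetermined_rate=cfg.undetermined_rate, rng=rng_cross)
    read_model = meiosis.ReadModel(mean_depth=cfg.read_depth, family=cfg.depth_family,
                                   dispersion=cfg.depth_dispersion,
                                   tag_copies=cfg.read_tag_copies)
    ref, alt = meiosis.simulate_reads(population, read_model, rng_reads)
    father_dose = np.array([len(c) if p == meiosis.PATERNAL else 0
                            for c, p in zip(population.marker_carriers,
                                            population.marker_parent)], dtype=np.int8)
    father_copies = np.array(
        [paternal.chromosome(c).n_copies for c in population.marker_chrom], dtype=float)
    if cfg.read_tag_copies is not None:
        father_copies = np.minimum(father_copies, cfg.read_tag_copies)
    depth = rng_reads.poisson(cfg.read_depth * cfg.father_depth_factor,
                              size=father_dose.shape)
    father_alt = rng_reads.binomial(depth, np.clip(father_dose / father_copies, 0, 1))
    father_ref = depth - father_alt
    return {
        "maternal": maternal, "paternal": paternal,
        "population": population, "ref": ref, "alt": alt,
        "father_ref": father_ref, "father_alt": father_alt,
    }


def call_stage(config: RunConfig, sim: Dict) -> Dict:
    """Genotype calling, marker filtering, parental genotypes, outlier screen."""
    pop: meiosis.ProgenyPopulation = sim["population"]
    genotypes = calling.call_genotypes(sim["ref"], sim["alt"], config.caller)
    father_geno = calling.call_genotypes(sim["father_ref"], sim["father_alt"],
                                         config.caller)
    selfs = pop.origin == meiosis.SELF
    maternal_geno = calling.impute_parent_matrix(genotypes[:, selfs]) if selfs.any() \
        else np.full(pop.n_markers, calling.MISSING, dtype=np.int8)
    retained = calling.filter_markers(genotypes, config.filter)
    return {
        "genotypes": genotypes,
        "maternal_genotype": maternal_geno,
        "paternal_genotype": father_geno,
        "retained_markers": retained,
    }


def classify_stage(config: RunConfig, sim: Dict, called: Dict) -> Dict:
    """Dosage classification over the hybrids, plus the outlier screen.

    Selfed individuals are excluded from segregation counts (they exist to
    impute the maternal parent, not to estimate segregation ratios); the
    analysis set is hybrids minus screened outliers.
    """
    pop: meiosis.ProgenyPopulation = sim["population"]
    keep = called["retained_markers"]
    hybrids = pop.origin == meiosis.HYBRID
    classifications = dosage.classify_markers(
        called["genotypes"][keep][:, hybrids],
        called["maternal_genotype"][keep],
        called["paternal_genotype"][keep],
        config.dosage,
        marker_ids=[m for m, k in zip(pop.marker_names, keep) if k],
    )
    sda_mask = np.zeros(pop.n_markers, dtype=bool)
    cls_by_marker = {c.marker: c for c in classifications}
    for i, (name, k) in enumerate(zip(pop.marker_names, keep)):
        if k and cls_by_marker[name].dosage_class == dosage.SDA:
            sda_mask[i] = True
    screen = calling.screen_outlier_progeny(called["genotypes"][sda_mask],
                                            config.filter)
    return {
        "classifications": classifications,
        "summary": dosage.summarize_dosage(classifications),
        "sda_mask": sda_mask,
        "outlier_screen": screen,
        "analysis_individuals": hybrids & ~screen.excluded,
    }


def karyotype_stage(
    config: RunConfig, sim: Dict, called: Dict, classified: Dict, parent: str,
) -> Dict:
    """Group one parent's SDA markers, karyotype, assign DDAs, cluster, classify pairing."""
    pop: meiosis.ProgenyPopulation = sim["population"]
    keep_ind = classified["analysis_individuals"]
    cls_by_marker = {c.marker: c for c in classified["classifications"]}
    par_arr = np.array(pop.marker_parent)

    def marker_mask(wanted_class: str) -> np.ndarray:
        mask = np.zeros(pop.n_markers, dtype=bool)
        for i, name in enumerate(pop.marker_names):
            c = cls_by_marker.get(name)
            if c is not None and c.informative_parent == parent \
                    and c.dosage_class == wanted_class:
                mask[i] = True
        return mask & (par_arr == parent)

    sda_mask = marker_mask(dosage.SDA)
    dda_mask = marker_mask(dosage.DDA_TETRASOMIC) | marker_mask(dosage.DDA_HEXASOMIC)
    presence = calling.presence_from_genotypes(called["genotypes"])[:, keep_ind]
    sda_presence = presence[sda_mask]
    labels = karyotype.two_point_grouping(sda_presence, config.karyotype)
    report = karyotype.aggregate_karyotype(sda_presence, labels, config.karyotype)
    dda_presence = presence[dda_mask]
    dda_models = [
        "tetrasomic" if cls_by_marker[name].dosage_class == dosage.DDA_TETRASOMIC
        else "hexasomic"
        for name, m in zip(pop.marker_names, dda_mask) if m
    ]
    dda_ids = [name for name, m in zip(pop.marker_names, dda_mask) if m]
    assignments = simplex_duplex.assign_dda_bulk(
        dda_presence, dda_models, sda_presence, labels, dda_ids=dda_ids,
        alpha=config.dosage.alpha) if len(dda_ids) else []
    shared = karyotype.dda_pair_counts(assignments)
    components = karyotype.cluster_homologs(report, shared)
    pairing = {}
    uniformity = {}
    for ci, comp in enumerate(components):
        pairing[ci] = karyotype.classify_pairing(comp.groups, report, config.karyotype)
        pairs = [(a, b) for i, a in enumerate(comp.groups) for b in comp.groups[i + 1:]]
        counts = [shared.get((min(a, b), max(a, b)), 0) for a, b in pairs]
        if sum(counts) >= 1 and len(pairs) >= 2:
            uniformity[ci] = simplex_duplex.subgenome_uniformity_test(counts)
    return {
        "parent": parent,
        "sda_mask": sda_mask,
        "dda_mask": dda_mask,
        "group_labels": labels,
        "report": report,
        "dda_assignments": assignments,
        "dda_shared": shared,
        "components": components,
        "pairing": pairing,
        "uniformity": uniformity,
    }


def asgr_stage(config: RunConfig, sim: Dict, called: Dict, classified: Dict) -> Dict:
    pop: meiosis.ProgenyPopulation = sim["population"]
    keep_ind = classified["analysis_individuals"]
    cls_by_marker = {c.marker: c for c in classified["classifications"]}
    pat_sda = np.array([
        cls_by_marker.get(name) is not None
        and cls_by_marker[name].informative_parent == meiosis.PATERNAL
        and cls_by_marker[name].dosage_class == dosage.SDA
        and parent == meiosis.PATERNAL
        for name, parent in zip(pop.marker_names, pop.marker_parent)
    ])
    modes = pop.phenotype[keep_ind]
    presence = calling.presence_from_genotypes(called["genotypes"])[pat_sda][:, keep_ind]
    n_sex = int((modes == asgr_mod.SEXUAL).sum())
    n_apo = int((modes == asgr_mod.APOMICTIC).sum())
    chi2, p = asgr_mod.test_monogenic_segregation(n_sex, n_apo)
    scan = asgr_mod.cosegregation_scan(
        modes, presence,
        marker_ids=[m for m, k in zip(pop.marker_names, pat_sda) if k],
        min_informative=config.min_informative_coseg)
    return {
        "n_sexual": n_sex, "n_apomictic": n_apo,
        "segregation_chi2": chi2, "segregation_p": p,
        "scan": scan,
    }


def run_all(config: RunConfig) -> Dict:
    """Run every stage and return the stage outputs plus a JSON-able report."""
    report: Dict = {"seed": config.seed, "stages": {}}
    out: Dict = {}

    t0 = time.perf_counter()
    out["sim"] = simulate_stage(config)
    pop = out["sim"]["population"]
    report["stages"]["simulate"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_progeny": pop.n_individuals,
        "n_selfs": int((pop.origin == meiosis.SELF).sum()),
        "n_markers": pop.n_markers,
    }

    t0 = time.perf_counter()
    out["called"] = call_stage(config, out["sim"])
    report["stages"]["call"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_markers_retained": int(out["called"]["retained_markers"].sum()),
        "missing_fraction": float((out["called"]["genotypes"] == calling.MISSING).mean()),
    }

    t0 = time.perf_counter()
    out["classified"] = classify_stage(config, out["sim"], out["called"])
    summary = out["classified"]["summary"]
    report["stages"]["classify"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "counts": {f"{r.informative_parent}/{r.dosage_class}": int(r.count)
                   for r in summary.itertuples()},
        "n_excluded_progeny": int(out["classified"]["outlier_screen"].excluded.sum()),
    }

    for parent in (meiosis.MATERNAL, meiosis.PATERNAL):
        t0 = time.perf_counter()
        res = karyotype_stage(config, out["sim"], out["called"], out["classified"], parent)
        out[f"karyotype_{parent}"] = res
        report["stages"][f"karyotype_{parent}"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_groups": len(res["report"].group_ids),
            "homolog_counts": [c.homolog_count for c in res["components"]],
            "n_dda_assigned": sum(1 for a in res["dda_assignments"] if a.pair),
            "n_preferential_pairs": sum(
                sum(1 for v in p.values() if v == karyotype.PREFERENTIAL)
                for p in res["pairing"].values()),
            "uniformity_p": {str(k): v.p_value for k, v in res["uniformity"].items()},
        }

    t0 = time.perf_counter()
    out["asgr"] = asgr_stage(config, out["sim"], out["called"], out["classified"])
    report["stages"]["asgr"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_sexual": out["asgr"]["n_sexual"],
        "n_apomictic": out["asgr"]["n_apomictic"],
        "segregation_chi2": round(out["asgr"]["segregation_chi2"], 4),
        "segregation_p": round(out["asgr"]["segregation_p"], 4),
        "n_perfect_linkage": len(out["asgr"]["scan"].perfect_set),
    }
    out["report"] = report
    return out
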