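"""Replicated simulation studies of the pipeline's detection properties.

Each study simulates populations under a stated meiotic regime, runs the
relevant analysis stages end to end (reads -> genotype calls -> dosage
classes -> karyotype -> duplex assignment), and measures a detection or
error rate over replicates.  The studies double as the package's
self-validation: pairing-regime discrimination (allopolyploid vs
autopolyploid), compensated-aneuploidy detection, recovery of a dominant
locus in a recombination-suppressed block, and recombination-fraction
estimation.

Study designs are scaled to the mapping design they probe: 102 analysable
hybrids, 12 maternal selfs, 12 evenly spaced simplex markers per homolog
over 100 cM and 60 duplex markers per chromosome, with one or a few base
chromosomes per replicate to keep replicated runs affordable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from polykaryo import asgr as asgr_mod
from polykaryo import calling, dosage, karyotype, meiosis, pipeline, simplex_duplex


def _replicate_rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _analyse_parent(
    config: pipeline.RunConfig, sim: Dict
) -> Tuple[Dict, Dict, meiosis.ProgenyPopulation]:
    """Call, classify and karyotype the paternal side of one simulation."""
    called = pipeline.call_stage(config, sim)
    classified = pipeline.classify_stage(config, sim, called)
    res = pipeline.karyotype_stage(config, sim, called, classified, meiosis.PATERNAL)
    return res, classified, sim["population"]


def group_truth(
    pop: meiosis.ProgenyPopulation,
    sda_mask: np.ndarray,
    labels: np.ndarray,
) -> Dict[int, Tuple[str, int]]:
    """Majority (chromosome, homolog) of each linkage group's markers."""
    sda_ids = [i for i, k in enumerate(sda_mask) if k]
    out: Dict[int, Tuple[str, int]] = {}
    for g in dict.fromkeys(labels.tolist()):
        items = [
            (pop.marker_chrom[i], min(pop.marker_carriers[i]))
            for i, l in zip(sda_ids, labels)
            if l == g and len(pop.marker_carriers[i]) == 1
        ]
        if items:
            out[g] = Counter(items).most_common(1)[0][0]
    return out


def _simulate(config: pipeline.RunConfig, rng: np.random.Generator) -> Dict:
    """pipeline.simulate_stage with an externally supplied generator."""
    streams = rng.spawn(3)
    cfg = config.simulate
    maternal, paternal, mat_pairing, pat_pairing = pipeline.build_cross(cfg, streams[0])
    population = meiosis.simulate_cross(
        maternal, paternal, n_progeny=cfg.n_progeny, n_selfs=cfg.n_selfs,
        maternal_pairing=mat_pairing, paternal_pairing=pat_pairing,
        undetermined_rate=cfg.undetermined_rate, rng=streams[1])
    read_model = meiosis.ReadModel(mean_depth=cfg.read_depth,
                                   tag_copies=cfg.read_tag_copies)
    ref, alt = meiosis.simulate_reads(population, read_model, streams[2])
    father_dose = np.array([len(c) if p == meiosis.PATERNAL else 0
                            for c, p in zip(population.marker_carriers,
                                            population.marker_parent)], dtype=np.int8)
    father_copies = np.array(
        [paternal.chromosome(c).n_copies for c in population.marker_chrom], dtype=float)
    if cfg.read_tag_copies is not None:
        father_copies = np.minimum(father_copies, cfg.read_tag_copies)
    depth = streams[2].poisson(cfg.read_depth * cfg.father_depth_factor,
                               size=father_dose.shape)
    father_alt = streams[2].binomial(depth, np.clip(father_dose / father_copies, 0, 1))
    return {"maternal": maternal, "paternal": paternal, "population": population,
            "ref": ref, "alt": alt, "father_ref": depth - father_alt,
            "father_alt": father_alt}


def _paternal_study_config(
    n_chromosomes: int,
    copy_numbers: Optional[Sequence[int]] = None,
    allo: bool = False,
) -> pipeline.RunConfig:
    """Study configuration: paternal markers only, no ASGR."""
    config = pipeline.RunConfig(seed=0)
    cfg = config.simulate
    cfg.n_chromosomes = n_chromosomes
    cfg.paternal_copy_numbers = list(copy_numbers) if copy_numbers else None
    cfg.asgr = None
    cfg.asgr_block_markers = 0
    cfg.undetermined_rate = 0.0
    if allo:
        cfg.preferential_pairs = {
            f"chr{i + 1}": [[4, 5, 1.0]] for i in range(n_chromosomes)}
        cfg.dda_subgenome = [0, 1, 2, 3]
    return config


@dataclass
class PairingStudyResult:
    n_replicates: int
    planted_pairs_total: int
    planted_pairs_detected: int
    uniformity_significant: int  #: replicates with chromosome-level P < 0.05
    replicates_with_any_preferential: int

    @property
    def detection_rate(self) -> float:
        return self.planted_pairs_detected / max(1, self.planted_pairs_total)

    @property
    def uniformity_rate(self) -> float:
        return self.uniformity_significant / self.n_replicates

    @property
    def any_preferential_rate(self) -> float:
        return self.replicates_with_any_preferential / self.n_replicates


def pairing_discrimination_study(
    n_replicates: int,
    seed: int,
    allo: bool,
    n_chromosomes: int = 1,
) -> PairingStudyResult:
    """Can the pipeline tell an allopolyploid from an autopolyploid parent?

    Each replicate simulates a paternal parent with either one affinity-1
    preferential pair per chromosome and subgenome-confined duplexes
    (``allo=True``) or fully random pairing with duplexes on all homolog
    pairs.  Measured per replicate: whether every planted pair is called
    preferential, whether any pair at all is called preferential, and
    whether the chromosome-level subgenome-uniformity test (duplex tally
    over the 15 homolog pairs, chromosome membership from simulation truth)
    is significant at 0.05.
    """
    config = _paternal_study_config(n_chromosomes, allo=allo)
    detected = total = uni_sig = any_pref = 0
    for rng in _replicate_rngs(seed, n_replicates):
        sim = _simulate(config, rng)
        res, _, pop = _analyse_parent(config, sim)
        truth = group_truth(pop, res["sda_mask"], res["group_labels"])
        rep_pref: List[Tuple[Tuple[str, int], Tuple[str, int]]] = []
        for ci, pairing in res["pairing"].items():
            for (ga, gb), call in pairing.items():
                if call == karyotype.PREFERENTIAL and ga in truth and gb in truth:
                    rep_pref.append(tuple(sorted([truth[ga], truth[gb]])))
        if rep_pref:
            any_pref += 1
        if allo:
            for c in range(n_chromosomes):
                total += 1
                planted = ((f"chr{c + 1}", 4), (f"chr{c + 1}", 5))
                if planted in rep_pref:
                    detected += 1
        # chromosome-level uniformity from truth chromosome membership
        tally: Dict[str, Counter] = {}
        for a in res["dda_assignments"]:
            if a.pair is None:
                continue
            ta, tb = truth.get(a.pair[0]), truth.get(a.pair[1])
            if ta is None or tb is None or ta[0] != tb[0]:
                continue
            tally.setdefault(ta[0], Counter())[tuple(sorted([ta[1], tb[1]]))] += 1
        sig = False
        for cname, counts in tally.items():
            k = 6
            pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
            vec = [counts.get(p, 0) for p in pairs]
            if sum(vec) >= 1:
                if simplex_duplex.subgenome_uniformity_test(vec).p_value < 0.05:
                    sig = True
        if sig:
            uni_sig += 1
    return PairingStudyResult(
        n_replicates=n_replicates,
        planted_pairs_total=total,
        planted_pairs_detected=detected,
        uniformity_significant=uni_sig,
        replicates_with_any_preferential=any_pref,
    )


@dataclass
class AneuploidyStudyResult:
    n_replicates: int
    both_detected: int  #: replicates with clean 5- and 7-homolog components
    sizes_5: List[int]
    sizes_7: List[int]

    @property
    def detection_rate(self) -> float:
        return self.both_detected / self.n_replicates


def aneuploidy_study(
    n_replicates: int,
    seed: int,
    copy_numbers: Sequence[int] = (6, 6, 6, 6, 5, 7),
) -> AneuploidyStudyResult:
    """Detection of compensated aneuploidy from homolog-group clustering.

    The paternal parent carries one 5-copy and one 7-copy chromosome in an
    otherwise euploid 2n = 36 complement.  A replicate succeeds when, for
    each aneuploid chromosome, its linkage groups form exactly one
    component containing nothing else and the reported homolog count
    equals the true copy number.
    """
    config = _paternal_study_config(len(copy_numbers), copy_numbers=copy_numbers)
    focal = {f"chr{i + 1}": k for i, k in enumerate(copy_numbers) if k != 6}
    both = 0
    sizes_5: List[int] = []
    sizes_7: List[int] = []
    for rng in _replicate_rngs(seed, n_replicates):
        sim = _simulate(config, rng)
        res, _, pop = _analyse_parent(config, sim)
        truth = group_truth(pop, res["sda_mask"], res["group_labels"])
        ok = True
        for cname, k in focal.items():
            comps = [c for c in res["components"]
                     if any(truth.get(g, ("", -1))[0] == cname for g in c.groups)]
            pure = [c for c in comps
                    if all(truth.get(g, ("", -1))[0] == cname for g in c.groups)]
            size = pure[0].homolog_count if len(comps) == 1 and len(pure) == 1 else -1
            if k == 5:
                sizes_5.append(size)
            else:
                sizes_7.append(size)
            ok = ok and size == k
        both += ok
    return AneuploidyStudyResult(n_replicates=n_replicates, both_detected=both,
                                 sizes_5=sizes_5, sizes_7=sizes_7)


@dataclass
class AsgrStudyResult:
    n_replicates: int
    successes: int
    n_block_markers: int

    @property
    def success_rate(self) -> float:
        return self.successes / self.n_replicates


def asgr_recovery_study(
    n_replicates: int,
    seed: int,
    n_block_markers: int = 5,
    r_exclusion: float = 0.10,
    use_read_calls: bool = False,
) -> AsgrStudyResult:
    """Recovery of a dominant locus in a recombination-suppressed block.

    The paternal genome carries the dominant apomixis locus with
    ``n_block_markers`` co-located simplex markers on its carrier homolog.
    A replicate succeeds when the perfect-cosegregation set contains every
    block marker and no marker at recombination fraction >= ``r_exclusion``
    from the locus.

    By default the scan runs on the simulated genotype matrix itself, so
    the study measures the meiotic model plus the scan logic.  With
    ``use_read_calls=True`` genotypes are re-called from simulated reads
    first; perfect cosegregation is then fragile, because a single
    miscalled heterozygote (a few per mille per call at the default depth)
    already removes a marker from the zero-recombinant set.
    """
    config = pipeline.RunConfig(seed=0)
    cfg = config.simulate
    cfg.n_chromosomes = 2
    cfg.dda_per_chromosome = 0
    cfg.asgr = {"chromosome": "chr1", "position": 55.8, "carrier": 0}
    cfg.asgr_block_markers = n_block_markers
    d_excl = -50.0 * np.log(1.0 - 2.0 * r_exclusion)  # Haldane inverse, cM
    successes = 0
    for rng in _replicate_rngs(seed, n_replicates):
        sim = _simulate(config, rng)
        pop = sim["population"]
        if use_read_calls:
            called = pipeline.call_stage(config, sim)
            classified = pipeline.classify_stage(config, sim, called)
            scan = pipeline.asgr_stage(config, sim, called, classified)["scan"]
        else:
            hybrids = pop.origin == meiosis.HYBRID
            pat_sda = np.array([
                p == meiosis.PATERNAL and len(c) == 1
                for p, c in zip(pop.marker_parent, pop.marker_carriers)])
            scan = asgr_mod.cosegregation_scan(
                pop.phenotype[hybrids], pop.presence()[pat_sda][:, hybrids],
                marker_ids=[m for m, k in zip(pop.marker_names, pat_sda) if k],
                min_informative=config.min_informative_coseg)
        perfect = set(scan.perfect_set)
        block = {m for m in pop.marker_names if "_asgr" in m}
        pos = dict(zip(pop.marker_names, pop.marker_pos))
        chrom = dict(zip(pop.marker_names, pop.marker_chrom))
        far = {m for m in perfect
               if chrom[m] != "chr1" or abs(pos[m] - 55.8) >= d_excl}
        if block <= perfect and not far:
            successes += 1
    return AsgrStudyResult(n_replicates=n_replicates, successes=successes,
                           n_block_markers=n_block_markers)


@dataclass
class RRecoveryResult:
    r_true: float
    n: int
    n_replicates: int
    mean_r_hat: float
    max_grid_deviation: float


def r_recovery_study(
    n_replicates: int,
    seed: int,
    r_values: Sequence[float] = (0.05, 0.10, 0.20),
    n: int = 102,
    model: str = "hexasomic",
    grid_check_every: int = 20,
) -> List[RRecoveryResult]:
    """Bias of the ML recombination estimator at the mapping-design size.

    Class counts are drawn multinomially from the closed-form frequencies;
    every ``grid_check_every``-th replicate is re-estimated with the
    1e-4-step grid-search oracle to bound the optimiser's deviation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out: List[RRecoveryResult] = []
    for r in r_values:
        probs = simplex_duplex.expected_class_freqs(r, model)
        r_hats = np.empty(n_replicates)
        max_dev = 0.0
        for i in range(n_replicates):
            counts = rng.multinomial(n, probs)
            table = simplex_duplex.ContingencyAB(*counts, model=model)
            est = simplex_duplex.estimate_r_ml(table)
            r_hats[i] = est.r
            if i % grid_check_every == 0:
                grid = simplex_duplex.estimate_r_grid(table)
                max_dev = max(max_dev, abs(grid - est.r))
        out.append(RRecoveryResult(r_true=r, n=n, n_replicates=n_replicates,
                                   mean_r_hat=float(r_hats.mean()),
                                   max_grid_deviation=max_dev))
    return out
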