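"""Forward simulation of polysomic (bivalent) meiosis in a polyploid parent.

The model is deliberately minimal but sufficient to reproduce every single-
and two-locus expectation used by the downstream statistics:

* homologs of each base chromosome form bivalents; with an odd copy number
  (compensated aneuploidy) one homolog remains univalent and enters the
  gamete with probability 1/2;
* pairing is uniform over perfect matchings, optionally preceded by
  preferential pairs (subgenome differentiation) that form a bivalent with
  a configurable affinity before the rest resolve at random;
* each bivalent transmits a single recombinant strand that starts from
  either member with probability 1/2 and switches member between adjacent
  loci with the Haldane probability r = (1 - exp(-2 d / 100)) / 2;
* no multivalents, no double reduction, no chiasma interference.

An F1 pseudo-testcross population is simulated as maternal gamete plus
paternal gamete, with a configurable number of accidental maternal selfs
(two independent maternal gametes), a dominant apomixis locus (ASGR)
transmitted on one paternal homolog, and GBS-like read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

HYBRID = "hybrid"
SELF = "maternal_self"

SEXUAL = "sexual"
APOMICTIC = "apomictic"
UNDETERMINED = "undetermined"


def haldane(d_cm: np.ndarray) -> np.ndarray:
    """Map distance (cM) to recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


# ---------------------------------------------------------------------------
# Genome configuration
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeSpec:
    """One base chromosome of one parent: homolog set and marker placements.

    ``carriers[m]`` is the set of homolog indices (0-based) carrying the
    segregating allele of marker ``m``; size 1 = simplex (SDA), size 2 =
    duplex (DDA).
    """

    name: str
    n_copies: int
    positions: np.ndarray
    marker_names: List[str]
    carriers: List[frozenset]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if len(self.positions) != len(self.marker_names) or len(self.carriers) != len(self.marker_names):
            raise ValueError("positions, marker_names and carriers must align")
        if self.positions.size and (
            not np.all(np.isfinite(self.positions))
            or np.any(self.positions < 0)
            or np.any(np.diff(self.positions) < 0)
        ):
            raise ValueError("cM positions must be finite, nonnegative and nondecreasing")
        homologs = set(range(self.n_copies))
        for name, carr in zip(self.marker_names, self.carriers):
            if not set(carr) <= homologs:
                raise ValueError(f"marker {name}: carriers {set(carr)} outside homolog set")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def carrier_matrix(self) -> np.ndarray:
        """Boolean (n_copies, n_markers) indicator of allele placement."""
        mat = np.zeros((self.n_copies, self.n_markers), dtype=bool)
        for m, carr in enumerate(self.carriers):
            for h in carr:
                mat[h, m] = True
        return mat


@dataclass
class AsgrLocus:
    """Dominant apomixis locus: chromosome, cM position, carrier homolog."""

    chromosome: str
    position: float
    carrier: int


@dataclass
class ParentalGenome:
    chromosomes: List[ChromosomeSpec]
    asgr: Optional[AsgrLocus] = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.asgr is not None:
            chrom = self.chromosome(self.asgr.chromosome)
            if self.asgr.carrier not in range(chrom.n_copies):
                raise ValueError("ASGR carrier homolog does not exist in its chromosome")

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    @property
    def total_copies(self) -> int:
        """2n of this parent (sum of per-chromosome copy numbers)."""
        return sum(c.n_copies for c in self.chromosomes)


@dataclass
class PairingModel:
    """Preferential bivalent formation before uniform residual matching.

    ``preferential[chrom]`` is an ordered list of ``((i, j), affinity)``
    entries; each listed pair forms a bivalent with probability equal to
    its affinity, resolved sequentially, before the remaining homologs are
    matched uniformly over perfect matchings.
    """

    preferential: Dict[str, List[Tuple[Tuple[int, int], float]]] = field(default_factory=dict)
    univalent_transmission_prob: float = 0.5

    def validate(self, genome: ParentalGenome) -> None:
        for chrom_name, prefs in self.preferential.items():
            chrom = genome.chromosome(chrom_name)
            seen: set = set()
            for (i, j), p in prefs:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"affinity {p} outside [0, 1]")
                if i == j or i not in range(chrom.n_copies) or j not in range(chrom.n_copies):
                    raise ValueError(
                        f"unknown homolog in preferential pair ({i}, {j}) on {chrom_name}")
                if i in seen or j in seen:
                    raise ValueError(f"preferential pairs on {chrom_name} are not disjoint")
                seen |= {i, j}


@dataclass
class ReadModel:
    """GBS-like sequencing depth model.

    Depth is Poisson (or negative binomial with ``dispersion``) with mean
    ``mean_depth`` times an optional per-marker multiplier; alternate-allele
    reads are Binomial(depth, dosage / copy_number).

    ``tag_copies`` emulates restriction-site tags whose flanking sequence is
    conserved on only a subset of the homologous copies (the common case in
    polyploids with diverged subgenomes, visible as a heterozygous
    read-frequency peak near 1/4 rather than 1/6): when set, the allele
    fraction is dosage / min(tag_copies, copy_number).  Leave ``None`` for
    reads drawn from all copies.
    """

    mean_depth: float = 60.0
    family: str = "poisson"
    dispersion: Optional[float] = None
    depth_multiplier: Optional[np.ndarray] = None
    tag_copies: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.family not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown depth family {self.family!r}")
        if self.family == "negative-binomial" and (self.dispersion is None or self.dispersion <= 0):
            raise ValueError("negative-binomial depth requires dispersion > 0")
        if self.depth_multiplier is not None:
            self.depth_multiplier = np.asarray(self.depth_multiplier, dtype=float)
            if np.any(self.depth_multiplier <= 0):
                raise ValueError("depth multipliers must be positive")


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def pair_homologs(
    n_copies: int,
    preferential: Sequence[Tuple[Tuple[int, int], float]] = (),
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Tuple[int, int]], Optional[int]]:
    """Partition homologs into bivalents (plus one univalent if odd).

    Preferential pairs are resolved sequentially in listed order; the
    remaining homologs are matched uniformly at random over perfect
    matchings (each of the 15 matchings of 6 homologs has probability 1/15
    when no preference applies).
    """
    rng = np.random.default_rng() if rng is None else rng
    available = set(range(n_copies))
    pairs: List[Tuple[int, int]] = []
    for (i, j), p in preferential:
        if i not in range(n_copies) or j not in range(n_copies) or i == j:
            raise ValueError(f"unknown homolog in preferential pair ({i}, {j})")
        if i in available and j in available and rng.random() < p:
            pairs.append((i, j))
            available -= {i, j}
    rest = sorted(available)
    order = rng.permutation(len(rest))
    shuffled = [rest[k] for k in order]
    for k in range(0, len(shuffled) - 1, 2):
        pairs.append((shuffled[k], shuffled[k + 1]))
    univalent = shuffled[-1] if len(shuffled) % 2 else None
    return pairs, univalent


def _strand_sources(i: int, j: int, loci: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Homolog of origin at each locus for the strand a bivalent transmits."""
    n = loci.size
    start = int(rng.integers(2))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n == 1:
        state = np.array([start])
    else:
        r = haldane(np.diff(loci))
        switches = rng.random(n - 1) < r
        state = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
    return np.where(state == 0, i, j)


@dataclass
class Gamete:
    """One gamete: per-chromosome marker allele dosage and strand count."""

    dosage: Dict[str, np.ndarray]
    n_strands: Dict[str, int]
    asgr_carried: bool = False


def generate_gamete(
    genome: ParentalGenome,
    partition: Mapping[str, Tuple[List[Tuple[int, int]], Optional[int]]],
    rng: np.random.Generator,
    univalent_transmission_prob: float = 0.5,
) -> Gamete:
    """Transmit one recombinant strand per bivalent and form a gamete.

    ``partition`` maps chromosome name to the output of
    :func:`pair_homologs` for that chromosome.
    """
    dosage: Dict[str, np.ndarray] = {}
    n_strands: Dict[str, int] = {}
    asgr_carried = False
    for chrom in genome.chromosomes:
        pairs, univalent = partition[chrom.name]
        loci = chrom.positions
        asgr_here = genome.asgr is not None and genome.asgr.chromosome == chrom.name
        if asgr_here:
            insert_at = int(np.searchsorted(loci, genome.asgr.position))
            loci = np.insert(loci, insert_at, genome.asgr.position)
        carrier = chrom.carrier_matrix()
        dose = np.zeros(chrom.n_markers, dtype=np.int8)
        strands = 0
        sources_list: List[np.ndarray] = []
        for (i, j) in pairs:
            sources_list.append(_strand_sources(i, j, loci, rng))
            strands += 1
        if univalent is not None and rng.random() < univalent_transmission_prob:
            sources_list.append(np.full(loci.size, univalent, dtype=np.int64))
            strands += 1
        marker_idx = np.arange(chrom.n_markers)
        for sources in sources_list:
            marker_sources = np.delete(sources, insert_at) if asgr_here else sources
            if chrom.n_markers:
                dose += carrier[marker_sources, marker_idx]
            if asgr_here and sources[insert_at] == genome.asgr.carrier:
                asgr_carried = True
        dosage[chrom.name] = dose
        n_strands[chrom.name] = strands
    return Gamete(dosage=dosage, n_strands=n_strands, asgr_carried=asgr_carried)


def sample_gamete(
    genome: ParentalGenome,
    pairing: Optional[PairingModel],
    rng: np.random.Generator,
) -> Gamete:
    """Sample a bivalent partition for every chromosome and a gamete from it."""
    pairing = pairing or PairingModel()
    partition = {
        c.name: pair_homologs(c.n_copies, pairing.preferential.get(c.name, ()), rng)
        for c in genome.chromosomes
    }
    return generate_gamete(genome, partition, rng,
                           univalent_transmission_prob=pairing.univalent_transmission_prob)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

MATERNAL = "maternal"
PATERNAL = "paternal"


@dataclass
class ProgenyPopulation:
    """Simulated F1 pseudo-testcross population with full truth tables."""

    marker_names: List[str]
    marker_chrom: List[str]
    marker_pos: np.ndarray
    marker_parent: List[str]  #: which parent each marker segregates from
    marker_carriers: List[frozenset]
    chrom_names: List[str]
    dosage: np.ndarray  #: (n_markers, n_individuals) true allele dosage
    copy_number: np.ndarray  #: (n_chromosomes, n_individuals)
    origin: np.ndarray  #: HYBRID or SELF per individual
    phenotype: np.ndarray  #: SEXUAL / APOMICTIC / UNDETERMINED
    asgr_paternal: np.ndarray  #: truth: paternal gamete carried the ASGR

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[1]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[0]

    def marker_copy_number(self) -> np.ndarray:
        """(n_markers, n_individuals) chromosome copy number per marker."""
        idx = np.array([self.chrom_names.index(c) for c in self.marker_chrom])
        return self.copy_number[idx, :]

    def presence(self) -> np.ndarray:
        """True allele presence/absence (1/0) per marker and individual."""
        return (self.dosage > 0).astype(np.int8)


def simulate_cross(
    maternal: ParentalGenome,
    paternal: ParentalGenome,
    n_progeny: int = 102,
    n_selfs: int = 12,
    maternal_pairing: Optional[PairingModel] = None,
    paternal_pairing: Optional[PairingModel] = None,
    undetermined_rate: float = 25 / 102,
    rng: Optional[np.random.Generator] = None,
) -> ProgenyPopulation:
    """Simulate an F1 pseudo-testcross with accidental maternal selfs.

    Hybrids combine a maternal and a paternal gamete; the first ``n_selfs``
    individuals are accidental selfs combining two independent maternal
    gametes and therefore carry no paternal-unique alleles.  Reproductive
    mode is apomictic iff the paternal gamete carries the dominant ASGR
    haplotype; an independent Bernoulli fraction is relabelled undetermined
    to emulate non-flowering or aborted-pistil losses.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_selfs > n_progeny:
        raise ValueError("n_selfs cannot exceed n_progeny")
    mat_names = {c.name for c in maternal.chromosomes}
    pat_names = {c.name for c in paternal.chromosomes}
    if mat_names != pat_names:
        raise ValueError("parents must share the same base chromosome set")
    if maternal_pairing:
        maternal_pairing.validate(maternal)
    if paternal_pairing:
        paternal_pairing.validate(paternal)

    chrom_names = [c.name for c in maternal.chromosomes]
    marker_names: List[str] = []
    marker_chrom: List[str] = []
    marker_pos: List[float] = []
    marker_parent: List[str] = []
    marker_carriers: List[frozenset] = []
    for parent_tag, genome in ((MATERNAL, maternal), (PATERNAL, paternal)):
        for chrom in genome.chromosomes:
            marker_names.extend(chrom.marker_names)
            marker_chrom.extend([chrom.name] * chrom.n_markers)
            marker_pos.extend(chrom.positions.tolist())
            marker_parent.extend([parent_tag] * chrom.n_markers)
            marker_carriers.extend(chrom.carriers)
    if len(set(marker_names)) != len(marker_names):
        raise ValueError("marker names must be unique across both parents")

    n_mat = sum(c.n_markers for c in maternal.chromosomes)
    n_markers = len(marker_names)
    dosage = np.zeros((n_markers, n_progeny), dtype=np.int8)
    copy_number = np.zeros((len(chrom_names), n_progeny), dtype=np.int8)
    asgr_pat = np.zeros(n_progeny, dtype=bool)
    origin = np.empty(n_progeny, dtype=object)
    phenotype = np.empty(n_progeny, dtype=object)

    mat_order = [c.name for c in maternal.chromosomes]
    pat_order = [c.name for c in paternal.chromosomes]

    for ind in range(n_progeny):
        is_self = ind < n_selfs
        g1 = sample_gamete(maternal, maternal_pairing, rng)
        if is_self:
            g2 = sample_gamete(maternal, maternal_pairing, rng)
            mat_dose = np.concatenate([g1.dosage[c] + g2.dosage[c] for c in mat_order]) \
                if n_mat else np.empty(0, dtype=np.int8)
            dosage[:n_mat, ind] = mat_dose
            for ci, cname in enumerate(chrom_names):
                copy_number[ci, ind] = g1.n_strands[cname] + g2.n_strands[cname]
            origin[ind] = SELF
            phenotype[ind] = SEXUAL
        else:
            g2 = sample_gamete(paternal, paternal_pairing, rng)
            if n_mat:
                dosage[:n_mat, ind] = np.concatenate([g1.dosage[c] for c in mat_order])
            if n_markers > n_mat:
                dosage[n_mat:, ind] = np.concatenate([g2.dosage[c] for c in pat_order])
            for ci, cname in enumerate(chrom_names):
                copy_number[ci, ind] = g1.n_strands[cname] + g2.n_strands[cname]
            origin[ind] = HYBRID
            asgr_pat[ind] = g2.asgr_carried
            phenotype[ind] = APOMICTIC if g2.asgr_carried else SEXUAL
    if undetermined_rate > 0:
        undet = rng.random(n_progeny) < undetermined_rate
        phenotype[undet] = UNDETERMINED

    return ProgenyPopulation(
        marker_names=marker_names,
        marker_chrom=marker_chrom,
        marker_pos=np.asarray(marker_pos, dtype=float),
        marker_parent=marker_parent,
        marker_carriers=marker_carriers,
        chrom_names=chrom_names,
        dosage=dosage,
        copy_number=copy_number,
        origin=origin,
        phenotype=phenotype,
        asgr_paternal=asgr_pat,
    )


def simulate_reads(
    population: ProgenyPopulation,
    read_model: Optional[ReadModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate (ref, alt) read-count matrices for a population.

    Depth follows the configured family; alternate reads are
    Binomial(depth, dosage / copy_number) with the individual's chromosome
    copy number.
    """
    read_model = read_model or ReadModel()
    rng = np.random.default_rng() if rng is None else rng
    shape = population.dosage.shape
    mean = np.full(shape, read_model.mean_depth, dtype=float)
    if read_model.depth_multiplier is not None:
        mult = np.asarray(read_model.depth_multiplier, dtype=float)
        if mult.shape[0] != shape[0]:
            raise ValueError("depth_multiplier must have one entry per marker")
        mean *= mult[:, None]
    if read_model.family == "poisson":
        depth = rng.poisson(mean)
    else:
        k = read_model.dispersion
        depth = rng.negative_binomial(k, k / (k + mean))
    copies = population.marker_copy_number().astype(float)
    if read_model.tag_copies is not None:
        copies = np.minimum(copies, read_model.tag_copies)
    frac = np.divide(population.dosage, copies, out=np.zeros(shape, dtype=float),
                     where=copies > 0)
    frac = np.clip(frac, 0.0, 1.0)
    alt = rng.binomial(depth, frac)
    ref = depth - alt
    return ref.astype(np.int64), alt.astype(np.int64)


# ---------------------------------------------------------------------------
# Genome builders
# ---------------------------------------------------------------------------

def build_parent(
    prefix: str,
    n_chromosomes: int = 6,
    copy_numbers: Optional[Sequence[int]] = None,
    chrom_length_cm: float = 100.0,
    sda_per_homolog: int = 8,
    dda_per_chromosome: int = 0,
    dda_pairs: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
    asgr: Optional[AsgrLocus] = None,
    asgr_block_markers: int = 0,
    chrom_names: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> ParentalGenome:
    """Construct a parental genome with evenly spaced simplex markers.

    Each homolog of each chromosome receives ``sda_per_homolog`` simplex
    (single-dose) markers evenly spaced over ``chrom_length_cm``; duplex
    (double-dose) markers are placed at uniform random positions on homolog
    pairs drawn uniformly from ``dda_pairs[chrom]`` (all pairs by default).
    When an ASGR locus is given, ``asgr_block_markers`` additional simplex
    markers are co-located with it on its carrier homolog, emulating the
    recombination-suppressed block around the locus.
    """
    rng = np.random.default_rng() if rng is None else rng
    if copy_numbers is None:
        copy_numbers = [6] * n_chromosomes
    if len(copy_numbers) != n_chromosomes:
        raise ValueError("copy_numbers must have one entry per chromosome")
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chroms: List[ChromosomeSpec] = []
    for ci, (cname, k) in enumerate(zip(chrom_names, copy_numbers)):
        positions: List[float] = []
        names: List[str] = []
        carriers: List[frozenset] = []
        if sda_per_homolog > 0:
            grid = np.linspace(0.0, chrom_length_cm, sda_per_homolog)
            for h in range(k):
                for mi, pos in enumerate(grid):
                    positions.append(float(pos))
                    names.append(f"{prefix}_{cname}_h{h}_s{mi}")
                    carriers.append(frozenset([h]))
        pair_choices = None
        if dda_per_chromosome > 0:
            if dda_pairs is not None and cname in dda_pairs:
                pair_choices = list(dda_pairs[cname])
            else:
                pair_choices = [(i, j) for i in range(k) for j in range(i + 1, k)]
            for d in range(dda_per_chromosome):
                pos = float(rng.uniform(0.0, chrom_length_cm))
                pair = pair_choices[int(rng.integers(len(pair_choices)))]
                positions.append(pos)
                names.append(f"{prefix}_{cname}_d{d}")
                carriers.append(frozenset(pair))
        if asgr is not None and asgr.chromosome == cname and asgr_block_markers > 0:
            for b in range(asgr_block_markers):
                positions.append(float(asgr.position))
                names.append(f"{prefix}_{cname}_asgr{b}")
                carriers.append(frozenset([asgr.carrier]))
        order = np.argsort(positions, kind="stable") if positions else np.empty(0, int)
        chroms.append(ChromosomeSpec(
            name=cname,
            n_copies=int(k),
            positions=np.asarray([positions[i] for i in order]),
            marker_names=[names[i] for i in order],
            carriers=[carriers[i] for i in order],
        ))
    return ParentalGenome(chromosomes=chroms, asgr=asgr)


def subgenome_pairs(n_copies: int, subgenome: Sequence[int]) -> List[Tuple[int, int]]:
    """Homolog pairs confined to one subgenome (for allopolyploid duplexes)."""
    sub = sorted(subgenome)
    if not set(sub) <= set(range(n_copies)):
        raise ValueError("subgenome homologs outside copy set")
    return [(sub[i], sub[j]) for i in range(len(sub)) for j in range(i + 1, len(sub))]
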