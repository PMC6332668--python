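"""Forward meiosis simulator: pairing, transmission and read models."""

from collections import Counter

import numpy as np
import pytest

from polykaryo import meiosis
from polykaryo import simplex_duplex as sd


def mc_se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestPairHomologs:
    def test_uniform_over_15_matchings(self, rng):
        n = 60_000
        counts = Counter()
        for _ in range(n):
            pairs, uni = meiosis.pair_homologs(6, rng=rng)
            assert uni is None
            counts[frozenset(frozenset(p) for p in pairs)] += 1
        assert len(counts) == 15
        for c in counts.values():
            assert abs(c / n - 1 / 15) < 3 * mc_se(1 / 15, n)

    def test_forced_preferential_pair(self, rng):
        for _ in range(200):
            pairs, _ = meiosis.pair_homologs(6, [((4, 5), 1.0)], rng=rng)
            assert (4, 5) in pairs

    def test_odd_copy_number_leaves_univalent(self, rng):
        for _ in range(200):
            pairs, uni = meiosis.pair_homologs(5, rng=rng)
            assert len(pairs) == 2 and uni is not None

    def test_unknown_homolog_rejected(self, rng):
        with pytest.raises(ValueError):
            meiosis.pair_homologs(6, [((5, 6), 1.0)], rng=rng)

    def test_pairing_model_validation(self, hexaploid_parent):
        bad = meiosis.PairingModel(preferential={"chr1": [((0, 1), 1.5)]})
        with pytest.raises(ValueError):
            bad.validate(hexaploid_parent)
        overlapping = meiosis.PairingModel(
            preferential={"chr1": [((0, 1), 1.0), ((1, 2), 1.0)]})
        with pytest.raises(ValueError):
            overlapping.validate(hexaploid_parent)


class TestGamete:
    def test_null_homolog_bivalent_transmits_nothing(self, rng):
        chrom = meiosis.ChromosomeSpec("c", 4, np.array([0.0, 50.0]),
                                       ["m1", "m2"],
                                       [frozenset([0]), frozenset([0])])
        genome = meiosis.ParentalGenome([chrom])
        g = meiosis.generate_gamete(genome, {"c": ([(2, 3), (0, 1)], None)}, rng)
        # homologs 2,3 are null: that bivalent can never contribute the allele
        assert g.dosage["c"].max() <= 1

    def test_simplex_transmission_is_half(self, hexaploid_parent, rng):
        n = 100_000
        hits = sum(
            int(meiosis.sample_gamete(hexaploid_parent, None, rng).dosage["chr1"][0])
            for _ in range(n))
        assert abs(hits / n - 0.5) < 3 * mc_se(0.5, n)

    def test_zero_distance_always_cotransmitted(self, rng):
        chrom = meiosis.ChromosomeSpec("c", 6, np.array([20.0, 20.0]),
                                       ["m1", "m2"],
                                       [frozenset([3]), frozenset([3])])
        genome = meiosis.ParentalGenome([chrom])
        for _ in range(500):
            d = meiosis.sample_gamete(genome, None, rng).dosage["c"]
            assert d[0] == d[1]

    @pytest.mark.parametrize("n_copies,expected_ratio", [(6, 4.0), (4, 5.0)])
    def test_duplex_presence_ratio_random_pairing(self, n_copies, expected_ratio, rng):
        chrom = meiosis.ChromosomeSpec("c", n_copies, np.array([0.0]), ["m"],
                                       [frozenset([0, 1])])
        genome = meiosis.ParentalGenome([chrom])
        n = 100_000
        present = sum(
            meiosis.sample_gamete(genome, None, rng).dosage["c"][0] > 0
            for _ in range(n))
        p_expected = expected_ratio / (expected_ratio + 1)
        assert abs(present / n - p_expected) < 3 * mc_se(p_expected, n)

    def test_duplex_confined_to_copairing_subgenome_gives_5_to_1(self, rng):
        # duplex on two of the four random homologs while {4,5} always co-pair
        chrom = meiosis.ChromosomeSpec("c", 6, np.array([0.0]), ["m"],
                                       [frozenset([0, 1])])
        genome = meiosis.ParentalGenome([chrom])
        pairing = meiosis.PairingModel(preferential={"c": [((4, 5), 1.0)]})
        n = 100_000
        present = sum(
            meiosis.sample_gamete(genome, pairing, rng).dosage["c"][0] > 0
            for _ in range(n))
        assert abs(present / n - 5 / 6) < 3 * mc_se(5 / 6, n)

    def test_haldane_recombinant_fraction(self, rng):
        d = 30.0
        chrom = meiosis.ChromosomeSpec("c", 2, np.array([0.0, d]),
                                       ["m1", "m2"],
                                       [frozenset([0]), frozenset([0])])
        genome = meiosis.ParentalGenome([chrom])
        n = 50_000
        rec = sum(
            (lambda g: g.dosage["c"][0] != g.dosage["c"][1])(
                meiosis.sample_gamete(genome, None, rng))
            for _ in range(n))
        r = float(meiosis.haldane(d))
        assert abs(rec / n - r) < 3 * mc_se(r, n)

    def test_class_frequencies_match_closed_form(self, rng):
        # coupling SDA-DDA pair at several r: simulator vs closed-form model
        n = 20_000
        for r_target, d in [(0.0, 0.0), (0.1, None), (0.25, None)]:
            d = 0.0 if d is None and r_target == 0 else \
                (-50 * np.log(1 - 2 * r_target) if d is None else d)
            chrom = meiosis.ChromosomeSpec(
                "c", 6, np.array([10.0, 10.0 + d]), ["sda", "dda"],
                [frozenset([0]), frozenset([0, 1])])
            genome = meiosis.ParentalGenome([chrom])
            counts = np.zeros(4)
            for _ in range(n):
                dose = meiosis.sample_gamete(genome, None, rng).dosage["c"]
                a, b = dose[0] > 0, dose[1] > 0
                counts[0 if a and b else 1 if a else 2 if b else 3] += 1
            expected = np.array(sd.expected_class_freqs(r_target, "hexasomic"))
            for obs, exp in zip(counts / n, expected):
                assert abs(obs - exp) < 3 * mc_se(max(exp, 1e-3), n)


class TestSimulateCross:
    def _default_pair(self, rng, **kwargs):
        maternal = meiosis.build_parent("M", n_chromosomes=2, sda_per_homolog=3, rng=rng)
        paternal = meiosis.build_parent(
            "P", n_chromosomes=2, sda_per_homolog=3,
            asgr=meiosis.AsgrLocus("chr1", 50.0, 0), rng=rng)
        return maternal, paternal

    def test_selfs_carry_no_paternal_alleles(self, rng):
        maternal, paternal = self._default_pair(rng)
        pop = meiosis.simulate_cross(maternal, paternal, n_progeny=40, n_selfs=10,
                                     rng=rng)
        pat = np.array(pop.marker_parent) == meiosis.PATERNAL
        selfs = pop.origin == meiosis.SELF
        assert selfs.sum() == 10
        assert pop.dosage[np.ix_(pat, selfs)].sum() == 0

    def test_apomictic_fraction_half(self, rng):
        maternal, paternal = self._default_pair(rng)
        pop = meiosis.simulate_cross(maternal, paternal, n_progeny=10_000, n_selfs=0,
                                     undetermined_rate=0.0, rng=rng)
        frac = (pop.phenotype == meiosis.APOMICTIC).mean()
        assert abs(frac - 0.5) < 3 * mc_se(0.5, 10_000)
        assert np.array_equal(pop.phenotype == meiosis.APOMICTIC, pop.asgr_paternal)

    def test_dosage_bounded_by_copy_number(self, rng):
        maternal, paternal = self._default_pair(rng)
        pop = meiosis.simulate_cross(maternal, paternal, n_progeny=50, rng=rng)
        assert np.all(pop.dosage <= pop.marker_copy_number())

    def test_identical_seed_reproduces_population(self):
        def build(seed):
            rng = np.random.default_rng(seed)
            maternal = meiosis.build_parent("M", n_chromosomes=2, sda_per_homolog=3,
                                            dda_per_chromosome=4, rng=rng)
            paternal = meiosis.build_parent("P", n_chromosomes=2, sda_per_homolog=3,
                                            rng=rng)
            return meiosis.simulate_cross(maternal, paternal, n_progeny=30, rng=rng)

        a, b = build(7), build(7)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.copy_number, b.copy_number)
        assert list(a.phenotype) == list(b.phenotype)

    def test_mismatched_chromosomes_rejected(self, rng):
        maternal = meiosis.build_parent("M", n_chromosomes=2, sda_per_homolog=2, rng=rng)
        paternal = meiosis.build_parent("P", n_chromosomes=3, sda_per_homolog=2, rng=rng)
        with pytest.raises(ValueError):
            meiosis.simulate_cross(maternal, paternal, n_progeny=10, rng=rng)

    def test_asgr_on_missing_chromosome_rejected(self):
        chrom = meiosis.ChromosomeSpec("c", 6, np.array([0.0]), ["m"],
                                       [frozenset([0])])
        with pytest.raises(KeyError):
            meiosis.ParentalGenome([chrom], asgr=meiosis.AsgrLocus("zz", 1.0, 0))


class TestSimulateReads:
    def _population(self, rng, copies=6, dose=1):
        chrom = meiosis.ChromosomeSpec("c", copies, np.array([0.0]), ["Mm"],
                                       [frozenset(range(dose))])
        maternal = meiosis.ParentalGenome([chrom])
        paternal = meiosis.ParentalGenome([meiosis.ChromosomeSpec(
            "c", copies, np.empty(0), [], [])])
        return meiosis.simulate_cross(maternal, paternal, n_progeny=200, rng=rng)

    def test_extreme_dosages(self, rng):
        pop = self._population(rng, dose=6)  # every homolog carries the allele
        ref, alt = meiosis.simulate_reads(pop, meiosis.ReadModel(mean_depth=30), rng)
        full = pop.dosage == pop.marker_copy_number()
        zero = pop.dosage == 0
        assert np.all(ref[full] == 0)
        assert np.all(alt[zero] == 0)

    def test_mean_alt_fraction_matches_dosage(self, rng):
        pop = self._population(rng)
        ref, alt = meiosis.simulate_reads(pop, meiosis.ReadModel(mean_depth=60), rng)
        carriers = pop.dosage[0] == 1
        frac = alt[0, carriers] / (alt[0, carriers] + ref[0, carriers])
        assert abs(frac.mean() - 1 / 6) < 0.02

    def test_tag_copies_raises_alt_fraction(self, rng):
        pop = self._population(rng)
        model = meiosis.ReadModel(mean_depth=60, tag_copies=4)
        ref, alt = meiosis.simulate_reads(pop, model, rng)
        carriers = pop.dosage[0] == 1
        frac = alt[0, carriers] / (alt[0, carriers] + ref[0, carriers])
        assert abs(frac.mean() - 0.25) < 0.02

    def test_negative_binomial_family_validated(self):
        with pytest.raises(ValueError):
            meiosis.ReadModel(family="negative-binomial")
        meiosis.ReadModel(family="negative-binomial", dispersion=2.0)
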