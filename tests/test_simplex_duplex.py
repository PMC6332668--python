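"""Closed-form SDA-DDA coupling model, its enumeration oracle, and tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polykaryo import simplex_duplex as sd


class TestExpectedClassFreqs:
    @pytest.mark.parametrize("model,expected", [
        ("hexasomic", (0.5, 0.0, 0.3, 0.2)),
        ("tetrasomic", (0.5, 0.0, 1 / 3, 1 / 6)),
    ])
    def test_complete_coupling(self, model, expected):
        assert sd.expected_class_freqs(0.0, model) == pytest.approx(expected, abs=1e-15)

    def test_independence_factorises_at_half(self):
        # at r = 0.5 each class is the product of the marginals
        for model, p_b in (("tetrasomic", 5 / 6), ("hexasomic", 4 / 5)):
            p = sd.expected_class_freqs(0.5, model)
            expected = (0.5 * p_b, 0.5 * (1 - p_b), 0.5 * p_b, 0.5 * (1 - p_b))
            assert p == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("r", [-0.01, 0.51, 1.0])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            sd.expected_class_freqs(r, "hexasomic")

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            sd.expected_class_freqs(0.1, "disomic")

    @given(st.floats(min_value=0.0, max_value=0.5))
    def test_probability_and_marginal_invariants(self, r):
        for model, p_b in (("tetrasomic", 5 / 6), ("hexasomic", 4 / 5)):
            p_ab, p_a, p_b_only, p_0 = sd.expected_class_freqs(r, model)
            probs = (p_ab, p_a, p_b_only, p_0)
            assert all(0.0 <= x <= 1.0 for x in probs)
            assert sum(probs) == pytest.approx(1.0, abs=1e-12)
            assert p_ab + p_a == pytest.approx(0.5, abs=1e-12)  # SDA marginal
            assert p_ab + p_b_only == pytest.approx(p_b, abs=1e-12)  # DDA marginal

    def test_p_ab_monotone_decreasing_p_a_increasing(self):
        grid = np.linspace(0, 0.5, 26)
        for model in ("tetrasomic", "hexasomic"):
            mat = sd.class_prob_matrix(grid, model)
            assert np.all(np.diff(mat[:, 0]) < 0)
            assert np.all(np.diff(mat[:, 1]) > 0)


class TestEnumerationOracle:
    @pytest.mark.parametrize("model", ["tetrasomic", "hexasomic"])
    def test_matches_closed_form_on_grid(self, model):
        for r in np.linspace(0.0, 0.5, 51):
            closed = np.array(sd.expected_class_freqs(r, model))
            enum = np.array(sd.enumerate_class_freqs(r, model))
            assert np.allclose(closed, enum, atol=1e-12)

    def test_matching_counts(self):
        assert len(sd.perfect_matchings(range(6))) == 15
        assert len(sd.perfect_matchings(range(4))) == 3
        with pytest.raises(ValueError):
            sd.perfect_matchings(range(5))

    @pytest.mark.parametrize("n,dose,gamete,expected", [
        (6, 2, 3, 4.0),   # duplex, hexasomic: presence:absence 4:1
        (4, 2, 2, 5.0),   # duplex, tetrasomic: 5:1
        (6, 1, 3, 1.0),   # simplex: 1:1
    ])
    def test_dosage_ratios_by_enumeration(self, n, dose, gamete, expected):
        present, absent, ratio = sd.enumerate_presence_ratio(n, dose, gamete)
        assert ratio == expected


class TestIndependenceTest:
    def test_exact_independence_gives_zero(self):
        counts = (100 * np.array(sd.expected_class_freqs(0.5, "hexasomic"))).astype(int)
        res = sd.independence_test(sd.ContingencyAB(*counts, model="hexasomic"))
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert not res.linked

    def test_complete_coupling_pattern(self):
        # 100 x freqs(0) hexasomic = (50, 0, 30, 20) vs expected (40, 10, 40, 10):
        # chi2 = 100/40 + 100/10 + 100/40 + 100/10 = 25
        res = sd.independence_test(sd.ContingencyAB(50, 0, 30, 20, model="hexasomic"))
        assert res.chi2 == pytest.approx(25.0)
        assert res.p_value < 1e-4
        assert res.linked

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            sd.independence_test(sd.ContingencyAB(0, 0, 0, 0))

    def test_ab_deficit_not_called_linked(self):
        # strong association but AB below expectation -> repulsion, not coupling
        res = sd.independence_test(sd.ContingencyAB(10, 40, 40, 10, model="hexasomic"))
        assert res.p_value < 0.05
        assert not res.linked


class TestEstimateR:
    def test_self_consistency_at_expected_counts(self):
        counts = (1000 * np.array(sd.expected_class_freqs(0.2, "hexasomic")))
        est = sd.estimate_r_ml(sd.ContingencyAB(*counts.astype(int), model="hexasomic"))
        assert est.r == pytest.approx(0.2, abs=1e-3)
        assert not est.at_boundary

    def test_complete_coupling_hits_lower_boundary(self):
        est = sd.estimate_r_ml(sd.ContingencyAB(50, 0, 30, 20, model="hexasomic"))
        assert est.r <= 1e-5
        assert est.at_boundary

    @pytest.mark.parametrize("r,model", [
        (0.05, "hexasomic"), (0.3, "hexasomic"), (0.15, "tetrasomic")])
    def test_agrees_with_grid_search_oracle(self, r, model, rng):
        probs = sd.expected_class_freqs(r, model)
        for _ in range(10):
            counts = rng.multinomial(500, probs)
            table = sd.ContingencyAB(*counts, model=model)
            assert sd.estimate_r_ml(table).r == pytest.approx(
                sd.estimate_r_grid(table), abs=1e-3)

    def test_degenerate_counts_flagged(self):
        est = sd.estimate_r_ml(sd.ContingencyAB(100, 0, 0, 0))
        assert est.degenerate

    def test_recovery_bias_small_at_large_n(self, rng):
        probs = sd.expected_class_freqs(0.1, "hexasomic")
        r_hats = [sd.estimate_r_ml(sd.ContingencyAB(*rng.multinomial(1000, probs),
                                                    model="hexasomic")).r
                  for _ in range(200)]
        assert abs(np.mean(r_hats) - 0.1) < 0.02


class TestUniformityTest:
    def test_uniform_counts_give_zero(self):
        res = sd.subgenome_uniformity_test([2] * 15)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 14

    def test_subgenome_concentration(self):
        # 30 duplexes on 6 of 15 pairs, uniform there: chi2 = 27 + 18 = 45
        counts = [5] * 6 + [0] * 9
        res = sd.subgenome_uniformity_test(counts)
        assert res.chi2 == pytest.approx(45.0)
        assert res.df == 14
        assert res.p_value < 1e-4

    def test_small_sample_flag_and_empty_error(self):
        assert sd.subgenome_uniformity_test([1] * 10 + [0] * 5).small_sample
        with pytest.raises(ValueError):
            sd.subgenome_uniformity_test([0] * 15)

    def test_pair_count_helper(self):
        assert [sd.n_homolog_pairs(k) for k in (5, 6, 7)] == [10, 15, 21]


class TestAssignDda:
    def _make_groups(self, rng, n=102, markers_per_group=6):
        """Truth-based single-chromosome presence data: 6 homolog groups."""
        from polykaryo import meiosis

        positions = np.linspace(0, 100, markers_per_group)
        names, carrs, pos = [], [], []
        for h in range(6):
            for i, p in enumerate(positions):
                names.append(f"h{h}m{i}")
                carrs.append(frozenset([h]))
                pos.append(p)
        names.append("dda")
        carrs.append(frozenset([0, 1]))
        pos.append(50.0)
        order = np.argsort(pos, kind="stable")
        chrom = meiosis.ChromosomeSpec("c", 6, np.array(pos)[order],
                                       [names[i] for i in order],
                                       [carrs[i] for i in order])
        genome = meiosis.ParentalGenome([chrom])
        other = meiosis.ParentalGenome([meiosis.ChromosomeSpec(
            "c", 6, np.empty(0), [], [])])
        pop = meiosis.simulate_cross(other, genome, n_progeny=n, n_selfs=0,
                                     undetermined_rate=0.0, rng=rng)
        pres = pop.presence()
        idx = {m: i for i, m in enumerate(pop.marker_names)}
        groups = {h: pres[[idx[f"h{h}m{i}"] for i in range(markers_per_group)]]
                  for h in range(6)}
        return groups, pres[idx["dda"]]

    def test_duplex_assigned_to_carrier_pair(self, rng):
        hits = 0
        for _ in range(30):
            groups, dda = self._make_groups(rng)
            res = sd.assign_dda(dda, groups, model="hexasomic", dda_id="dda")
            if res.pair == (0, 1):
                hits += 1
        assert hits >= 20  # carrier homologs recovered in most replicates

    def test_unlinked_duplex_unassigned(self, rng):
        misses = 0
        for _ in range(20):
            groups, _ = self._make_groups(rng)
            unlinked = (rng.random(102) < 0.8).astype(np.int8)  # independent 4:1
            res = sd.assign_dda(unlinked, groups, model="hexasomic")
            if res.pair is None:
                misses += 1
        assert misses >= 18

    def test_bulk_matches_single(self, rng):
        groups, dda = self._make_groups(rng)
        labels = np.concatenate([[h] * 6 for h in range(6)])
        sda = np.vstack([groups[h] for h in range(6)])
        single = sd.assign_dda(dda, groups, model="hexasomic")
        bulk = sd.assign_dda_bulk(dda[None, :], ["hexasomic"], sda, labels)[0]
        assert bulk.pair == single.pair
        for g in range(6):
            assert bulk.group_scores[g] == pytest.approx(single.group_scores[g])
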