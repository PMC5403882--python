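"""Structure tests of the column and ring builders."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1micro import network as nw
from v1micro import params as P


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (100, (46, 30, 24)),
        (0, (0, 0, 0)),
        (1459, (671, 438, 350)),  # the full-size superficial count
    ])
    def test_examples(self, n, expected):
        assert nw.split_superficial_inhibitory(n) == expected

    @given(st.integers(min_value=0, max_value=20000))
    @settings(max_examples=100, deadline=None)
    def test_conserves_total(self, n):
        pv, sst, vip = nw.split_superficial_inhibitory(n)
        assert pv + sst + vip == n
        assert min(pv, sst, vip) >= 0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            nw.split_superficial_inhibitory(-1)


class TestAllocate:
    def test_proportional_with_largest_remainder(self):
        # quotas (470.588, 470.588, 58.824): the largest fractional
        # remainder (0.824) takes the first leftover synapse
        out = nw.allocate_inhibitory_synapses(1000, [1, 1, 0.125], [1, 1, 1])
        assert list(out) == [471, 470, 59]

    def test_zero_budget(self):
        assert list(nw.allocate_inhibitory_synapses(
            0, [1, 1, 0.125], [10, 10, 10])) == [0, 0, 0]

    def test_single_nonzero_weight_takes_all(self):
        assert list(nw.allocate_inhibitory_synapses(
            777, [0, 2.5, 0], [5, 5, 5])) == [0, 777, 0]

    def test_zero_total_weight_errors(self):
        with pytest.raises(ValueError):
            nw.allocate_inhibitory_synapses(10, [0, 0], [1, 1])

    @given(st.integers(min_value=0, max_value=100000),
           st.lists(st.floats(min_value=0, max_value=10), min_size=2,
                    max_size=6),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_budget_conserved(self, budget, weights, data):
        sizes = data.draw(st.lists(
            st.integers(min_value=1, max_value=5000),
            min_size=len(weights), max_size=len(weights)))
        if sum(w * s for w, s in zip(weights, sizes)) <= 0:
            return
        out = nw.allocate_inhibitory_synapses(budget, weights, sizes)
        assert out.sum() == budget
        assert np.all(out >= 0)


class TestIncRatio:
    def test_identity(self):
        assert nw.inc_ratio_check(-100.0, 2.0, 0.5, -100.0, 2.0, 0.5) == 1.0

    def test_peak_scaling(self):
        assert nw.inc_ratio_check(-200.0, 2.0, 1.0, -100.0, 2.0, 1.0) == 2.0

    def test_sst_pathways_ratio(self):
        # SST->VIP vs SST->PV with equal decay and unit probability
        r = nw.inc_ratio_check(-525.8, 3.4, 1.0, -228.6, 3.4, 1.0)
        assert r == pytest.approx(2.30, abs=0.01)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            nw.inc_ratio_check(-1.0, 1.0, 1.0, -1.0, 1.0, 0.0)


class TestColumnLayout:
    def test_full_size_totals(self):
        pops = nw.column_populations(scale=1.0)
        total = sum(p.count for p in pops)
        assert total == 19294
        by_name = {p.name: p.count for p in pops}
        assert by_name["L23_Pyr"] == 5171
        assert by_name["L23_PV"] + by_name["L23_SST"] \
            + by_name["L23_VIP"] == 1459
        assert (by_name["L4_E"], by_name["L4_I"]) == (5479, 1370)
        assert (by_name["L5_E"], by_name["L5_I"]) == (1213, 266)
        assert (by_name["L6_E"], by_name["L6_I"]) == (3599, 737)

    def test_superficial_subtypes(self):
        by_name = {p.name: p.count for p in nw.column_populations(scale=1.0)}
        assert by_name["L23_PV"] == 671
        assert by_name["L23_SST"] == 438
        assert by_name["L23_VIP"] == 350


class TestBuild:
    def test_determinism(self):
        g1 = nw.build_network(n_columns=13, scale=0.02, seed=9)
        g2 = nw.build_network(n_columns=13, scale=0.02, seed=9)
        for attr in ("pre", "post", "weight", "delay", "channel", "rule_id"):
            assert np.array_equal(getattr(g1, attr), getattr(g2, attr))

    def test_validation_passes(self, small_column):
        report = nw.validate_network(small_column)
        assert report["ok"], report["failures"]
        assert report["dale_violations"] == 0

    def test_planted_sign_flip_detected(self, small_column):
        import copy
        g = copy.copy(small_column)
        g.weight = small_column.weight.copy()
        inh = np.where(g.weight < 0)[0]
        g.weight[inh[0]] *= -1
        report = nw.validate_network(g)
        assert report["dale_violations"] == 1

    def test_counts_within_binomial_bounds_over_seeds(self):
        for seed in range(10):
            g = nw.build_network(n_columns=1, scale=0.05, seed=seed)
            counts = nw.expected_rule_counts(g)
            assert np.all(np.abs(counts["z"]) <= 5.0), \
                counts[np.abs(counts["z"]) > 5.0]

    def test_l4e_to_pyr_exception_weight(self, small_column):
        g = small_column
        a4, b4 = g.index_range("L4_E")
        ap, bp = g.index_range("L23_Pyr")
        mask = ((g.pre >= a4) & (g.pre < b4)
                & (g.post >= ap) & (g.post < bp))
        assert mask.any()
        assert g.weight[mask].mean() == pytest.approx(245.84, rel=0.05)

    def test_superficial_interneurons_treated_alike_interlaminar(
            self, small_column):
        # each L2/3 interneuron class receives L4E input at the same
        # probability: realised in-degree per neuron statistically equal
        g = small_column
        a4, b4 = g.index_range("L4_E")
        deg = {}
        for name in ("L23_PV", "L23_SST", "L23_VIP"):
            a, b = g.index_range(name)
            mask = (g.pre >= a4) & (g.pre < b4) & (g.post >= a) & (g.post < b)
            deg[name] = mask.sum() / (b - a)
        vals = np.array(list(deg.values()))
        assert vals.std() / vals.mean() < 0.25

    def test_reach_error_for_small_rings(self):
        with pytest.raises(ValueError, match="reach"):
            nw.build_network(n_columns=2, scale=0.02, seed=0)

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            nw.build_network(n_columns=13, scale=0.02, seed=0,
                             prob_overrides={"Pyr->Sst": 0.04})


class TestRing:
    def test_sst_intercolumnar_sources_span_four_columns(self, small_ring):
        # an SST cell in ring position 6 receives long-range excitation
        # from exactly the eight columns at offsets +-1..+-4
        g = small_ring
        src_cols = set()
        for tag in g.rule_names:
            name, cols = tag.split("@")
            if name == "L23_Pyr->L23_SST:inter":
                c_src, c_tgt = (int(c[1:]) for c in cols.split("->"))
                if c_tgt == 6:
                    src_cols.add(c_src)
        assert src_cols == {2, 3, 4, 5, 7, 8, 9, 10}

    def test_intercolumnar_links_are_superficial_only(self, small_ring):
        g = small_ring
        pop_of = g.population_of()
        pre_pop = pop_of[g.pre]
        post_pop = pop_of[g.post]
        pre_col = np.array([p.column for p in g.populations])[pre_pop]
        post_col = np.array([p.column for p in g.populations])[post_pop]
        names = np.array([p.name for p in g.populations])
        cross = pre_col != post_col
        assert np.all(np.char.startswith(names[pre_pop[cross]], "L23"))
        assert np.all(np.char.startswith(names[post_pop[cross]], "L23"))
        # and only the four allowed pathways
        pairs = set(zip(names[pre_pop[cross]], names[post_pop[cross]]))
        assert pairs <= {("L23_Pyr", "L23_Pyr"), ("L23_Pyr", "L23_PV"),
                         ("L23_PV", "L23_Pyr"), ("L23_Pyr", "L23_SST")}

    def test_intercolumnar_delays_five_times_longer(self, small_ring):
        g = small_ring
        pop_of = g.population_of()
        cols = np.array([p.column for p in g.populations])
        names = np.array([p.name for p in g.populations])
        cross = cols[pop_of[g.pre]] != cols[pop_of[g.post]]
        exc_pre = np.char.startswith(names[pop_of[g.pre]], "L23_Pyr")
        intra_exc = g.delay[~cross & exc_pre]
        inter_exc = g.delay[cross & exc_pre]
        assert inter_exc.mean() / intra_exc.mean() == pytest.approx(5.0,
                                                                    rel=0.1)

    def test_homogeneous_in_degree_by_symmetry(self, small_ring):
        g = small_ring
        pop_of = g.population_of()
        cols = np.array([p.column for p in g.populations])
        in_deg = np.bincount(g.post, minlength=g.n_neurons)
        per_col = np.array([in_deg[(cols[pop_of] == c)].mean()
                            for c in range(13)])
        assert per_col.std() / per_col.mean() < 0.05


class TestScaleCompensation:
    @pytest.mark.parametrize("mode", ["probability", "weight"])
    def test_in_degree_weight_product_preserved(self, mode):
        # expected per-neuron in-degree x mean |weight| of a scaled build
        # matches the full-size value within 1% for each Bernoulli rule
        scale = 0.25
        g = nw.build_network(n_columns=1, scale=scale, seed=1,
                             compensation=mode)
        sizes_full = {p.name: p.count for p in nw.column_populations()}
        sizes_small = {p.name: p.count for p in g.populations}
        for rule in nw.column_rules(sizes_small):
            if rule.p is None:
                continue
            full = nw.column_rules(sizes_full)
            peer = next(r for r in full if r.name == rule.name)
            n_pre_f = sizes_full[rule.source]
            ref = peer.p * n_pre_f * abs(rule.syn.peak)
            if mode == "probability":
                p_eff = min(rule.p / scale, 1.0)
                w = abs(rule.syn.peak) * max(rule.p / scale, 1.0) \
                    if rule.p / scale > 1 else abs(rule.syn.peak)
                got = p_eff * sizes_small[rule.source] * w
            else:
                got = rule.p * sizes_small[rule.source] \
                    * abs(rule.syn.peak) / scale
            # population rounding at 25% scale costs < 1% per rule
            assert got == pytest.approx(ref, rel=0.01)

    def test_uncompensated_product_shrinks(self):
        g = nw.build_network(n_columns=1, scale=0.1, seed=1,
                             compensation="none")
        in_deg = np.bincount(g.post, minlength=g.n_neurons).mean()
        g_full_sizes = {p.name: p.count for p in nw.column_populations()}
        # expected full-size mean in-degree is ~10x larger
        full_syn = sum(
            (r.p * g_full_sizes[r.source] * g_full_sizes[r.target]
             if r.p is not None else r.budget)
            for r in nw.column_rules(g_full_sizes))
        full_in_deg = full_syn / 19294
        assert in_deg < 0.2 * full_in_deg


class TestSpecValidation:
    def test_synapse_spec_rejects_zero_peak(self):
        with pytest.raises(ValueError):
            nw.SynapseTypeSpec("a", "b", 0.0, 1.0, 2.0, 1.5, 0.5)

    def test_rule_needs_exactly_one_mode(self):
        syn = nw.SynapseTypeSpec("a", "b", 100.0, 1.0, 2.0, 1.5, 0.5)
        with pytest.raises(ValueError):
            nw.ConnectionRule("a", "b", syn, p=0.1, budget=10)
        with pytest.raises(ValueError):
            nw.ConnectionRule("a", "b", syn, p=1.5)
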