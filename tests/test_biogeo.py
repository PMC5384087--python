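"""Time-stratified DEC: state space, rate matrix, likelihood (against an
exhaustive enumeration oracle), ancestral ranges and event counting."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy.linalg import expm

from pterodiv import biogeo, trees
from pterodiv.biogeo import (
    AreaSystem,
    DECParams,
    DispersalSchedule,
    StateSpace,
    ancestral_ranges,
    branch_transition,
    build_rate_matrix,
    count_colonizations,
    count_in_situ_speciation,
    dec_loglik,
    enumerate_states,
    fit_dec,
)

AREAS2 = AreaSystem(("A", "B"), ("a", "b"))
AREAS3 = AreaSystem(("A", "B", "C"), ("a", "b", "c"))
SCHED2 = DispersalSchedule.uniform(2)
SCHED3 = DispersalSchedule.uniform(3)


# ---------------------------------------------------------------------------
# independent enumeration oracle (kept deliberately naive)
# ---------------------------------------------------------------------------


def oracle_states(n_areas, max_size):
    out = []
    for size in range(1, max_size + 1):
        for comb in combinations(range(n_areas), size):
            out.append(frozenset(comb))
    return sorted(out, key=lambda s: (len(s), sorted(s)))


def oracle_Q(states, n_areas, d, e, mult):
    """Generator over observable states + null, built from the definitions."""
    allst = list(states) + [frozenset()]
    idx = {s: i for i, s in enumerate(allst)}
    max_size = max(len(s) for s in states)
    Q = np.zeros((len(allst), len(allst)))
    for s in states:
        i = idx[s]
        if len(s) < max_size:
            for j in range(n_areas):
                if j not in s:
                    rate = d * sum(mult[a][j] for a in s)
                    Q[i, idx[s | {j}]] += rate
        for a in s:
            Q[i, idx[s - {a}]] += e
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, idx


def oracle_clado(state):
    """Ordered daughter pairs with weights: 2|S| scenarios of weight
    1/(2|S|); each non-degenerate scenario contributes both orders at full
    scenario weight."""
    if len(state) == 1:
        return [(state, state, 1.0)]
    w = 1.0 / (2 * len(state))
    pairs = []
    for a in state:
        single = frozenset({a})
        for other in (state - single, state):
            pairs.append((single, other, w))
            pairs.append((other, single, w))
    return pairs


def oracle_loglik(tree, tip_ranges, n_areas, max_size, d, e):
    """Exhaustive: recursively sum over daughter start states and anagenetic
    transitions, flat root prior over observable states."""
    states = oracle_states(n_areas, max_size)
    mult = [[1.0] * n_areas for _ in range(n_areas)]
    Q, idx = oracle_Q(states, n_areas, d, e, mult)
    ages = tree.node_ages()

    def P(dt):
        return expm(Q * dt)

    def below(node, state):
        """P(data below node | lineage at node occupies `state`)."""
        if node < tree.n_tips:
            obs = frozenset(
                "ABC".index(c) for c in tip_ranges[tree.tip_labels[node]]
            )
            return 1.0 if state == obs else 0.0
        total = 0.0
        kids = tree.children[node]
        for m1, m2, w in oracle_clado(state):
            term = w
            for child, start in zip(kids, (m1, m2)):
                Pm = P(ages[node] - ages[child])
                s = 0.0
                for end in states:
                    s += Pm[idx[start], idx[end]] * below(child, end)
                term *= s
            total += term
        return total

    root = tree.postorder[-1]
    prior = 1.0 / len(states)
    lik = sum(prior * below(root, s) for s in states)
    return np.log(lik) if lik > 0 else -np.inf


# ---------------------------------------------------------------------------


class TestEnumerateStates:
    def test_nine_areas_max_four(self):
        states = enumerate_states(biogeo.DEFAULT_AREAS, 4)
        assert len(states) - 1 == 255  # C(9,1)+C(9,2)+C(9,3)+C(9,4)
        assert states[-1] == 0  # null appended last

    def test_two_areas(self):
        states = enumerate_states(AREAS2, 2)
        assert states[:-1] == [0b01, 0b10, 0b11]

    def test_max_size_out_of_range(self):
        with pytest.raises(ValueError):
            StateSpace(AREAS3, 5)

    def test_canonical_order(self):
        states = enumerate_states(AREAS3, 3)[:-1]
        sizes = [bin(m).count("1") for m in states]
        assert sizes == sorted(sizes)


class TestRateMatrix:
    def test_definition_entries(self):
        sp = StateSpace(AREAS2, 2)
        Q = build_rate_matrix(sp, DECParams(0.1, 0.05), np.ones((2, 2)))
        iA, iB, iAB = sp.index[1], sp.index[2], sp.index[3]
        assert Q[iA, iAB] == pytest.approx(0.1)
        assert Q[iAB, iA] == pytest.approx(0.05)
        assert Q[iA, iB] == 0.0  # no direct range switching
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_null_absorbing_and_singleton_loss(self):
        sp = StateSpace(AREAS2, 2)
        Q = build_rate_matrix(sp, DECParams(0.1, 0.05), np.ones((2, 2)))
        assert np.allclose(Q[sp.null_index], 0.0)
        assert Q[sp.index[1], sp.null_index] == pytest.approx(0.05)

    def test_multiplier_weighting(self):
        sp = StateSpace(AREAS3, 2)
        m = np.ones((3, 3))
        m[0, 2] = 0.25
        Q = build_rate_matrix(sp, DECParams(0.2, 0.0), m)
        # {A} -> {A,C} at d * m[A][C]
        assert Q[sp.index[1], sp.index[0b101]] == pytest.approx(0.2 * 0.25)

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            DECParams(-0.1, 0.0)


class TestBranchTransition:
    def test_zero_span_identity(self):
        sp = StateSpace(AREAS2, 2)
        Q = build_rate_matrix(sp, DECParams(0.1, 0.05), np.ones((2, 2)))
        P = branch_transition([Q] * 3, SCHED2, 4.0, 4.0)
        assert np.allclose(P, np.eye(sp.n_states))

    def test_zero_rates_identity(self):
        sp = StateSpace(AREAS2, 2)
        Q = build_rate_matrix(sp, DECParams(0.0, 0.0), np.ones((2, 2)))
        P = branch_transition([Q] * 3, SCHED2, 9.5, 0.0)
        assert np.allclose(P, np.eye(sp.n_states))

    def test_rows_sum_to_one(self):
        sp = StateSpace(AREAS3, 3)
        Qs = [build_rate_matrix(sp, DECParams(0.3, 0.1), m)
              for m in SCHED3.multipliers]
        P = branch_transition(Qs, SCHED3, 10.0, 1.0)
        # null row is absorbing; observable rows are stochastic
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(P >= 0)

    def test_single_slice_matches_direct_expm(self):
        sp = StateSpace(AREAS2, 2)
        Q = build_rate_matrix(sp, DECParams(0.17, 0.06), np.ones((2, 2)))
        P = branch_transition([Q], DispersalSchedule.uniform(2, [50.0, 0.0]),
                              7.0, 2.5)
        assert np.allclose(P, expm(Q * 4.5), atol=1e-10)

    def test_ages_beyond_schedule_extend_oldest(self):
        sp = StateSpace(AREAS2, 2)
        Q = build_rate_matrix(sp, DECParams(0.1, 0.0), np.ones((2, 2)))
        P = branch_transition([Q] * 3, SCHED2, 30.0, 12.0)  # never errors
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)


class TestDECLoglik:
    def test_cherry_identical_tips_zero_rates(self, cherry):
        ll = dec_loglik(cherry, {"A": "A", "B": "A"}, DECParams(0, 0),
                        SCHED2, areas=AREAS2, max_range_size=2)
        assert ll == pytest.approx(np.log(1 / 3), abs=1e-10)

    def test_cherry_vicariant_tips_zero_rates(self, cherry):
        ll = dec_loglik(cherry, {"A": "A", "B": "B"}, DECParams(0, 0),
                        SCHED2, areas=AREAS2, max_range_size=2)
        assert ll == pytest.approx(np.log((1 / 3) * (1 / 2)), abs=1e-10)

    def test_range_exceeding_cap_rejected(self, cherry):
        with pytest.raises(ValueError, match="A"):
            dec_loglik(cherry, {"A": "ABC", "B": "A"}, DECParams(0, 0),
                       SCHED3, areas=AREAS3, max_range_size=2)

    @pytest.mark.parametrize("nwk,tips", [
        ("(A:1,B:1);", {"A": "A", "B": "B"}),
        ("((A:1,B:1):1,C:2);", {"A": "A", "B": "AB", "C": "B"}),
        ("((A:1,B:1):1.5,(C:1.2,D:1.2):1.3);",
         {"A": "A", "B": "B", "C": "AB", "D": "A"}),
    ])
    def test_matches_enumeration_oracle(self, nwk, tips):
        t = trees.parse_newick(nwk)
        for d, e in product([0.0, 0.01, 0.1, 1.0], repeat=2):
            got = dec_loglik(t, tips, DECParams(d, e),
                             DispersalSchedule.uniform(2), areas=AREAS2,
                             max_range_size=2)
            want = oracle_loglik(t, tips, 2, 2, d, e)
            assert got == pytest.approx(want, abs=1e-6), (d, e)

    def test_oracle_three_areas(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": "AC", "B": "B", "C": "C"}
        for d, e in [(0.05, 0.0), (0.1, 0.1), (1.0, 0.01)]:
            got = dec_loglik(t, tips, DECParams(d, e), SCHED3, areas=AREAS3,
                             max_range_size=2)
            want = oracle_loglik(t, tips, 3, 2, d, e)
            assert got == pytest.approx(want, abs=1e-6)

    def test_label_permutation_invariance(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        d, e = 0.2, 0.05
        base = dec_loglik(t, {"A": "A", "B": "B", "C": "AB"}, DECParams(d, e),
                          SCHED2, areas=AREAS2, max_range_size=2)
        swapped = dec_loglik(t, {"A": "B", "B": "A", "C": "AB"},
                             DECParams(d, e), SCHED2, areas=AREAS2,
                             max_range_size=2)
        assert base == pytest.approx(swapped, abs=1e-10)

    def test_slice_consistency(self):
        t = trees.parse_newick("((A:2,B:2):5,C:7);")
        tips = {"A": "A", "B": "AB", "C": "B"}
        p = DECParams(0.15, 0.04)
        multi = dec_loglik(t, tips, p, DispersalSchedule.uniform(2),
                           areas=AREAS2, max_range_size=2)
        single = dec_loglik(
            t, tips, p, DispersalSchedule.uniform(2, [11.0, 0.0]),
            areas=AREAS2, max_range_size=2)
        assert multi == pytest.approx(single, abs=1e-10)

    def test_conflicting_tips_less_likely(self, cherry):
        for rate in (0.01, 0.05, 0.2):
            p = DECParams(rate, rate)
            same = dec_loglik(cherry, {"A": "A", "B": "A"}, p, SCHED2,
                              areas=AREAS2, max_range_size=2)
            diff = dec_loglik(cherry, {"A": "A", "B": "B"}, p, SCHED2,
                              areas=AREAS2, max_range_size=2)
            assert same >= diff


class TestFitDEC:
    def test_identical_singleton_tips_hit_lower_bound(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        tips = {k: "A" for k in "ABCD"}
        fit = fit_dec(t, tips, SCHED2, areas=AREAS2, max_range_size=2,
                      seed=0, n_starts=3, with_ancestral=False)
        assert fit.params.d < 1e-6
        assert fit.params.e < 1e-6

    def test_dispersal_rate_recovery(self):
        """d simulated at 0.05 on 200-tip trees is recovered within a
        factor of 2 in at least 80% of 20 seeded replicates."""
        from pterodiv import simulate

        sched = DispersalSchedule.uniform(3)
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(8000 + s)
            t = simulate.simulate_yule_n_tips(200, 0.3, rng)
            hist = simulate.simulate_dec_history(
                t, DECParams(0.05, 0.01), sched, AREAS3, max_range_size=2,
                root_range="A", rng=rng, on_null="resimulate")
            fit = fit_dec(t, hist["tip_ranges"], sched, areas=AREAS3,
                          max_range_size=2, seed=s, n_starts=3,
                          with_ancestral=False)
            hits += 0.025 <= fit.params.d <= 0.1
        assert hits >= 16

    def test_seeded_determinism(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        tips = {"A": "A", "B": "AB", "C": "B", "D": "A"}
        f1 = fit_dec(t, tips, SCHED2, areas=AREAS2, max_range_size=2,
                     seed=7, n_starts=3, with_ancestral=False)
        f2 = fit_dec(t, tips, SCHED2, areas=AREAS2, max_range_size=2,
                     seed=7, n_starts=3, with_ancestral=False)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik


class TestAncestralRanges:
    def test_cherry_certain_root(self, cherry):
        rec = ancestral_ranges(cherry, {"A": "A", "B": "A"}, DECParams(0, 0),
                               SCHED2, areas=AREAS2, max_range_size=2)
        root = cherry.postorder[-1]
        sp = StateSpace(AREAS2, 2)
        assert rec.node_probs[root][sp.index[1]] == pytest.approx(1.0)

    def test_symmetry(self, cherry):
        rec = ancestral_ranges(cherry, {"A": "A", "B": "B"},
                               DECParams(0.1, 0.05), SCHED2, areas=AREAS2,
                               max_range_size=2)
        root = cherry.postorder[-1]
        sp = StateSpace(AREAS2, 2)
        assert rec.node_probs[root][sp.index[1]] == pytest.approx(
            rec.node_probs[root][sp.index[2]], abs=1e-10)

    def test_rows_normalized_and_tips_concentrated(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        rec = ancestral_ranges(t, {"A": "A", "B": "AB", "C": "B"},
                               DECParams(0.2, 0.05), SCHED2, areas=AREAS2,
                               max_range_size=2)
        assert np.allclose(rec.node_probs.sum(axis=1), 1.0, atol=1e-8)
        sp = StateSpace(AREAS2, 2)
        assert rec.node_probs[t.tip_index("B")][sp.index[3]] == pytest.approx(1.0)

    def test_root_marginal_consistent_with_total_likelihood(self):
        # prior-weighted conditional likelihood at the root reproduces logL
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": "A", "B": "B", "C": "AB"}
        p = DECParams(0.3, 0.1)
        sp = StateSpace(AREAS2, 2)
        eng = biogeo._DECEngine(t, tips, SCHED2, sp)
        _, L, _, scale = eng.up_pass(p)
        root = t.postorder[-1]
        total = eng.root_weights() @ L[root]
        assert np.log(total) + scale[root] == pytest.approx(
            dec_loglik(t, tips, p, SCHED2, areas=AREAS2, max_range_size=2),
            abs=1e-8)


class TestEventCounting:
    def _fake_recon(self, tree, letters_by_node, areas=AREAS2, max_size=2):
        sp = StateSpace(areas, max_size)
        probs = np.zeros((tree.n_nodes, sp.n_observable))
        best = np.zeros(tree.n_nodes, dtype=int)
        for node, letters in letters_by_node.items():
            mask = areas.mask_from_letters(letters)
            si = sp.index[mask]
            probs[node, si] = 1.0
            best[node] = si
        return biogeo.AncestralRanges(probs, list(sp.observable), areas, best)

    def test_all_in_focal(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        rec = self._fake_recon(t, {i: "A" for i in range(t.n_nodes)})
        count, frac = count_in_situ_speciation(t, rec, {"A"})
        assert (count, frac) == (2, 1.0)

    def test_no_overlap(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        rec = self._fake_recon(t, {i: "B" for i in range(t.n_nodes)})
        count, _ = count_in_situ_speciation(t, rec, {"A"})
        assert count == 0

    def test_hand_built_four_tip(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        # root {A,B}; left internal and its tips {A}; right side {B}
        idx = {t.tip_index(lab): lab for lab in "ABCD"}
        left = t.mrca(["A", "B"])
        right = t.mrca(["C", "D"])
        root = t.postorder[-1]
        letters = {t.tip_index("A"): "A", t.tip_index("B"): "A",
                   t.tip_index("C"): "B", t.tip_index("D"): "B",
                   left: "A", right: "B", root: "AB"}
        rec = self._fake_recon(t, letters)
        count, frac = count_in_situ_speciation(t, rec, {"A"})
        assert count == 1 and frac == pytest.approx(1 / 3)

    def test_empty_focal_rejected(self, cherry):
        rec = self._fake_recon(cherry, {0: "A", 1: "A", 2: "A"})
        with pytest.raises(ValueError):
            count_in_situ_speciation(cherry, rec, set())

    def test_colonization_definition(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        left = t.mrca(["A", "B"])
        root = t.postorder[-1]
        letters = {t.tip_index("A"): "AB", t.tip_index("B"): "B",
                   t.tip_index("C"): "B", left: "B", root: "B"}
        rec = self._fake_recon(t, letters)
        events = count_colonizations(t, rec, "A")
        assert len(events) == 1
        assert events[0]["branch_label"] == "A"
        lo, hi = events[0]["age_interval"]
        assert (lo, hi) == (1.0, 0.0)

    def test_no_colonization_when_area_absent(self):
        t = trees.parse_newick("((A:1,B:1):1,C:2);")
        rec = self._fake_recon(t, {i: "B" for i in range(t.n_nodes)})
        assert count_colonizations(t, rec, "A") == []

    def test_two_independent_gains(self):
        t = trees.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        left = t.mrca(["A", "B"])
        right = t.mrca(["C", "D"])
        root = t.postorder[-1]
        letters = {t.tip_index("A"): "A", t.tip_index("B"): "B",
                   t.tip_index("C"): "A", t.tip_index("D"): "B",
                   left: "B", right: "B", root: "B"}
        rec = self._fake_recon(t, letters)
        assert len(count_colonizations(t, rec, "A")) == 2

    def test_unknown_area_rejected(self, cherry):
        rec = self._fake_recon(cherry, {0: "A", 1: "A", 2: "A"})
        with pytest.raises(KeyError):
            count_colonizations(cherry, rec, "Z")
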