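"""Time-dependent birth-death likelihood, model selection, shift scan."""

import numpy as np
import pytest

from pterodiv import diversification as dv, simulate, trees
from pterodiv.diversification import (
    MODELS,
    BDModelSpec,
    BDParams,
    bd_loglik,
    fit_bd_models,
    rate_at,
    rate_through_time,
    shift_scan,
)

from conftest import random_chronogram


def yule_loglik_reference(bt, lam):
    """Closed-form crown-conditioned pure-birth log-likelihood, root
    speciation excluded: (n-2) log lam - lam * total branch length."""
    bt = np.asarray(bt, dtype=float)
    n = len(bt) + 1
    TL = 2 * bt[0] + bt[1:].sum()
    return (n - 2) * np.log(lam) - lam * TL


class TestRateAt:
    def test_constant(self):
        p = BDParams(0.2)
        assert rate_at(p, 5.0) == pytest.approx(0.2)

    def test_present_value(self):
        assert rate_at(BDParams(0.161, 0.110), 0.0) == pytest.approx(0.161)

    def test_exponential_growth_into_past(self):
        # the fitted study-scale numbers: 0.161 * e^{1.10} at 10 my
        assert rate_at(BDParams(0.161, 0.110), 10.0) == pytest.approx(
            0.161 * np.exp(1.10), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rate_at(BDParams(0.2), -1.0)

    def test_extinction_rate(self):
        p = BDParams(0.2, mu0=0.05, beta=0.1)
        assert rate_at(p, 2.0, "extinction") == pytest.approx(0.05 * np.exp(0.2))


class TestBDLoglik:
    def test_three_tip_yule_closed_form(self):
        bt = [2.0, 1.0]
        assert bd_loglik(bt, BDParams(0.2)) == pytest.approx(
            yule_loglik_reference(bt, 0.2), abs=1e-10)

    def test_yule_closed_form_random_trees(self, rng):
        for _ in range(20):
            t = random_chronogram(rng, int(rng.integers(3, 60)))
            lam = float(rng.uniform(0.05, 1.0))
            assert bd_loglik(t.branching_times(), BDParams(lam)) == pytest.approx(
                yule_loglik_reference(t.branching_times(), lam), abs=1e-7)

    def test_bvar_alpha_zero_nests_bcst(self, rng):
        t = random_chronogram(rng, 25)
        bt = t.branching_times()
        for lam in (0.1, 0.4):
            assert bd_loglik(bt, BDParams(lam, alpha=0.0)) == pytest.approx(
                bd_loglik(bt, BDParams(lam)), abs=1e-10)

    def test_mu_zero_collapses_extinction_models(self, rng):
        t = random_chronogram(rng, 25)
        bt = t.branching_times()
        for lam, a in [(0.2, 0.1), (0.5, -0.05)]:
            full = bd_loglik(bt, BDParams(lam, alpha=a, mu0=0.0, beta=0.3))
            pure = bd_loglik(bt, BDParams(lam, alpha=a))
            assert full == pytest.approx(pure, abs=1e-10)

    def test_gauss_matches_adaptive_quadrature(self, rng):
        t = random_chronogram(rng, 30)
        bt = t.branching_times()
        for _ in range(10):
            p = BDParams(float(rng.uniform(0.05, 0.5)),
                         float(rng.uniform(-0.3, 0.3)),
                         float(rng.uniform(0.01, 0.3)),
                         float(rng.uniform(-0.2, 0.2)))
            assert bd_loglik(bt, p, method="gauss") == pytest.approx(
                bd_loglik(bt, p, method="quad"), abs=1e-7)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bd_loglik([1.0, 2.0], BDParams(0.2))  # ascending
        with pytest.raises(ValueError):
            bd_loglik([2.0, 1.0], BDParams(0.2), f=0.0)

    def test_sampling_fraction_lowers_loglik_for_complete_data(self, rng):
        t = random_chronogram(rng, 20)
        bt = t.branching_times()
        p = BDParams(0.3)
        assert bd_loglik(bt, p, f=1.0) != bd_loglik(bt, p, f=0.5)


class TestModelTable:
    def test_six_canonical_models(self):
        assert set(MODELS) == {"BCST", "BVAR", "BCST-DCST", "BVAR-DCST",
                               "BCST-DVAR", "BVAR-DVAR"}
        assert [MODELS[m].k for m in
                ("BCST", "BVAR", "BCST-DCST", "BVAR-DCST", "BCST-DVAR",
                 "BVAR-DVAR")] == [1, 2, 2, 3, 3, 4]

    def test_dvar_requires_extinction(self):
        with pytest.raises(ValueError):
            BDModelSpec("bad", False, False, True)

    def test_aic_identity_and_ranking(self, rng):
        t = random_chronogram(rng, 60)
        fits = fit_bd_models(t, seed=3, n_starts=4)
        assert len(fits) == 6
        for ft in fits:
            assert ft.aic == pytest.approx(2 * ft.k - 2 * ft.loglik, abs=1e-12)
        assert fits[0].delta_aic == 0.0
        assert all(np.diff([ft.aic for ft in fits]) >= -1e-12)

    def test_nested_models_never_beat_supersets(self, rng):
        t = random_chronogram(rng, 60)
        fits = {ft.spec.name: ft for ft in fit_bd_models(t, seed=3, n_starts=4)}
        assert fits["BVAR"].loglik >= fits["BCST"].loglik - 1e-4
        assert fits["BVAR-DVAR"].loglik >= fits["BVAR-DCST"].loglik - 1e-4
        assert fits["BVAR-DCST"].loglik >= fits["BVAR"].loglik - 1e-4

    def test_table_arithmetic_printed_values(self):
        # AIC recomputed from a printed logL/k pair, and the printed gap
        aic_bvar = 2 * 2 - 2 * (-122.93)
        aic_bvar_dcst = 2 * 3 - 2 * (-122.93)
        assert round(aic_bvar, 2) == 249.86
        assert round(aic_bvar_dcst - aic_bvar, 2) == 2.00

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            fit_bd_models(np.array([1.0]), seed=0)

    def test_seeded_determinism(self, rng):
        t = random_chronogram(rng, 40)
        f1 = fit_bd_models(t, seed=11, n_starts=4)
        f2 = fit_bd_models(t, seed=11, n_starts=4)
        assert [(a.spec.name, a.loglik, a.aic) for a in f1] == \
               [(b.spec.name, b.loglik, b.aic) for b in f2]


class TestRateThroughTime:
    def test_flat_for_constant_model(self):
        ft = dv.BDFit(MODELS["BCST"], BDParams(0.25), -10.0, 1, 22.0)
        curve = rate_through_time(ft, crown_age=10.0)
        assert np.allclose(curve.rates, 0.25)

    def test_decreasing_toward_present(self):
        ft = dv.BDFit(MODELS["BVAR"], BDParams(0.16, 0.11), -10.0, 2, 24.0)
        curve = rate_through_time(ft, crown_age=10.6)
        assert curve.rates[0] == pytest.approx(0.16 * np.exp(0.11 * 10.6))
        assert curve.rates[-1] == pytest.approx(0.16)
        assert np.all(np.diff(curve.rates) < 0)

    def test_single_point_grid(self):
        ft = dv.BDFit(MODELS["BVAR"], BDParams(0.16, 0.11), -10.0, 2, 24.0)
        curve = rate_through_time(ft, times=[0.0])
        assert curve.rates == pytest.approx([0.16])

    def test_empty_grid_rejected(self):
        ft = dv.BDFit(MODELS["BCST"], BDParams(0.2), -10.0, 1, 22.0)
        with pytest.raises(ValueError):
            rate_through_time(ft, times=[])


def graft_fast_clade(seed, n_bg=40, n_clade=25, lam_bg=0.1, mult=10.0):
    """Background Yule tree with one tip replaced by a clade simulated at
    mult x the background speciation rate (natural depth preserved)."""
    import re

    rng = np.random.default_rng(seed)
    bg = simulate.simulate_yule_n_tips(n_bg, lam_bg, rng)
    cl = simulate.simulate_yule_n_tips(n_clade, lam_bg * mult, rng)
    cand = [i for i in range(bg.n_tips) if bg.lengths[i] > cl.crown_age + 0.1]
    if not cand:
        return None
    host = max(cand, key=lambda j: bg.lengths[j])
    lab = bg.tip_labels[host]
    clade = trees.Chronogram(
        cl.parent.copy(), cl.lengths,
        [f"cl{j + 1:04d}" for j in range(n_clade)], check_ultrametric=False)
    stub = bg.lengths[host] - cl.crown_age
    nwk = re.sub(rf"{lab}:[0-9.eE+-]+",
                 f"{clade.to_newick()[:-1]}:{stub:.17g}", bg.to_newick(),
                 count=1)
    return trees.parse_newick(nwk)


class TestShiftScan:
    def test_threshold_validation(self, cherry):
        with pytest.raises(ValueError):
            shift_scan([cherry], threshold=0.0)

    def test_homogeneous_trees_mostly_clean(self, rng):
        flagged = 0
        for _ in range(8):
            t = random_chronogram(rng, 45)
            res = shift_scan([t])
            flagged += bool(res.locations)
        assert flagged <= 2

    def test_fast_clade_detected(self):
        hits = 0
        for seed in range(4):
            t = graft_fast_clade(seed)
            if t is None:
                continue
            res = shift_scan([t])
            hits += any(
                loc["n_tips"] >= 13
                and all(x.startswith("cl") for x in loc["tip_set"])
                for loc in res.locations)
        assert hits >= 3

    def test_low_frequency_rule(self, rng):
        # a shift present in 1 of 25 trees (4%) is below the 5% rule
        trees_list = [random_chronogram(rng, 35) for _ in range(24)]
        shifted = graft_fast_clade(1)
        assert shifted is not None
        trees_list.append(shifted)
        res = shift_scan(trees_list, min_fraction=0.05)
        clade_locs = [loc for loc in res.locations
                      if any(x.startswith("cl") for x in loc["tip_set"])]
        assert clade_locs, "the injected shift must at least be located"
        assert all(loc["frequency"] < 0.05 for loc in clade_locs)
        for loc in clade_locs:
            assert loc not in res.significant

    def test_recurrent_shift_significant(self):
        # the same clade shifted in every tree crosses the frequency rule
        ts = [graft_fast_clade(s) for s in range(3)]
        ts = [t for t in ts if t is not None]
        res = shift_scan(ts, min_fraction=0.5)
        assert any(
            all(x.startswith("cl") for x in loc["tip_set"])
            for loc in res.significant)
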