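"""Per-recruit engine: ogives, expected compositions, SPR, and the fit."""

import numpy as np
import pytest
from scipy.stats import norm

from lenassess.core_data import LifeHistory
from lenassess.lbspr import (LN19, LengthComposition, SelectivityParams,
                             default_bin_edges, expected_length_composition,
                             fit_lbspr, maturity_at_length,
                             per_recruit_quantities, selectivity_at_length,
                             spawning_potential_ratio)


class TestOgives:
    def test_selectivity_anchors_exact(self, sel_2012):
        assert selectivity_at_length(39.0, sel_2012) == pytest.approx(0.5, abs=1e-12)
        assert selectivity_at_length(46.7, sel_2012) == pytest.approx(0.95, abs=1e-12)

    def test_selectivity_direct_evaluation(self, sel_2012):
        expect = 1.0 / (1.0 + np.exp(-LN19 * (43 - 39) / (46.7 - 39)))
        got = selectivity_at_length(43.0, sel_2012)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(0.822, abs=5e-4)

    def test_maturity_anchors_and_asymptote(self, lh):
        assert maturity_at_length(65.3, lh) == pytest.approx(0.5, abs=1e-12)
        assert maturity_at_length(lh.lm95, lh) == pytest.approx(0.95, abs=1e-12)
        assert maturity_at_length(300.0, lh) == pytest.approx(1.0, abs=1e-9)

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            SelectivityParams(50.0, 40.0)


class TestExpectedComposition:
    def test_proportions_sum_to_one(self, lh, sel_2012):
        for fm in (0.0, 0.7, 2.0):
            comp = expected_length_composition(lh, fm, sel_2012)
            assert comp.counts.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_group_matches_bruteforce_oracle(self, lh, sel_2012):
        """One growth-type group, annual ages: the engine must equal an
        independently coded survivorship × normal-binning sum to 1e-8."""
        edges = default_bin_edges(lh)
        fm = 1.5
        # brute-force oracle: explicit loops, no shared code path
        M, F, k = lh.m_nat, 1.5 * lh.m_nat, lh.k_growth
        mass = np.zeros(len(edges) - 1)
        n_a = 1.0
        for a in range(int(lh.tmax) + 1):
            mu = lh.l_inf * (1 - np.exp(-k * a))
            s = 1.0 / (1.0 + np.exp(-LN19 * (mu - sel_2012.sl50)
                                    / (sel_2012.sl95 - sel_2012.sl50))) if mu > 0 else 0.0
            if mu > 0:
                sd = lh.cv_linf * mu
                cdf = norm.cdf(edges, loc=mu, scale=sd)
                p = np.diff(cdf) / (cdf[-1] - cdf[0])
                mass += n_a * s * p
            n_a *= np.exp(-(M + F * s))
        oracle = mass / mass.sum()
        comp = expected_length_composition(lh, fm, sel_2012, edges, n_gtg=1)
        assert np.max(np.abs(comp.counts - oracle)) < 1e-8

    def test_unfished_unselected_equals_population_mixture(self, lh):
        """With F = 0 and flat selectivity the catch composition is the
        population length mixture itself."""
        edges = default_bin_edges(lh)
        wide = SelectivityParams(1e-6, 2e-6)  # ≈1 at any positive length
        comp = expected_length_composition(lh, 0.0, wide, edges, n_gtg=1)
        mass = np.zeros(len(edges) - 1)
        for a in range(int(lh.tmax) + 1):
            mu = lh.l_inf * (1 - np.exp(-lh.k_growth * a))
            if mu > 0:
                cdf = norm.cdf(edges, loc=mu, scale=lh.cv_linf * mu)
                mass += np.exp(-lh.m_nat * a) * np.diff(cdf) / (cdf[-1] - cdf[0])
        assert np.max(np.abs(comp.counts - mass / mass.sum())) < 1e-6

    def test_rescaling_counts_leaves_proportions(self, lh, sel_2012):
        comp = expected_length_composition(lh, 1.0, sel_2012)
        scaled = LengthComposition(comp.bin_edges, comp.counts * 489)
        assert np.allclose(scaled.proportions, comp.proportions)

    def test_cv_widens_composition(self, lh):
        """Larger CV L∞ cannot shrink the variance of the binned lengths."""
        sel = SelectivityParams(39.0, 46.7)
        variances = []
        for cv in (0.05, 0.10, 0.15):
            lh_cv = LifeHistory(l_inf=110, lm50=65.3, m_nat=0.29,
                                m_over_k=2.7, cv_linf=cv, tmax=21.0, am=6.5)
            comp = expected_length_composition(lh_cv, 1.98, sel)
            mids, p = comp.mids, comp.proportions
            m = np.sum(mids * p)
            variances.append(np.sum(p * (mids - m) ** 2))
        assert variances[0] < variances[1] < variances[2]

    def test_degenerate_grid_rejected(self, lh, sel_2012):
        with pytest.raises(ValueError):
            expected_length_composition(lh, 1.0, sel_2012, np.array([0.0, 2.0]))


class TestSPR:
    def test_unfished_spr_is_one(self, lh, sel_2012):
        assert spawning_potential_ratio(lh, 0.0, sel_2012) == pytest.approx(1.0, abs=1e-12)

    def test_heavy_fishing_drives_spr_to_zero(self, lh):
        sel = SelectivityParams(20.0, 25.0)  # recruits far below maturity
        assert spawning_potential_ratio(lh, 50.0, sel) < 1e-3

    def test_strictly_decreasing_in_f_over_m(self, lh, sel_2012):
        fms = [0.0, 0.25, 0.5, 1.0, 1.98, 3.0, 5.0]
        sprs = [spawning_potential_ratio(lh, fm, sel_2012) for fm in fms]
        assert all(a > b for a, b in zip(sprs, sprs[1:]))

    def test_invariants_of_per_recruit_quantities(self, lh, sel_2012):
        prq = per_recruit_quantities(lh, 1.98, sel_2012)
        assert prq.p_unfished > 0
        assert prq.spr == pytest.approx(prq.p_fished / prq.p_unfished)
        assert np.all(prq.z_at_age >= lh.m_nat - 1e-12)


class TestFit:
    def test_self_consistency_on_exact_proportions(self, lh):
        """Fitting the model's own expected composition (scaled to n = 1e5)
        must return the generating parameters within 1%."""
        truth_fm, truth_sel = 2.0, SelectivityParams(39.0, 47.0)
        comp = expected_length_composition(lh, truth_fm, truth_sel)
        obs = LengthComposition(comp.bin_edges, comp.counts * 1e5)
        fit = fit_lbspr(obs, lh)
        assert fit.converged
        assert fit.f_over_m == pytest.approx(truth_fm, rel=0.01)
        assert fit.sel.sl50 == pytest.approx(truth_sel.sl50, rel=0.01)
        assert fit.sel.sl95 == pytest.approx(truth_sel.sl95, rel=0.01)

    def test_null_fishing_hits_boundary(self, lh, sel_2012):
        comp = expected_length_composition(lh, 0.0, sel_2012)
        obs = LengthComposition(comp.bin_edges, comp.counts * 2e4)
        fit = fit_lbspr(obs, lh)
        assert fit.converged
        assert fit.f_over_m < 0.05
        assert fit.at_boundary

    def test_bootstrap_sds_populated_and_positive(self, lh, sel_2012):
        from lenassess.synthetic_data import (equilibrium_population,
                                              sample_catch_lengths)
        pop = equilibrium_population(lh, 1.98, sel_2012, n_gtg=13)
        ds = sample_catch_lengths(pop, sel_2012, 489, seed=5)
        edges = default_bin_edges(lh)
        obs = LengthComposition.from_lengths(ds.lengths(), 2.0, l_max=edges[-1])
        fit = fit_lbspr(obs, lh, n_boot=20, seed=11)
        assert fit.converged
        for sd in (fit.sd_f_over_m, fit.sd_sl50, fit.sd_sl95, fit.sd_spr):
            assert sd is not None and sd > 0

    def test_empty_and_sparse_compositions_rejected(self, lh):
        edges = np.arange(0, 144, 2.0)
        with pytest.raises(ValueError):
            fit_lbspr(LengthComposition(edges, np.zeros(len(edges) - 1)), lh)
        sparse = np.zeros(len(edges) - 1)
        sparse[30] = 100
        with pytest.raises(ValueError, match="3 non-empty"):
            fit_lbspr(LengthComposition(edges, sparse), lh)
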