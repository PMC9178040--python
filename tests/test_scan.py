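"""Stepwise QTL detection: threshold arithmetic, weighted scans against a
normal-equations oracle, forward/backward selection, FDR tagging,
intervals, variance explained and founder-effect vectors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import magicqtl as m
from magicqtl.scan import CandidateQTL

from conftest import simulate_single_qtl_trait


class TestThresholds:
    def test_bonferroni_values(self):
        assert m.bonferroni_threshold(0.1, 237.19) == pytest.approx(4.216e-4, rel=1e-3)
        assert m.bonferroni_threshold(0.05, 237.19) == pytest.approx(2.108e-4, rel=1e-3)
        assert m.bonferroni_threshold(0.05, 1.0) == 0.05

    def test_block_count_reconstruction(self):
        assert m.estimate_n_blocks(21, 4, 54.05) == pytest.approx(237.19, rel=1e-3)
        assert m.estimate_n_blocks(21, 4, 0) == 21
        assert m.estimate_n_blocks(1, 0, 99.0) == 1

    def test_penalty_p_equivalence(self):
        assert m.penalty_to_p(13.73, 1) == pytest.approx(2.1e-4, rel=0.01)
        assert m.penalty_to_p(0.0, 1) == 1.0
        # independent numeric inversion of the chi-square quantile
        assert m.p_to_penalty(0.05, 1) == pytest.approx(3.841, abs=1e-3)
        assert m.p_to_penalty(m.penalty_to_p(13.73, 1), 1) == pytest.approx(13.73, rel=1e-9)

    def test_penalty_roundtrip_7df(self):
        p = m.penalty_to_p(5.0, 7)
        assert m.p_to_penalty(p, 7) == pytest.approx(5.0, rel=1e-9)

    def test_plan_validates(self):
        with pytest.raises(ValueError):
            m.MultipleTestingPlan(alpha_add=0.01, alpha_drop=0.05)


class TestFunnelWeights:
    def test_equal_funnels_give_unit_weights(self):
        w = m.funnel_weights(["a", "a", "b", "b"])
        assert np.allclose(w, 1.0)

    def test_unequal_funnels_equalize_totals(self):
        w = m.funnel_weights(["a", "b", "b", "b"])
        raw = w / w.sum() * 2  # two funnels, total weight 2
        assert raw[0] == pytest.approx(1.0)
        assert raw[1:].sum() == pytest.approx(1.0)

    def test_invariant_to_line_order(self):
        ids = ["a", "b", "b", "c", "c", "c"]
        w = m.funnel_weights(ids)
        perm = [5, 0, 3, 1, 4, 2]
        w_perm = m.funnel_weights([ids[i] for i in perm])
        assert np.allclose(w_perm, w[perm])

    def test_proportional_mode(self):
        w = m.funnel_weights(["a", "b", "b", "b"], mode="proportional")
        assert w[0] < w[1]


def _wls_oracle_p(y, X, w, j):
    """Textbook weighted least squares t-test for coefficient j."""
    W = np.diag(w)
    XtW = X.T @ W
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    r = y - X @ beta
    dfres = len(y) - X.shape[1]
    sigma2 = (r @ (w * r)) / dfres
    cov = sigma2 * np.linalg.inv(XtW @ X)
    t = beta[j] / np.sqrt(cov[j, j])
    return 2 * stats.t.sf(abs(t), dfres), beta[j]


def _random_instance(seed, n=50, n_markers=12, n_fixed=0):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, 100, n_markers))
    markers = pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(n_markers)], "chrom": "1A", "cM": pos}
    )
    gmap = m.GeneticMap(markers, {"1A": 100.0})
    G = rng.integers(0, 2, (n, n_markers)).astype(float)
    geno = pd.DataFrame(G, index=[f"L{i}" for i in range(n)], columns=markers["marker_id"])
    y = rng.normal(size=n) + G[:, 0] * rng.normal()
    w = rng.uniform(0.3, 3.0, n)
    w /= w.mean()
    fixed = [f"m{i}" for i in range(1, 1 + n_fixed)]
    return y, geno, gmap, w, fixed


class TestSingleMarkerScan:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        """Scan p-values equal direct WLS solves, |dp| < 1e-10."""
        n_fixed = seed % 3
        y, geno, gmap, w, fixed = _random_instance(seed, n_fixed=n_fixed)
        prof = m.single_marker_scan(y, geno, gmap, w, fixed)
        fixed_cols = [geno[f].to_numpy() for f in fixed]
        for j, mid in enumerate(geno.columns):
            if mid in fixed:
                assert np.isnan(prof.loc[j, "p"])
                continue
            X = np.column_stack([np.ones(len(y))] + fixed_cols + [geno[mid]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            p_oracle, beta = _wls_oracle_p(y, X, w, X.shape[1] - 1)
            assert abs(prof.loc[j, "p"] - p_oracle) < 1e-10
            assert prof.loc[j, "effect"] == pytest.approx(beta, abs=1e-10)

    def test_equal_weights_match_ols(self):
        y, geno, gmap, _, _ = _random_instance(99)
        prof_w = m.single_marker_scan(y, geno, gmap, np.ones(len(y)))
        prof_u = m.single_marker_scan(y, geno, gmap, None)
        assert np.nanmax(np.abs(prof_w["neglog10p"] - prof_u["neglog10p"])) < 1e-8

    def test_noise_free_signal_peaks_at_causal_marker(self):
        y, geno, gmap, w, _ = _random_instance(7)
        y_exact = 3.0 + 2.0 * geno["m4"].to_numpy()
        prof = m.single_marker_scan(y_exact, geno, gmap, w)
        assert prof.loc[4, "p"] == prof["p"].min()  # causal marker attains the minimum
        assert prof.loc[4, "effect"] == pytest.approx(2.0)

    def test_monomorphic_marker_flagged_p1(self):
        y, geno, gmap, w, _ = _random_instance(3)
        geno = geno.copy()
        geno["m5"] = 1.0
        prof = m.single_marker_scan(y, geno, gmap, w)
        assert prof.loc[5, "p"] == 1.0
        assert prof.loc[5, "effect"] == 0.0
        assert prof.loc[5, "flag"] == "monomorphic"

    def test_per_marker_type_I_error_calibrated(self):
        """Null traits reject at ~5% per marker at nominal 0.05."""
        rng = np.random.default_rng(12345)
        n, n_markers = 200, 200
        markers = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n_markers)],
                "chrom": "1A",
                "cM": np.linspace(0, 199, n_markers),
            }
        )
        gmap = m.GeneticMap(markers, {"1A": 200.0})
        frac = []
        for _ in range(50):
            G = rng.integers(0, 2, (n, n_markers)).astype(float)
            geno = pd.DataFrame(G, columns=markers["marker_id"])
            y = rng.normal(size=n)
            prof = m.single_marker_scan(y, geno, gmap)
            frac.append(np.mean(prof["p"] < 0.05))
        assert abs(np.mean(frac) - 0.05) < 0.02


class TestHaplotypeScan:
    def test_founder_specific_effect_recovered_noise_free(self, population, prob_grid):
        grid_oh = m.probability_grid(population, step_cM=2.0, uncertainty=0.0)
        target = population.founders_at("1A", 50.0)
        y = (target == 2).astype(float) * 2.0
        prof = m.haplotype_scan(y, grid_oh)
        peak = prof.loc[prof["p"].idxmin()]
        assert peak["chrom"] == "1A"
        assert abs(peak["cM"] - 50.0) <= 2.0
        vec = np.asarray(peak["founder_effects"])
        assert np.argmax(np.abs(vec - vec.mean())) == 2

    def test_no_signal_profile_flat(self, population, prob_grid):
        rng = np.random.default_rng(4)
        y = rng.normal(size=population.n_lines)
        prof = m.haplotype_scan(y, prob_grid)
        assert prof["p"].min() > 1e-4  # no spurious strong peak
        assert prof["df"].max() == 7

    def test_agrees_with_snp_scan_on_biallelic_qtl(self, population, small_map, prob_grid, weights):
        y = simulate_single_qtl_trait(population, "1A", 50.0, 0.5, seed=77)
        prof_s = m.single_marker_scan(y, population.genotypes, small_map, weights)
        prof_h = m.haplotype_scan(y, prob_grid, weights)
        peak_s = prof_s.loc[prof_s["p"].idxmin()]
        peak_h = prof_h.loc[prof_h["p"].idxmin()]
        assert peak_s["chrom"] == peak_h["chrom"] == "1A"
        assert abs(peak_s["cM"] - peak_h["cM"]) <= 2.0

    def test_rows_must_sum_to_one(self, population, prob_grid):
        bad = m.FounderProbabilityGrid(
            prob_grid.positions, prob_grid.probs * 0.5, prob_grid.line_ids
        )
        with pytest.raises(ValueError):
            m.haplotype_scan(np.zeros(population.n_lines), bad)


class TestFDR:
    def test_bh_worked_example(self):
        adj = m.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_single_test_unchanged(self):
        assert m.bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_equal_ps_equal_adjustment(self):
        adj = m.bh_adjust(np.full(10, 0.02))
        assert np.allclose(adj, adj[0])

    def test_hand_rolled_step_up_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=57)
        order = np.argsort(p)
        stepped = p[order] * len(p) / np.arange(1, len(p) + 1)
        expected = np.empty_like(p)
        expected[order] = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1)
        assert np.allclose(m.bh_adjust(p), expected)

    def test_confidence_label(self):
        prof = pd.DataFrame({"p": [1e-6, 0.5, 0.8, 0.9]})
        p_fdr, conf = m.fdr_confidence(prof, 0)
        assert p_fdr == pytest.approx(4e-6)
        assert conf == "high"


class TestForwardSelect:
    def test_planted_qtl_added_first_and_rescans_skip_it(
        self, population, small_map, weights, founders
    ):
        y = simulate_single_qtl_trait(population, "1A", 50.0, 0.4, seed=5)
        backend = m.SnpBackend(population.genotypes, small_map, weights, founders)
        cands = m.forward_select(y, backend, m.MultipleTestingPlan())
        assert len(cands) >= 1
        assert cands[0].chrom == "1A"
        assert abs(cands[0].pos_cM - 50.0) < 10.0
        # conditional rescan skips the added marker
        prof2 = backend.scan(y, [cands[0].term])
        row = prof2[prof2["marker_id"] == cands[0].term]
        assert np.isnan(row["p"].iloc[0])

    def test_two_unlinked_qtl_found_larger_first(self, small_map, founders):
        plan_f = m.make_funnel_plan(30, 300, seed=61)
        pop = m.simulate_population(small_map, founders, plan_f, seed=62)
        q1 = m.PlantedQTL("1A", 40.0, "biallelic", np.array([np.sqrt(2.0)]), np.array([1.0]))
        q2 = m.PlantedQTL("1B", 60.0, "biallelic", np.array([1.0]), np.array([1.0]))
        arch = m.TraitArchitecture(["T1"], [q1, q2], np.array([0.45]))
        ph = m.simulate_phenotypes(pop, arch, years=1, replicates=1, seed=63)
        y = ph.wide(1)["T1"].reindex(pop.line_ids).to_numpy()
        backend = m.SnpBackend(pop.genotypes, small_map, m.funnel_weights(pop.funnel_ids))
        cands = m.forward_select(y, backend, m.MultipleTestingPlan())
        chroms = [c.chrom for c in cands]
        assert set(chroms) >= {"1A", "1B"}
        assert cands[0].chrom == "1A"  # larger effect enters first

    def test_runaway_selection_aborts(self, population, small_map):
        y = simulate_single_qtl_trait(population, "1A", 50.0, 0.6, seed=8)
        backend = m.SnpBackend(population.genotypes, small_map)
        plan = m.MultipleTestingPlan(n_blocks=1.0, alpha_add=0.99, alpha_drop=0.001, max_qtl=2)
        with pytest.raises(RuntimeError):
            m.forward_select(y, backend, plan)


class _StubBackend:
    """Deterministic backend exposing hand-set columns for elimination tests."""

    mode = "snp"

    def __init__(self, cols: dict, penalty: float):
        self.cols = cols
        self._penalty = penalty
        self.weights = None

    def term_columns(self, term):
        return self.cols[term][:, None]

    def penalty(self, plan):
        return self._penalty


def _cand(term, order):
    return CandidateQTL(term, "1A", float(order), str(term), 1e-5, 1e-4, "high",
                        1.0, None, pd.DataFrame(), order)


class TestBackwardEliminate:
    def _setup(self, strong_beta, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        n = 120
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        y = strong_beta * x1 + rng.normal(size=n)
        return y, {"a": x1, "b": x2}

    def test_informative_term_retained_null_term_dropped(self):
        y, cols = self._setup(2.0)
        backend = _StubBackend(cols, penalty=13.73)
        model = m.backward_eliminate(y, [_cand("a", 0), _cand("b", 1)], backend,
                                     m.MultipleTestingPlan())
        assert [c.term for c in model.candidates] == ["a"]

    def test_weak_term_dropped_at_high_penalty_kept_at_low(self):
        rng = np.random.default_rng(3)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        y = 0.28 * x + rng.normal(size=n)  # -2ll rise between 2 and 13.73
        rise = n * (np.log(np.var(y)) - np.log(np.var(y - 0.28 * (x - x.mean()) / 1)))
        backend_hi = _StubBackend({"a": x}, penalty=13.73)
        model_hi = m.backward_eliminate(y, [_cand("a", 0)], backend_hi,
                                        m.MultipleTestingPlan())
        backend_lo = _StubBackend({"a": x}, penalty=0.5)
        model_lo = m.backward_eliminate(y, [_cand("a", 0)], backend_lo,
                                        m.MultipleTestingPlan())
        assert [c.term for c in model_lo.candidates] == ["a"]
        assert model_hi.candidates == [] or rise > 13.73

    def test_collinear_pair_later_added_removed_first(self):
        rng = np.random.default_rng(4)
        n = 150
        x = rng.integers(0, 2, n).astype(float)
        y = 3.0 * x + rng.normal(size=n)
        backend = _StubBackend({"a": x, "b": x.copy()}, penalty=13.73)
        model = m.backward_eliminate(y, [_cand("a", 0), _cand("b", 1)], backend,
                                     m.MultipleTestingPlan())
        assert [c.term for c in model.candidates] == ["a"]

    def test_retained_terms_beat_penalty_equivalent_p(
        self, population, small_map, weights, founders
    ):
        """Forward-then-backward never keeps a term whose final conditional
        p exceeds the penalty-equivalent threshold."""
        y = simulate_single_qtl_trait(population, "1A", 50.0, 0.3, seed=21)
        backend = m.SnpBackend(population.genotypes, small_map, weights, founders)
        plan = m.MultipleTestingPlan()
        cands = m.forward_select(y, backend, plan)
        model = m.backward_eliminate(y, cands, backend, plan)
        p_equiv = m.penalty_to_p(plan.aic_penalty_snp, 1)
        for c in model.candidates:
            others = [o.term for o in model.candidates if o.term != c.term]
            prof = backend.scan(y, others)
            p_final = prof.loc[prof["marker_id"] == c.term, "p"].iloc[0]
            assert p_final < p_equiv * 1.5  # AIC vs F-test approximation slack


def _interval_oracle(profile, chrom, peak_cM, window=20.0, drop=2.0):
    """Independent brute-force application of the support-interval rule."""
    sub = profile[(profile["chrom"] == chrom) & profile["p"].notna()]
    pos = sub["cM"].to_numpy()
    nlp = sub["neglog10p"].to_numpy()
    peak_nlp = nlp[np.isclose(pos, peak_cM)].max()
    support = [
        i
        for i in range(len(pos))
        if abs(pos[i] - peak_cM) <= window and nlp[i] >= peak_nlp - drop
    ]
    left = [i for i in range(len(pos)) if pos[i] < peak_cM and i not in support]
    right = [i for i in range(len(pos)) if pos[i] > peak_cM and i not in support]
    lp = max((pos[i] for i in left), default=None)
    rp = min((pos[i] for i in right), default=None)
    return lp, rp


class TestInterval:
    def _profile(self, pos, nlp, chrom="1A"):
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(pos))],
                "chrom": chrom,
                "cM": pos,
                "p": 10.0 ** (-np.asarray(nlp)),
                "neglog10p": nlp,
            }
        )

    def test_unimodal_peak_flanks_just_beyond_two_unit_drop(self):
        # Gaussian peak, sigma 7: -log10 p drops by 2 between 5 and 7.5 cM
        # from the peak, so the flanks are the first markers beyond +/-5 cM
        pos = np.arange(0, 101, 2.5)
        nlp = 8.0 * np.exp(-((pos - 50) ** 2) / (2 * 7.0**2))
        prof = self._profile(pos, nlp)
        (l, _), (r, _) = m.define_interval(prof, "1A", 50.0)
        assert (l, r) == (42.5, 57.5)
        lo, ro = _interval_oracle(prof, "1A", 50.0)
        assert l == lo and r == ro

    def test_flat_profile_bounded_by_window(self):
        pos = np.arange(0, 101, 1.0)
        prof = self._profile(pos, np.full(len(pos), 6.0))
        left, right = m.define_interval(prof, "1A", 50.0)
        assert left[0] == 29.0 and right[0] == 71.0

    def test_peak_at_chromosome_start_one_sided(self):
        pos = np.arange(0, 50.0, 1.0)
        nlp = 8.0 * np.exp(-(pos**2) / (2 * 2.0**2))
        prof = self._profile(pos, nlp)
        left, right = m.define_interval(prof, "1A", 0.0)
        assert left is None and right is not None

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        pos = np.sort(rng.uniform(0, 120, n))
        nlp = rng.uniform(0, 10, n)
        prof = self._profile(pos, nlp)
        peak_i = int(np.argmax(nlp))
        left, right = m.define_interval(prof, "1A", pos[peak_i])
        lo, ro = _interval_oracle(prof, "1A", pos[peak_i])
        assert (left[0] if left else None) == lo
        assert (right[0] if right else None) == ro


class TestVarianceExplained:
    def test_simple_regression_equals_r_squared(self):
        rng = np.random.default_rng(5)
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        y = x + rng.normal(size=n)
        backend = _StubBackend({"a": x}, penalty=0.5)
        model = m.backward_eliminate(y, [_cand("a", 0)], backend, m.MultipleTestingPlan())
        per_term, total = m.variance_explained(model)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert per_term["a"] == pytest.approx(100 * r2, abs=1e-8)

    def test_noise_free_trait_explains_everything(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 2, 80).astype(float)
        y = 2.0 * x + 1.0
        backend = _StubBackend({"a": x}, penalty=0.5)
        model = m.backward_eliminate(y, [_cand("a", 0)], backend, m.MultipleTestingPlan())
        _, total = m.variance_explained(model)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_constant_trait_rejected(self):
        x = np.ones(50)
        backend = _StubBackend({"a": x}, penalty=0.5)
        model = m.backward_eliminate(np.ones(50), [_cand("a", 0)], backend,
                                     m.MultipleTestingPlan())
        with pytest.raises(ValueError):
            m.variance_explained(model)


class TestFounderEffectVector:
    def test_snp_vector_centered_split(self, population, small_map, weights, founders):
        y = simulate_single_qtl_trait(population, "1A", 50.0, 0.5, seed=13)
        backend = m.SnpBackend(population.genotypes, small_map, weights, founders)
        recs = m.map_qtl(y, backend, m.MultipleTestingPlan())
        assert recs
        v = recs[0].founder_effects
        assert abs(v.sum()) < 1e-9
        # biallelic pattern: entries take exactly two values
        assert len(np.unique(np.round(v, 9))) == 2

    def test_haplotype_vector_recovers_planted_founder(self, population, prob_grid, weights):
        y = simulate_single_qtl_trait(
            population, "1B", 60.0, 0.5, seed=14, mode="founder",
            pattern=np.eye(8)[4],
        )
        backend = m.HaplotypeBackend(prob_grid, weights)
        recs = m.map_qtl(y, backend, m.MultipleTestingPlan())
        assert recs
        v = recs[0].founder_effects
        assert abs(v.sum()) < 1e-9
        assert np.argmax(np.abs(v)) == 4
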