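"""Classifier criteria, sweep scan and HKA likelihood machinery."""

import numpy as np
import pytest

from pathsel import selection_scan as scan
from pathsel.diversity_stats import CodonStatTrack, GeneStatRecord, harmonic_number
from pathsel.io_formats import GeneModel


class TestEmpiricalPercentile:
    def test_minimum_of_distinct_values_is_zero(self, rng):
        values = rng.permutation(np.arange(100, dtype=float))
        assert scan.empirical_percentile(values, values.min()) == 0.0

    def test_median_of_101_distinct_values_is_50(self):
        values = np.arange(101, dtype=float)
        assert scan.empirical_percentile(values, 50.0) == pytest.approx(50.0)

    def test_tied_background_half_rule(self):
        assert scan.empirical_percentile([1.0, 1.0, 1.0], 1.0) == pytest.approx(50.0)

    def test_external_value_not_in_background(self):
        values = np.arange(10, dtype=float)
        assert scan.empirical_percentile(values, -5.0) == 0.0
        assert scan.empirical_percentile(values, 100.0) == 100.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            scan.empirical_percentile([], 1.0)


def _record(gene, s, pi, tw, d, n=20, L=3000):
    return GeneStatRecord(gene_id=gene, group="landrace", n=n, L=L, L_effective=L,
                          S=s, theta_pi=pi, theta_w=tw, tajimas_d=d)


def _background(rng, n=100):
    # smooth neutral-looking background distributions
    return scan.BackgroundTables(
        theta_pi=rng.gamma(4, 2.5e-4, n),
        theta_w=rng.gamma(4, 2.2e-4, n),
        fst=rng.beta(2, 10, n),
        tajimas_d=rng.normal(0, 0.9, n),
    )


class TestClassifyGene:
    def test_purifying_conditions(self, rng):
        bg = _background(rng)
        rec_l = _record("g", s=1,
                        pi=float(np.quantile(bg.theta_pi, 0.02)),
                        tw=float(np.quantile(bg.theta_w, 0.03)),
                        d=-1.2)
        rec_w = _record("g", s=12, pi=1e-3, tw=1e-3, d=0.1)
        fst = float(np.quantile(bg.fst, 0.97))
        call = scan.classify_gene(rec_l, rec_w, fst, bg)
        assert call.label == "purifying"
        assert call.evidence["theta_pi_pct"] < 5

    def test_all_statistics_at_median_is_none(self, rng):
        bg = _background(rng)
        rec_l = _record("g", s=8,
                        pi=float(np.median(bg.theta_pi)),
                        tw=float(np.median(bg.theta_w)),
                        d=float(np.median(bg.tajimas_d)))
        rec_w = _record("g", s=8, pi=1e-3, tw=1e-3, d=0.0)
        call = scan.classify_gene(rec_l, rec_w, float(np.median(bg.fst)), bg)
        assert call.label == "none"

    def test_balancing_conditions(self, rng):
        bg = _background(rng)
        rec_l = _record("g", s=30,
                        pi=float(np.quantile(bg.theta_pi, 0.85)),
                        tw=float(np.quantile(bg.theta_w, 0.85)),
                        d=float(bg.tajimas_d.max()) + 0.5)
        rec_w = _record("g", s=10, pi=8e-4, tw=8e-4, d=0.0)
        call = scan.classify_gene(rec_l, rec_w, float(np.median(bg.fst)), bg)
        assert call.label == "balancing"

    def test_invariant_descendant(self, rng):
        bg = _background(rng)
        rec_l = _record("g", s=0, pi=0.0, tw=0.0, d=None)
        rec_w = _record("g", s=9, pi=1e-3, tw=1e-3, d=0.2)
        call = scan.classify_gene(rec_l, rec_w, 0.7, bg)
        assert call.label == "invariant"

    def test_boundary_percentile_exactly_5_fails(self, rng):
        # strict inequality: a gene sitting exactly at the cutoff is not called
        bg = scan.BackgroundTables(
            theta_pi=np.arange(1, 101, dtype=float),
            theta_w=np.arange(1, 101, dtype=float),
            fst=np.linspace(0, 1, 100),
            tajimas_d=np.linspace(-2, 2, 100),
        )
        # x = 5.5 -> 5 of 100 strictly smaller -> percentile exactly 5.0
        rec_l = _record("g", s=2, pi=5.5, tw=5.5, d=-1.0)
        rec_w = _record("g", s=2, pi=5.5, tw=5.5, d=0.0)
        call = scan.classify_gene(rec_l, rec_w, 0.999, bg)
        assert scan.empirical_percentile(bg.theta_pi, 5.5) == 5.0
        assert call.label == "none"

    def test_missing_fst_rejected(self, rng):
        bg = _background(rng)
        rec = _record("g", s=3, pi=1e-4, tw=1e-4, d=-1.0)
        with pytest.raises(ValueError, match="FST"):
            scan.classify_gene(rec, rec, float("nan"), bg)

    def test_invariant_to_monotone_rescaling(self, rng):
        # percentile criteria only see ranks
        bg = _background(rng)
        rec_l = _record("g", s=1, pi=float(np.quantile(bg.theta_pi, 0.02)),
                        tw=float(np.quantile(bg.theta_w, 0.02)), d=-0.8)
        rec_w = _record("g", s=9, pi=1e-3, tw=1e-3, d=0.1)
        fst = float(np.quantile(bg.fst, 0.98))
        call1 = scan.classify_gene(rec_l, rec_w, fst, bg)
        scale = 37.5
        bg2 = scan.BackgroundTables(
            theta_pi=bg.theta_pi * scale, theta_w=bg.theta_w * scale,
            fst=bg.fst, tajimas_d=bg.tajimas_d)
        rec_l2 = _record("g", s=1, pi=rec_l.theta_pi * scale,
                         tw=rec_l.theta_w * scale, d=-0.8)
        call2 = scan.classify_gene(rec_l2, rec_w, fst, bg2)
        assert call1.label == call2.label == "purifying"


class TestClassifyCodon:
    def _track(self, pi_l, pi_w, fst, d, effect):
        n = len(pi_l)
        return CodonStatTrack(
            gene_id="g", pi_landrace=np.array(pi_l), pi_wild=np.array(pi_w),
            fst=np.array(fst), tajimas_d=np.array(d), effect=list(effect))

    def test_monomorphic_codon_no_call(self):
        track = self._track([0.0], [0.0], [0.0], [np.nan], ["monomorphic"])
        assert scan.classify_codon(track, 0.001) == []

    def test_purifying_codon(self):
        track = self._track([0.0], [0.02], [0.4], [-0.9], ["nonsynonymous"])
        calls = scan.classify_codon(track, 0.001)
        assert len(calls) == 1 and calls[0].label == "purifying"
        assert calls[0].evidence["effect"] == "nonsynonymous"

    def test_balancing_codon(self):
        track = self._track([0.15], [0.001], [0.3], [1.4], ["synonymous"])
        calls = scan.classify_codon(track, 0.001)
        assert len(calls) == 1 and calls[0].label == "balancing"

    def test_zero_d_boundary_no_call(self):
        track = self._track([0.0], [0.02], [0.4], [0.0], ["synonymous"])
        assert scan.classify_codon(track, 0.001) == []

    def test_both_label_from_disjoint_codon_sets(self):
        gene_call = scan.SelectionCall(gene_id="g", level="gene", label="purifying")
        codon_calls = [
            scan.SelectionCall("g", "codon", "purifying", codon_index=3),
            scan.SelectionCall("g", "codon", "balancing", codon_index=9),
        ]
        assert scan.combine_gene_and_codon_calls(gene_call, codon_calls) == "both"


def _order(n, chrom="chr1", start0=0):
    return [GeneModel(f"g{i:02d}", chrom, start0 + 1000 * i, start0 + 1000 * i + 500)
            for i in range(n)]


class TestSweepScan:
    def test_all_none_neighbours(self):
        order = _order(21)
        calls = {m.gene_id: "none" for m in order}
        s = scan.flanking_sweep_scan("g10", order, calls)
        assert s.sweep_flag is False
        assert s.n_flanking == 20
        assert sum(v for k, v in s.counts.items() if k != "none") == 0

    def test_chromosome_end_truncates_window(self):
        order = _order(25)
        calls = {m.gene_id: "none" for m in order}
        s = scan.flanking_sweep_scan("g21", order, calls)  # 3 genes downstream
        assert s.n_flanking == 13

    def test_planted_cluster_counts(self):
        order = _order(21)
        calls = {m.gene_id: "none" for m in order}
        for g in ("g06", "g07", "g08", "g09"):
            calls[g] = "balancing"
        for g in ("g12", "g13"):
            calls[g] = "purifying"
        s = scan.flanking_sweep_scan("g10", order, calls)
        assert s.counts["balancing"] == 4
        assert s.counts["purifying"] == 2
        assert s.sweep_flag is True

    def test_invariant_neighbour_raises_flag(self):
        order = _order(5)
        calls = {m.gene_id: "none" for m in order}
        calls["g01"] = "invariant"
        s = scan.flanking_sweep_scan("g02", order, calls, radius=2)
        assert s.sweep_flag is True

    def test_other_chromosome_excluded(self):
        order = _order(5) + _order(5, chrom="chr2", start0=10**6)
        calls = {m.gene_id: "none" for m in order}
        with pytest.raises(KeyError):
            scan.flanking_sweep_scan("missing", order, calls)
        s = scan.flanking_sweep_scan("g04", order[:5] + _order(5, "chr2", 10**6), calls)
        assert s.n_flanking == 4  # only chr1 genes

    def test_focal_gene_absent_rejected(self):
        order = _order(3)
        with pytest.raises(KeyError):
            scan.flanking_sweep_scan("gX", order, {})


class TestHKALoglik:
    def _dataset(self, **kw):
        defaults = dict(S=[12, 30], D=[40, 95], L=[1000, 2500], n=[20, 20])
        defaults.update(kw)
        return scan.HKADataset(**defaults)

    def test_nesting_identity_k_equal_one(self):
        ds = self._dataset(selected=(0,))
        theta = np.array([0.01, 0.012])
        ll_sel = scan.hka_loglik(ds, theta, T=3.0, k={0: 1.0})
        ll_neu = scan.hka_loglik(ds, theta, T=3.0)
        assert ll_sel == pytest.approx(ll_neu, abs=1e-12)

    def test_parameterisation_symmetry(self):
        # doubling L and halving theta leaves the likelihood unchanged
        ds1 = self._dataset()
        ds2 = self._dataset(L=[2000, 5000])
        theta = np.array([0.01, 0.012])
        assert scan.hka_loglik(ds1, theta, 3.0) == pytest.approx(
            scan.hka_loglik(ds2, theta / 2, 3.0), abs=1e-9)

    def test_gradient_zero_at_method_of_moments(self):
        # 1-locus dataset: MoM point (theta * L * a = S, theta * L * (T+c) = D)
        # is the interior optimum; numerical gradient vanishes there
        ds = scan.HKADataset(S=[25], D=[60], L=[1500], n=[20])
        a = ds.a_n()[0]
        c = ds.divergence_coeff()[0]
        theta_hat = 25 / (1500 * a)
        t_hat = 60 / (theta_hat * 1500) - c
        f0 = scan.hka_loglik(ds, np.array([theta_hat]), t_hat)
        eps = 1e-6
        g_theta = (scan.hka_loglik(ds, np.array([theta_hat * (1 + eps)]), t_hat)
                   - scan.hka_loglik(ds, np.array([theta_hat * (1 - eps)]), t_hat))
        g_t = (scan.hka_loglik(ds, np.array([theta_hat]), t_hat * (1 + eps))
               - scan.hka_loglik(ds, np.array([theta_hat]), t_hat * (1 - eps)))
        assert abs(g_theta) < 1e-5 * abs(f0)
        assert abs(g_t) < 1e-5 * abs(f0)

    def test_invalid_parameters_rejected(self):
        ds = self._dataset()
        with pytest.raises(ValueError):
            scan.hka_loglik(ds, np.array([0.0, 0.01]), 1.0)
        with pytest.raises(ValueError):
            scan.hka_loglik(ds, np.array([0.01, 0.01]), -1.0)
        with pytest.raises(ValueError):
            scan.hka_loglik(ds, np.array([0.01, 0.01]), 1.0, k={1: 2.0})


class TestHKALrt:
    def test_empty_selected_set_statistic_exactly_zero(self):
        ds = scan.HKADataset(S=[12, 30, 8], D=[40, 95, 30],
                             L=[1000, 2500, 900], n=[20, 20, 20])
        res = scan.hka_lrt(ds)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 0

    def test_statistic_nonnegative_and_chi2_reference(self, rng):
        theta = np.full(8, 0.008)
        L = np.full(8, 1500.0)
        n = np.full(8, 20)
        ds = scan.simulate_hka_dataset(rng, theta, L, n, T=4.0, selected=(0, 1))
        res = scan.hka_lrt(ds)
        assert res.statistic >= 0
        assert 0 <= res.p_value <= 1
        assert res.df == 2

    def test_planted_polymorphism_deficit_detected(self, rng):
        # strong k=0.1 deficit at one locus among many neutral loci
        m = 10
        theta = np.full(m, 0.01)
        L = np.full(m, 2000.0)
        n = np.full(m, 20)
        ds = scan.simulate_hka_dataset(rng, theta, L, n, T=4.0,
                                       k={0: 0.1}, selected=(0,))
        res = scan.hka_lrt(ds)
        assert res.p_value < 0.001
        assert res.k[0] < 0.5  # recovers the deficit direction

    def test_quick_null_calibration(self, rng):
        # small-scale version of the full calibration: rejection near alpha
        m, reps, alpha = 8, 120, 0.05
        theta = np.full(m, 0.008)
        L = np.full(m, 1500.0)
        n = np.full(m, 20)
        rejections = 0
        for _ in range(reps):
            ds = scan.simulate_hka_dataset(rng, theta, L, n, T=4.0, selected=(0,))
            rejections += scan.hka_lrt(ds).p_value < alpha
        rate = rejections / reps
        assert 0.0 <= rate < 0.15  # loose 3-sigma bound at this small n

    def test_all_selected_rejected(self):
        ds = scan.HKADataset(S=[5, 6], D=[10, 12], L=[500, 600], n=[10, 10],
                             selected=(0, 1))
        with pytest.raises(ValueError):
            scan.hka_lrt(ds)


class TestRecoveryMetrics:
    def test_invariant_counts_toward_purifying(self):
        truth = {"a": "purifying", "b": "purifying", "c": "neutral", "d": "balancing"}
        calls = {"a": "invariant", "b": "purifying", "c": "none", "d": "balancing"}
        m = scan.recovery_metrics(truth, calls)
        assert m["purifying_sensitivity"] == 1.0
        assert m["balancing_sensitivity"] == 1.0
        assert m["purifying_fpr"] == 0.0
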