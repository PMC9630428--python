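import math

import numpy as np
import pandas as pd
import pytest
import sympy

from transmeta import mr, simulate
from transmeta.mr import (
    HEIDIResult,
    InstrumentSet,
    clump,
    heidi_test,
    mr_egger,
    mr_ivw,
    mr_mode,
    mr_multivariable_ivw,
    mr_weighted_median,
    smr_test,
    weighted_median,
)


def inst_frame(beta_exp, beta_out, se_exp=0.01, se_out=0.02):
    beta_exp = np.atleast_1d(np.asarray(beta_exp, dtype=float))
    return pd.DataFrame(
        {
            "SNP": [f"iv{i}" for i in range(beta_exp.size)],
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(se_exp, beta_exp.shape),
            "beta_out": np.broadcast_to(np.asarray(beta_out, dtype=float), beta_exp.shape),
            "se_out": np.broadcast_to(se_out, beta_exp.shape),
        }
    )


class TestClump:
    def test_correlated_pair_keeps_smaller_p(self):
        markers = pd.DataFrame(
            {"SNP": ["a", "b"], "CHR": "1", "BP": [1000, 2000], "P": [1e-8, 1e-5]}
        )
        ld = pd.DataFrame([[1.0, 0.707], [0.707, 1.0]],
                          index=["a", "b"], columns=["a", "b"])
        assert clump(markers, ld, r2_max=0.001) == ["a"]

    def test_different_chromosomes_are_independent(self):
        markers = pd.DataFrame(
            {"SNP": ["a", "b"], "CHR": ["1", "2"], "BP": [1000, 1000],
             "P": [1e-8, 1e-5]}
        )
        ld = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        assert set(clump(markers, ld)) == {"a", "b"}

    def test_missing_ld_pair_is_zero_unless_strict(self):
        markers = pd.DataFrame(
            {"SNP": ["a", "b"], "CHR": "1", "BP": [1000, 2000], "P": [1e-8, 1e-5]}
        )
        ld = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        assert set(clump(markers, ld)) == {"a", "b"}
        with pytest.raises(mr.MRError):
            clump(markers, ld, strict=True)

    def test_distance_only_clumping_without_ld(self):
        markers = pd.DataFrame(
            {"SNP": ["a", "b", "c"], "CHR": "1",
             "BP": [1_000_000, 2_000_000, 50_000_000], "P": [1e-8, 1e-5, 1e-6]}
        )
        assert set(clump(markers, ld=None, window_bp=10_000_000)) == {"a", "c"}

    def test_block_ld_panel_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(41)
        n, block, rho = 200, 20, 0.5
        snps = [f"s{i:03d}" for i in range(n)]
        chrom = np.repeat([str(c + 1) for c in range(4)], n // 4)
        bp = np.tile(np.arange(n // 4) * 100_000 + 1, 4)
        p = 10.0 ** rng.uniform(-12, -2, n)
        markers = pd.DataFrame({"SNP": snps, "CHR": chrom, "BP": bp, "P": p})
        idx = np.arange(n)
        same = (idx[:, None] // block) == (idx[None, :] // block)
        r = np.where(same, rho ** np.abs(idx[:, None] - idx[None, :]), 0.0)
        ld = pd.DataFrame(r, index=snps, columns=snps)

        kept = clump(markers, ld, r2_max=0.1, window_bp=10_000_000)

        order = markers.sort_values(["P", "CHR", "BP"], kind="mergesort")
        expected = []
        for row in order.itertuples(index=False):
            conflict = False
            for other in expected:
                orow = markers[markers["SNP"] == other].iloc[0]
                if (str(orow["CHR"]) == str(row.CHR)
                        and abs(int(orow["BP"]) - int(row.BP)) <= 10_000_000
                        and float(ld.loc[row.SNP, other]) ** 2 > 0.1):
                    conflict = True
                    break
            if not conflict:
                expected.append(row.SNP)
        assert kept == expected


class TestIVW:
    def test_single_instrument_reduces_to_wald_ratio(self):
        est = mr_ivw(inst_frame([0.1], [0.05]))
        assert est.beta == pytest.approx(0.5)
        assert est.extra.get("wald_ratio") is True

    def test_all_null_outcome_effects_give_zero(self):
        est = mr_ivw(inst_frame([0.1, 0.2, 0.15], 0.0))
        assert est.beta == pytest.approx(0.0)

    def test_toy_table_matches_weighted_regression_through_origin(self):
        be = np.array([0.10, 0.15, 0.08, 0.20, 0.12])
        bo = np.array([0.05, 0.09, 0.03, 0.11, 0.07])
        so = np.array([0.02, 0.03, 0.02, 0.04, 0.025])
        est = mr_ivw(inst_frame(be, bo, se_out=so))
        # oracle: sqrt-weighted least squares via lstsq
        w = 1.0 / so
        coef, *_ = np.linalg.lstsq((be * w)[:, None], bo * w, rcond=None)
        assert est.beta == pytest.approx(float(coef[0]), abs=1e-8)

    def test_reordering_and_exposure_scaling_invariance(self):
        rng = np.random.default_rng(43)
        be = rng.normal(0, 0.05, 20)
        bo = 0.3 * be + rng.normal(0, 0.02, 20)
        d = inst_frame(be, bo)
        est = mr_ivw(d)
        est_perm = mr_ivw(d.sample(frac=1, random_state=1))
        assert est_perm.beta == pytest.approx(est.beta, abs=1e-12)
        d2 = d.assign(beta_exp=2.0 * d["beta_exp"])
        assert mr_ivw(d2).beta == pytest.approx(est.beta / 2.0, abs=1e-12)

    def test_zero_instruments_is_error(self):
        with pytest.raises(mr.MRError):
            mr_ivw(inst_frame([], []))


class TestEgger:
    def test_exact_linear_data_recovers_intercept_and_slope(self):
        be = np.array([0.05, 0.10, 0.15, 0.20])
        bo = 0.02 + 0.5 * be
        slope, intercept = mr_egger(inst_frame(be, bo))
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)

    def test_orientation_flips_rows_to_nonnegative_exposure(self):
        be = np.array([0.05, -0.10, 0.15, -0.20])
        bo = 0.02 + 0.5 * be
        # after flipping, (be, bo) -> (-be, -bo) for negative rows, so the
        # exact relationship becomes bo = +-0.02 + 0.5 be: no longer exact
        slope, intercept = mr_egger(inst_frame(be, bo))
        assert slope.n_instruments == 4
        assert np.isfinite(slope.p) and np.isfinite(intercept.p)

    def test_matches_generic_weighted_regression_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(5):
            be = np.abs(rng.normal(0.1, 0.05, 12))
            bo = rng.normal(0.01 + 0.4 * be, 0.02)
            so = rng.uniform(0.01, 0.04, 12)
            slope, intercept = mr_egger(inst_frame(be, bo, se_out=so))
            # oracle: weighted normal equations
            X = np.column_stack([np.ones_like(be), be])
            W = np.diag(1.0 / so**2)
            coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ bo)
            assert intercept.beta == pytest.approx(coef[0], abs=1e-8)
            assert slope.beta == pytest.approx(coef[1], abs=1e-8)

    def test_balanced_pleiotropy_gives_null_intercept_on_average(self):
        intercepts = []
        for rep in range(40):
            cfg = simulate.MRSimConfig(seed=5000 + rep, theta=0.1,
                                       pleiotropy="balanced", pleio_sd=0.01,
                                       n_instruments=100, winners_curse=False)
            inst, _ = simulate.simulate_mr_scenario(cfg)
            _, intercept = mr_egger(inst)
            intercepts.append(intercept.beta)
        mean = np.mean(intercepts)
        mc_se = np.std(intercepts, ddof=1) / math.sqrt(len(intercepts))
        assert abs(mean) < 2 * mc_se + 1e-4

    def test_fewer_than_three_instruments_is_error(self):
        with pytest.raises(mr.MRError):
            mr_egger(inst_frame([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_three_equal_weight_ratios_give_middle(self):
        assert weighted_median(np.array([0.2, 0.5, 0.9]),
                               np.ones(3)) == pytest.approx(0.5)

    def test_concentrated_weight_returns_that_ratio(self):
        values = np.array([0.1, 0.9, 0.5])
        weights = np.array([1e-6, 1e-6, 1e6])
        assert weighted_median(values, weights) == pytest.approx(0.5)

    def test_estimator_on_frame_uses_inverse_variance_weights(self):
        be = np.array([0.1, 0.1, 0.1])
        bo = np.array([0.02, 0.05, 0.09])
        est = mr_weighted_median(inst_frame(be, bo), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)
        assert est.se > 0

    def test_single_outlier_among_consistent_instruments_is_resisted(self):
        rng = np.random.default_rng(53)
        be = np.abs(rng.normal(0.1, 0.02, 10))
        bo = 0.3 * be
        bo[0] += 0.5  # one wildly pleiotropic instrument
        est = mr_weighted_median(inst_frame(be, bo), n_boot=100, seed=2)
        ivw = mr_ivw(inst_frame(be, bo))
        assert abs(est.beta - 0.3) < 0.05
        assert abs(est.beta - 0.3) < abs(ivw.beta - 0.3)

    def test_bootstrap_is_seed_deterministic(self):
        d = inst_frame([0.1, 0.12, 0.09, 0.11], [0.03, 0.04, 0.02, 0.035])
        a = mr_weighted_median(d, n_boot=100, seed=9)
        b = mr_weighted_median(d, n_boot=100, seed=9)
        assert a.se == b.se


class TestMode:
    def test_identical_ratios_return_that_value(self):
        est = mr_mode(inst_frame([0.1, 0.2, 0.4], [0.05, 0.10, 0.20]),
                      n_boot=20, seed=3)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_dominant_cluster_wins_over_minority(self):
        be = np.full(12, 0.1)
        bo = np.concatenate([np.full(9, 0.03), np.full(3, 0.08)])
        bo = bo + np.linspace(-1e-4, 1e-4, 12)  # break exact ties
        est = mr_mode(inst_frame(be, bo), n_boot=20, seed=4)
        assert abs(est.beta - 0.3) < 0.05

    def test_density_maximum_matches_fine_grid_scan(self):
        rng = np.random.default_rng(59)
        be = np.abs(rng.normal(0.1, 0.03, 15))
        bo = rng.normal(0.25 * be, 0.01)
        d = inst_frame(be, bo)
        est = mr_mode(d, n_boot=10, seed=5)

        ratios = (d["beta_out"] / d["beta_exp"]).to_numpy()
        weights = (d["beta_exp"] / d["se_out"]).to_numpy() ** 2
        n = len(ratios)
        s = min(np.std(ratios, ddof=1),
                1.4826 * np.median(np.abs(ratios - np.median(ratios))))
        bw = 0.9 * s * n ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 200_001)
        dens = np.zeros_like(grid)
        for r, w in zip(ratios, weights):
            dens += w * np.exp(-0.5 * ((grid - r) / bw) ** 2)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-3)


class TestMultivariableIVW:
    def test_noise_free_system_recovers_coefficients(self):
        rng = np.random.default_rng(61)
        X = pd.DataFrame({"exp1": rng.normal(0, 0.05, 30),
                          "exp2": rng.normal(0, 0.05, 30)})
        bo = 0.3 * X["exp1"] - 0.2 * X["exp2"]
        est = mr_multivariable_ivw(X, bo, np.full(30, 0.02))
        assert est[0].beta == pytest.approx(0.3, abs=1e-10)
        assert est[1].beta == pytest.approx(-0.2, abs=1e-10)

    def test_zero_signal_second_exposure_reduces_to_univariable(self):
        rng = np.random.default_rng(67)
        be = rng.normal(0, 0.05, 25)
        bo = 0.3 * be + rng.normal(0, 0.02, 25)
        so = np.full(25, 0.02)
        X = pd.DataFrame({"exp1": be, "exp2": np.zeros(25)})
        est = mr_multivariable_ivw(X, bo, so)
        uni = mr_ivw(inst_frame(be, bo, se_out=so))
        assert est[0].beta == pytest.approx(uni.beta, abs=1e-10)
        assert est[1].extra.get("no_instrument_signal") is True

    def test_random_tables_match_normal_equations_oracle(self):
        rng = np.random.default_rng(71)
        for _ in range(5):
            X = pd.DataFrame({"a": rng.normal(0, 0.05, 40),
                              "b": rng.normal(0, 0.05, 40),
                              "c": rng.normal(0, 0.05, 40)})
            bo = rng.normal(0, 0.03, 40)
            so = rng.uniform(0.01, 0.05, 40)
            est = mr_multivariable_ivw(X, bo, so)
            W = np.diag(1.0 / so**2)
            M = X.to_numpy()
            coef = np.linalg.solve(M.T @ W @ M, M.T @ W @ bo)
            for e, c in zip(est, coef):
                assert e.beta == pytest.approx(c, abs=1e-8)

    def test_collinear_exposures_are_rejected(self):
        rng = np.random.default_rng(73)
        a = rng.normal(0, 0.05, 20)
        X = pd.DataFrame({"a": a, "b": 2.0 * a})
        with pytest.raises(mr.MRError, match="collinear"):
            mr_multivariable_ivw(X, a, np.full(20, 0.02))


class TestSMR:
    def test_equal_z_scores_give_half_z_squared(self):
        for z in (2.0, 5.0, 8.0):
            res = smr_test(z, z)
            assert res.t_smr == pytest.approx(z * z / 2)

    def test_null_gwas_gives_zero_statistic_and_p_one(self):
        res = smr_test(5.0, 0.0)
        assert res.t_smr == 0.0
        assert res.p_smr == pytest.approx(1.0)

    def test_statistic_and_p_match_symbolic_oracle(self):
        rng = np.random.default_rng(79)
        for _ in range(20):
            z1, z2 = rng.normal(0, 4, 2)
            if z1 == 0:
                continue
            res = smr_test(z1, z2)
            t_sym = sympy.Rational(1, 1) * (
                sympy.Float(z2, 30) ** 2 * sympy.Float(z1, 30) ** 2
                / (sympy.Float(z2, 30) ** 2 + sympy.Float(z1, 30) ** 2))
            # chi-square(1) survival function: erfc(sqrt(t/2))
            p_sym = sympy.erfc(sympy.sqrt(t_sym / 2))
            assert res.t_smr == pytest.approx(float(t_sym.evalf(30)), rel=1e-12)
            assert res.p_smr == pytest.approx(float(p_sym.evalf(30)), rel=1e-9)

    def test_betas_override_ratio_estimate(self):
        res = smr_test(6.0, 3.0, beta_qtl=0.4, beta_gwas=0.1)
        assert res.b_xy == pytest.approx(0.25)

    def test_zero_qtl_z_is_error(self):
        with pytest.raises(mr.MRError):
            smr_test(0.0, 3.0)


def _heidi_locus(seed, causal_qtl=75, causal_gwas=75, z_qtl=10.0, z_gwas=7.0,
                 n_markers=150, rho=0.9):
    locus = simulate.simulate_locus_pair(
        seed=seed, n_markers=n_markers, rho=rho,
        causal1=causal_qtl, causal2=causal_gwas, z1=z_qtl, z2=z_gwas)
    locus = locus.rename(columns={"BETA1": "BETA_QTL", "SE1": "SE_QTL",
                                  "BETA2": "BETA_GWAS", "SE2": "SE_GWAS"})
    idx = np.arange(n_markers)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    ld = pd.DataFrame(r, index=locus["SNP"], columns=locus["SNP"])
    return locus, ld


class TestHEIDI:
    def test_too_few_eligible_neighbors_yields_missing_result(self):
        locus, ld = _heidi_locus(seed=101, n_markers=3, causal_qtl=1,
                                 causal_gwas=1)
        res = heidi_test(locus, ld)
        assert res.heidi_p is None
        assert "fewer than 3" in res.reason

    def test_shared_causal_signal_is_rarely_rejected(self):
        rejections = 0
        n_rep = 40
        for rep in range(n_rep):
            locus, ld = _heidi_locus(seed=6000 + rep)
            res = heidi_test(locus, ld)
            assert res.heidi_p is not None
            rejections += res.heidi_p < mr.HEIDI_P_THRESHOLD
        # nominal alpha is 1.57e-3: expect ~0.06 rejections in 40 replicates
        assert rejections <= 2

    def test_linked_distinct_causal_signals_raise_rejection_rate(self):
        rejections = 0
        n_rep = 20
        for rep in range(n_rep):
            locus, ld = _heidi_locus(seed=7000 + rep, causal_qtl=70,
                                     causal_gwas=80, z_qtl=12.0, z_gwas=10.0)
            res = heidi_test(locus, ld)
            rejections += (res.heidi_p is not None
                           and res.heidi_p < mr.HEIDI_P_THRESHOLD)
        assert rejections >= n_rep // 2

    def test_uses_at_most_twenty_neighbors(self):
        locus, ld = _heidi_locus(seed=103, n_markers=300)
        res = heidi_test(locus, ld)
        assert res.n_snps <= 20


class TestInstrumentSet:
    def test_tsv_round_trip_in_two_sample_layout(self, tmp_path):
        d = inst_frame([0.1, 0.2], [0.05, 0.1])
        out = d.rename(columns={"beta_exp": "beta.exposure", "se_exp": "se.exposure",
                                "beta_out": "beta.outcome", "se_out": "se.outcome"})
        path = tmp_path / "inst.tsv"
        out.to_csv(path, sep="\t", index=False)
        inst = InstrumentSet.from_tsv(path)
        assert len(inst) == 2
        assert mr_ivw(inst).n_instruments == 2

    def test_missing_columns_are_rejected(self):
        with pytest.raises(mr.MRError):
            InstrumentSet("x", "y", pd.DataFrame({"SNP": ["a"]}))
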