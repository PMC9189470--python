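"""The four MR estimators against closed forms and independent oracles."""

import numpy as np
import pytest

from mrkit import (
    EggerRegression,
    IVWEstimator,
    WeightedMedianEstimator,
    WeightedModeEstimator,
    egger,
    ivw,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from mrkit.estimators import (
    mode_bandwidth,
    weighted_median_estimate,
    weighted_mode_estimate,
)

from conftest import make_instrument, make_ratio, random_instruments


class TestWaldRatios:
    def test_basic_ratio(self):
        (r,) = wald_ratios([make_instrument(g=0.1, G=0.05, sG=0.02)])
        assert r.ratio == pytest.approx(0.5)
        assert r.se_ratio == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        (r,) = wald_ratios([make_instrument(G=0.0)])
        assert r.ratio == 0.0

    def test_negative_exposure_effect(self):
        (r,) = wald_ratios([make_instrument(g=-0.1, G=0.05, sG=0.02)])
        assert r.ratio == pytest.approx(-0.5)
        assert r.se_ratio == pytest.approx(0.2)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(ValueError, match="rsZ"):
            wald_ratios([make_instrument("rsZ", g=0.0)])


class TestIVW:
    def test_single_ratio_identity(self):
        for model in ("fe", "mre"):
            res = ivw([make_ratio(ratio=0.5, se=0.2)], model)
            assert (res.beta, res.se) == (0.5, 0.2)

    def test_equal_weight_closed_form(self):
        ratios = [make_ratio(f"rs{i}", r, 0.1) for i, r in enumerate([0.2, 0.4, 0.6])]
        res = ivw(ratios, "fe")
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.1 / np.sqrt(3))

    def test_homogeneous_ratios_mre_equals_fe(self):
        ratios = [make_ratio(f"rs{i}", 0.3, 0.1) for i in range(5)]
        assert ivw(ratios, "mre").se == ivw(ratios, "fe").se

    def test_mre_inflates_under_heterogeneity(self):
        ratios = [make_ratio(f"rs{i}", r, 0.05) for i, r in enumerate([0.0, 0.5, 1.0])]
        assert ivw(ratios, "mre").se > ivw(ratios, "fe").se

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ivw([], "fe")

    def test_equals_zero_intercept_wls(self, rng):
        """IVW(FE) is algebraically the through-origin WLS slope of the
        outcome on the exposure effects with weights 1/se(Γ)²."""
        for _ in range(100):
            insts = random_instruments(rng, n=int(rng.integers(3, 12)))
            g = np.array([i.beta_exposure for i in insts])
            G = np.array([i.beta_outcome for i in insts])
            w = np.array([1 / i.se_outcome**2 for i in insts])
            slope = np.sum(w * g * G) / np.sum(w * g * g)
            se = np.sqrt(1.0 / np.sum(w * g * g))
            res = ivw(wald_ratios(insts), "fe")
            assert res.beta == pytest.approx(slope, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)


def egger_normal_equations(insts):
    """Independent 2x2 weighted normal-equations solution for the Egger fit."""
    g = np.array([i.beta_exposure for i in insts])
    G = np.array([i.beta_outcome for i in insts])
    w = np.array([1 / i.se_outcome**2 for i in insts])
    sign = np.sign(g)
    g, G = g * sign, G * sign
    A = np.array([[w.sum(), (w * g).sum()], [(w * g).sum(), (w * g * g).sum()]])
    b = np.array([(w * G).sum(), (w * g * G).sum()])
    alpha, beta = np.linalg.solve(A, b)
    return alpha, beta


class TestEgger:
    def test_exact_affine_fit_recovered(self, rng):
        g = rng.uniform(0.05, 0.3, 6)
        insts = [
            make_instrument(f"rs{i}", g[i], 0.01, 0.01 + 0.3 * g[i], 0.02)
            for i in range(6)
        ]
        res = egger(insts)
        assert res.beta == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.01, abs=1e-10)
        fit = EggerRegression().fit(insts)
        assert fit.q_prime_ == pytest.approx(0.0, abs=1e-12)

    def test_proportional_data_zero_intercept(self, rng):
        g = rng.uniform(0.05, 0.3, 5)
        insts = [make_instrument(f"rs{i}", g[i], 0.01, 0.5 * g[i], 0.02) for i in range(5)]
        res = egger(insts)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.beta == pytest.approx(0.5, abs=1e-12)

    def test_against_normal_equations_oracle(self, rng):
        for _ in range(100):
            insts = random_instruments(rng, n=int(rng.integers(4, 10)), pleiotropy_sd=0.02)
            alpha, beta = egger_normal_equations(insts)
            res = egger(insts)
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.intercept == pytest.approx(alpha, abs=1e-10)

    def test_four_point_hand_example(self):
        insts = [
            make_instrument("rs1", 0.10, 0.01, 0.05, 0.02),
            make_instrument("rs2", 0.20, 0.01, 0.08, 0.03),
            make_instrument("rs3", 0.15, 0.01, 0.07, 0.025),
            make_instrument("rs4", 0.30, 0.01, 0.12, 0.04),
        ]
        alpha, beta = egger_normal_equations(insts)
        res = egger(insts)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.intercept == pytest.approx(alpha, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger([make_instrument("rs1"), make_instrument("rs2")])


class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        ratios = [make_ratio(f"rs{i}", r, 0.1) for i, r in enumerate([0.1, 0.4, 0.9])]
        assert weighted_median(ratios, n_boot=50, seed=0).beta == pytest.approx(0.4)

    def test_constant_ratios(self):
        ratios = [make_ratio(f"rs{i}", 0.25, 0.1) for i in range(4)]
        assert weighted_median(ratios, n_boot=50, seed=0).beta == pytest.approx(0.25)

    def test_against_dense_grid_oracle(self):
        """Brute-force scan of the interpolated cumulative-weight function."""
        b = np.array([0.1, 0.2, 0.3])
        w = np.array([1.0, 1.0, 8.0])
        est = weighted_median_estimate(b, w)
        order = np.argsort(b)
        bs, ws = b[order], w[order]
        s = (np.cumsum(ws) - ws / 2) / ws.sum()
        grid = np.linspace(bs[0], bs[-1], 200_001)
        sg = np.interp(grid, bs, s)
        oracle = grid[np.argmin(np.abs(sg - 0.5))]
        assert est == pytest.approx(oracle, abs=1e-5)

    def test_bootstrap_reproducible(self):
        ratios = [make_ratio(f"rs{i}", r, 0.1) for i, r in enumerate([0.1, 0.4, 0.9])]
        a = weighted_median(ratios, n_boot=200, seed=7)
        b = weighted_median(ratios, n_boot=200, seed=7)
        assert a == b


class TestWeightedMode:
    def test_constant_ratios_return_common_value(self):
        ratios = [make_ratio(f"rs{i}", 0.3, 0.1) for i in range(4)]
        res = weighted_mode(ratios, n_boot=50, seed=0)
        assert res.beta == 0.3
        assert res.se == pytest.approx(0.05)  # FE IVW fallback

    def test_cluster_beats_mean(self):
        vals = [0.3, 0.31, 0.29, 1.5]
        ratios = [make_ratio(f"rs{i}", v, 0.1) for i, v in enumerate(vals)]
        res = weighted_mode(ratios, n_boot=50, seed=0)
        assert abs(res.beta - 0.3) < 0.1
        # independent kernel-density oracle on a fine grid
        b = np.array(vals)
        w = np.ones(4) / 4
        h = mode_bandwidth(b)
        grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 50_001)
        dens = (w[None] * np.exp(-0.5 * ((grid[:, None] - b[None]) / h) ** 2)).sum(1)
        oracle = grid[dens.argmax()]
        assert res.beta == pytest.approx(oracle, abs=0.02)

    def test_symmetric_ratios_give_zero(self):
        ratios = [make_ratio(f"rs{i}", v, 0.1) for i, v in enumerate([-0.4, 0.0, 0.4])]
        res = weighted_mode(ratios, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.0, abs=0.02)


def test_all_estimators_invariant_to_joint_negation(rng):
    """Negating (γ, Γ) of any instrument leaves every estimate unchanged."""
    insts = random_instruments(rng, n=6, pleiotropy_sd=0.01)
    flipped = [
        make_instrument(i.rsid, -i.beta_exposure, i.se_exposure,
                        -i.beta_outcome, i.se_outcome)
        if j % 2 else i
        for j, i in enumerate(insts)
    ]
    r1, r2 = wald_ratios(insts), wald_ratios(flipped)
    assert ivw(r1, "fe") == ivw(r2, "fe")
    assert egger(insts) == egger(flipped)
    assert weighted_median(r1, 100, 3) == weighted_median(r2, 100, 3)
    assert weighted_mode(r1, n_boot=100, seed=3) == weighted_mode(r2, n_boot=100, seed=3)


def test_egger_unbiased_under_inside_directional_pleiotropy(rng):
    """With directional pleiotropy independent of instrument strength, the
    Egger slope stays near the truth while IVW absorbs the mean direct
    effect."""
    from mrkit import PleiotropySpec, SimulationConfig, simulate_study

    beta_true, n_rep = 0.2, 120
    ivw_est, egger_est = [], []
    for rep in range(n_rep):
        cfg = SimulationConfig(
            n_snps=40, n_exposure=60_000, n_outcome_cases=20_000,
            n_outcome_controls=20_000, beta_causal=beta_true, target_r2=0.3,
            pleiotropy=PleiotropySpec("directional", mean=0.02, sd=0.01),
            seed=1_000 + rep,
        )
        study = simulate_study(cfg)
        insts = [
            make_instrument(r.rsid, r.beta, r.se, o.beta, o.se)
            for r, o in zip(study.exposure_records(), study.outcome_records())
        ]
        ivw_est.append(ivw(wald_ratios(insts), "fe").beta)
        egger_est.append(egger(insts).beta)
    assert abs(np.mean(egger_est) - beta_true) < 0.05
    assert np.mean(ivw_est) - beta_true > 0.05  # inflated by the direct effects


def test_sklearn_estimator_protocol(rng):
    insts = random_instruments(rng, n=6)
    for est in (
        IVWEstimator(effects_model="mre"),
        EggerRegression(),
        WeightedMedianEstimator(n_boot=100, seed=1),
        WeightedModeEstimator(n_boot=100, seed=1),
    ):
        params = est.get_params()
        est.set_params(**params)
        fitted = est.fit(insts)
        assert fitted is est
        assert np.isfinite(est.beta_) and est.se_ > 0
    model = IVWEstimator().fit(insts)
    pred = model.predict([0.1, -0.2])
    assert pred == pytest.approx([0.1 * model.beta_, -0.2 * model.beta_])
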