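import numpy as np
import pytest
from scipy.special import expit, logsumexp
from scipy.stats import beta, kstest

from parage import (
    MCMCConfig,
    ModelSpec,
    PosteriorDraws,
    check_convergence,
    compute_dic,
    fit_model,
    or_vs_reference,
    rw1_structure_matrix,
)
from parage.crosstab import MarginalAgeTab


def test_single_cell_sampler_matches_beta_posterior():
    """Flat prior on the logit of a single binomial cell implies mu ~ Beta(y, n-y);
    the sampler's mu draws must match that analytic posterior (KS oracle)."""
    tab = MarginalAgeTab(ages=[25], births=[40], cases=[11], parent="maternal")
    spec = ModelSpec(maternal_form="none", paternal_form="none", intercept_prior="flat")
    d = fit_model(tab, spec, MCMCConfig(burn_in=500, samples=4000, chains=2, seed=3))
    mu = expit(d.alpha.reshape(-1))
    ks = kstest(mu, beta(11, 29).cdf).statistic
    assert ks < 0.05


def test_three_age_car_matches_quadrature_oracle():
    """Fixed-tau RW1 on 3 ages: sampler moments vs brute-force quadrature
    over the 3 free parameters (alpha and the two sum-to-zero coordinates)."""
    tab = MarginalAgeTab(ages=[20, 21, 22], births=[500, 800, 600],
                         cases=[40, 90, 45], parent="maternal")
    tau = 4.0
    spec = ModelSpec(maternal_form="car", paternal_form="none")
    d = fit_model(tab, spec, MCMCConfig(burn_in=500, samples=4000, chains=2, seed=9),
                  _fixed_tau={"maternal": tau})

    # quadrature over (alpha, g1, g2); theta = (g1, g2, -g1-g2)
    A = np.vstack([np.eye(2), -np.ones((1, 2))])
    Q = rw1_structure_matrix(3)
    QA = A.T @ Q @ A
    n = np.array([500.0, 800.0, 600.0])
    y = np.array([40.0, 90.0, 45.0])
    grid_a = np.linspace(-3.2, -1.6, 90)
    grid_g = np.linspace(-0.9, 0.9, 90)
    Aa, G1, G2 = np.meshgrid(grid_a, grid_g, grid_g, indexing="ij")
    th = np.stack([G1, G2, -G1 - G2], axis=-1)
    psi = Aa[..., None] + th
    loglik = (y * psi - n * np.logaddexp(0, psi)).sum(axis=-1)
    quad = G1 * (QA[0, 0] * G1 + QA[0, 1] * G2) + G2 * (QA[1, 0] * G1 + QA[1, 1] * G2)
    logp = loglik - 0.5 * tau * quad
    w = np.exp(logp - logsumexp(logp))
    w /= w.sum()

    for i in range(3):
        ref_mean = float((w * th[..., i]).sum())
        ref_sd = float(np.sqrt((w * (th[..., i] - ref_mean) ** 2).sum()))
        s = d.maternal[:, :, i].reshape(-1)
        assert s.mean() == pytest.approx(ref_mean, abs=4 * ref_sd / np.sqrt(200))
        assert s.std() == pytest.approx(ref_sd, rel=0.12)
    a_mean = float((w * Aa).sum())
    a_sd = float(np.sqrt((w * (Aa - a_mean) ** 2).sum()))
    assert d.alpha.mean() == pytest.approx(a_mean, abs=4 * a_sd / np.sqrt(200))


def test_seed_determinism(tiny_tab):
    cfg = MCMCConfig(burn_in=100, samples=200, chains=2, seed=42)
    spec = ModelSpec.preset("model3")
    d1 = fit_model(tiny_tab, spec, cfg)
    d2 = fit_model(tiny_tab, spec, cfg)
    assert np.array_equal(d1.alpha, d2.alpha)
    assert np.array_equal(d1.maternal, d2.maternal)
    assert np.array_equal(d1.deviance, d2.deviance)
    d3 = fit_model(tiny_tab, spec, MCMCConfig(burn_in=100, samples=200, chains=2, seed=43))
    assert not np.array_equal(d1.alpha, d3.alpha)


def test_car_draws_sum_to_zero(joint_fit):
    for eff in (joint_fit.maternal, joint_fit.paternal):
        assert np.abs(eff.sum(axis=2)).max() < 1e-10


def test_joint_fit_converges_and_recovers(joint_fit, ramp_data):
    _, truth = ramp_data
    rep = check_convergence(joint_fit, threshold=1.05)
    assert rep.passed, f"max R-hat {rep.max_rhat:.3f}"
    ort = or_vs_reference(joint_fit, "maternal", 15)
    true_or = np.exp(truth.maternal_effects - truth.maternal_effects[0])
    # truth inside the 95% band at the ramp top, and median in the right regime
    i45 = 45 - 15
    assert ort.lower[i45] < true_or[i45] < ort.upper[i45]
    assert ort.median[i45] == pytest.approx(true_or[i45], rel=0.5)


def test_null_table_or_covers_one(smoke_config):
    from parage import SimScenario, simulate_crosstab

    tab, _ = simulate_crosstab(SimScenario(total_births=500_000, seed=21))
    d = fit_model(tab, ModelSpec.preset("model1"), smoke_config)
    ort = or_vs_reference(d, "maternal", 15)
    inside = (ort.lower <= 1.0) & (1.0 <= ort.upper)
    assert inside[1:].mean() > 0.9  # flat truth: CI should cover OR=1 nearly everywhere


def test_convergence_report_contract(joint_fit):
    rep = check_convergence(joint_fit)
    assert set(rep.rhat) == set(rep.ess)
    assert rep.max_rhat >= 1.0 - 1e-3

    # two chains centred at different constants must fail loudly
    bad = PosteriorDraws(
        spec=joint_fit.spec, config=joint_fit.config, data=joint_fit.data,
        alpha=np.vstack([np.random.default_rng(0).normal(0, 1, 400),
                         np.random.default_rng(1).normal(8, 1, 400)]),
        deviance=np.zeros((2, 400)), mu_mean=joint_fit.mu_mean,
    )
    assert not check_convergence(bad).passed

    single = PosteriorDraws(
        spec=joint_fit.spec, config=joint_fit.config, data=joint_fit.data,
        alpha=joint_fit.alpha[:1], deviance=joint_fit.deviance[:1],
        mu_mean=joint_fit.mu_mean,
    )
    with pytest.raises(ValueError, match="2 chains"):
        check_convergence(single)


def test_dic_point_mass_has_zero_complexity():
    from parage import binomial_loglik

    tab = MarginalAgeTab(ages=[20, 21], births=[100, 200], cases=[10, 30],
                         parent="maternal")
    mu = np.array([0.1, 0.15])
    dev = -2.0 * binomial_loglik(tab, mu)
    spec = ModelSpec(maternal_form="none", paternal_form="none")
    draws = PosteriorDraws(
        spec=spec, config=MCMCConfig(burn_in=1, samples=10), data=tab,
        alpha=np.zeros((2, 10)), deviance=np.full((2, 10), dev), mu_mean=mu,
    )
    out = compute_dic(draws)
    assert out.p_d == pytest.approx(0.0, abs=1e-9)
    assert out.dic == pytest.approx(dev)


def test_dic_complexity_tracks_parameter_count(ramp_data, smoke_config):
    """pD approximates the number of free parameters for fixed-effect models:
    3 for linear (intercept + two slopes), 5 for curvilinear."""
    tab, _ = ramp_data
    d_lin = fit_model(tab, ModelSpec.preset("linear"), smoke_config)
    d_cur = fit_model(tab, ModelSpec.preset("curvilinear"), smoke_config)
    assert compute_dic(d_lin).p_d == pytest.approx(3.0, abs=1.0)
    assert compute_dic(d_cur).p_d == pytest.approx(5.0, abs=1.2)


def test_zero_case_table_warns():
    tab = MarginalAgeTab(ages=[20, 21, 22], births=[50, 60, 70], cases=[0, 0, 0],
                         parent="maternal")
    with pytest.warns(UserWarning, match="zero cases"):
        fit_model(tab, ModelSpec(maternal_form="car", paternal_form="none"),
                  MCMCConfig(burn_in=20, samples=30, chains=1, seed=0))


def test_marginal_parent_mismatch_rejected():
    tab = MarginalAgeTab(ages=[20, 21, 22], births=[50, 60, 70], cases=[1, 2, 3],
                         parent="paternal")
    with pytest.raises(ValueError, match="maternal"):
        fit_model(tab, ModelSpec.preset("model1"), MCMCConfig(burn_in=5, samples=5))


def test_draws_export_shapes(joint_fit):
    df = joint_fit.to_dataframe()
    assert len(df) == joint_fit.alpha.size
    assert "maternal[0]" in df.columns and "sd_paternal" in df.columns
    idata = joint_fit.to_inference_data()
    assert idata.posterior["maternal"].shape == joint_fit.maternal.shape
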