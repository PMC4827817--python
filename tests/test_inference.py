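import warnings

import numpy as np
import pandas as pd
import pytest

from msodyn import _kernel
from msodyn.encounters import StudyData, block_arrays, standardize_dates
from msodyn.inference import (
    ConvergenceWarning,
    McmcConfig,
    PriorSpec,
    extract_parameter,
    gelman_rubin,
    load_npz,
    rhat_table,
    sample_posterior,
    save_npz,
)
from msodyn.model import build_tpm
from oracles import enumerate_path_posterior, random_params


def test_prior_spec_validation():
    with pytest.raises(ValueError):
        PriorSpec(phi0_dirichlet=(1, 1, 0, 1))
    with pytest.raises(ValueError):
        PriorSpec(sd_prior_on="precision")
    assert PriorSpec().mean_prior_sd == pytest.approx(np.sqrt(2))
    assert PriorSpec(mean_prior_scale_is_variance=False).mean_prior_sd == 2.0


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError):
        McmcConfig(thin=0)
    cfg = McmcConfig()
    assert (cfg.n_chains, cfg.n_iter, cfg.n_burnin, cfg.thin) == (3, 55_000, 5_000, 100)


def test_fixed_seed_reproducibility(small_truth):
    cfg = McmcConfig(n_chains=2, n_iter=300, n_burnin=100, thin=2, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        a = sample_posterior(small_truth.data, config=cfg, block="A")
        b = sample_posterior(small_truth.data, config=cfg, block="A")
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.mu_trans, b.mu_trans)
    np.testing.assert_array_equal(a.alpha, b.alpha)


def test_posterior_draw_invariants(small_fit):
    assert small_fit.z.min() >= 1 and small_fit.z.max() <= 4
    np.testing.assert_allclose(small_fit.phi0.sum(axis=-1), 1.0, atol=1e-12)
    assert np.all(small_fit.sigma_trans > 0)
    assert np.all(small_fit.sigma_det > 0)
    # a reassembled draw passes ModelParams validation
    params = small_fit.params_at(0, 0)
    assert params.n_seasons == small_fit.n_seasons


def test_imputed_states_never_below_observations(small_fit, small_design):
    """The classification constraint y <= z must hold in every imputed draw."""
    z = small_fit.z_stacked()
    for v in range(len(small_design.visit_y)):
        i, t = small_design.visit_terr[v], small_design.visit_season[v]
        assert np.all(z[:, i, t] >= small_design.visit_y[v])


def test_degenerate_data_dominates_latents():
    """All visits observed in state 4 every season: z mass concentrates on 4."""
    rows = []
    for i in range(8):
        for year in range(2000, 2006):
            for jd in (100, 160):
                rows.append(("A", f"t{i}", year, jd, 4))
    df = pd.DataFrame(rows, columns=["block", "territory", "year", "julian_date", "observed_state"])
    data = standardize_dates(StudyData(records=df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        draws = sample_posterior(
            data, config=McmcConfig(n_chains=2, n_iter=800, n_burnin=200, thin=2, seed=3),
            block="A",
        )
    assert np.mean(draws.z == 4) == 1.0  # state 4 is certain given y=4 observations


def test_gelman_rubin_direct_formula():
    chains = np.array([[1.2, 0.8, 1.1, 0.9, 1.0], [1.4, 1.0, 1.3, 1.1, 1.2]])
    C, S = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    B_over_S = chains.mean(axis=1).var(ddof=1)
    expected = np.sqrt(((S - 1) / S * W + B_over_S) / W)
    assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-14)


def test_gelman_rubin_limits(rng):
    same = rng.normal(0, 1, (3, 4000))
    assert gelman_rubin(same) == pytest.approx(1.0, abs=0.02)
    apart = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
    assert gelman_rubin(apart) > 10


def test_gelman_rubin_single_chain_unavailable():
    with pytest.raises(ValueError, match="2 chains"):
        gelman_rubin(np.ones((1, 100)))


def test_gelman_rubin_matches_arviz(rng):
    arviz = pytest.importorskip("arviz")
    x = rng.normal(0, 1, (3, 400)) + np.array([[0.0], [0.4], [0.1]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert gelman_rubin(x) == pytest.approx(float(arviz.rhat(x, method="identity")), rel=1e-10)
        assert gelman_rubin(x, split=True) == pytest.approx(
            float(arviz.rhat(x, method="split")), rel=1e-10
        )


def test_extract_parameter_and_rhat_table(small_fit):
    mu = extract_parameter(small_fit, "mu_trans[4,4]")
    assert mu.shape == (small_fit.n_chains, small_fit.n_draws_per_chain)
    np.testing.assert_array_equal(mu, small_fit.mu_trans[:, :, 3, 2])
    with pytest.raises(KeyError):
        extract_parameter(small_fit, "nonsense[1]")
    table = rhat_table(small_fit)
    assert {"parameter", "rhat"} <= set(table.columns)
    assert np.isfinite(table["rhat"]).all()


def test_ffbs_matches_exact_conditional(rng):
    """FFBS path frequencies agree with enumeration (chi-square, 10^4 draws)."""
    scipy_stats = pytest.importorskip("scipy.stats")
    T = 3
    params = random_params(rng, n_seasons=T)
    visits = [[(0.5, 2)], [], [(-0.3, 1), (0.2, 3)]]
    exact = enumerate_path_posterior(visits, params)

    # detection log-likelihood table for the kernel
    L = np.zeros((T, 4))
    from msodyn.model import build_dpm_from_coeffs

    for t, vs in enumerate(visits):
        for jd, y in vs:
            with np.errstate(divide="ignore"):
                L[t] += np.log(build_dpm_from_coeffs(params.detection.coeffs[t], jd)[:, y - 1])
    _kernel.seed_rng(99)
    n = 10_000
    draws = _kernel.ffbs_draws(params.phi0, params.transition.tpms(), L, n)
    observed = {}
    for row in draws + 1:
        observed[tuple(row)] = observed.get(tuple(row), 0) + 1
    paths = [p for p, pr in exact.items() if pr > 1e-12]
    expected_counts = np.array([exact[p] * n for p in paths])
    observed_counts = np.array([observed.get(p, 0) for p in paths])
    assert observed_counts.sum() == n  # nothing lands on impossible paths
    # pool tiny-expectation cells for chi-square validity
    keep = expected_counts >= 5
    chisq = float(
        (((observed_counts[keep] - expected_counts[keep]) ** 2) / expected_counts[keep]).sum()
    )
    dof = int(keep.sum()) - 1
    assert chisq < scipy_stats.chi2.ppf(0.999, dof)


def test_prior_reproduction_without_data():
    """With zero visits the sampler must return the priors for hyper-means.

    Joint correctness check: a Gibbs sampler that targets the posterior of a
    model with no likelihood terms must reproduce its priors: hyper-means
    N(0, sd √2), hyper-SDs Gamma(2, 0.5) with mean 4, uniform ϕ0.
    """
    empty_i = np.empty(0, dtype=np.int32)
    empty_f = np.empty(0, dtype=np.float64)
    res = _kernel.run_chain(
        11, 30_000, 2_000, 5, 5, 5,
        empty_i, empty_i, empty_f, empty_i,
        np.zeros(6, dtype=np.int64),
        np.ones(4), np.sqrt(2.0), 2.0, 0.5, False,
    )
    mu, sig, phi0 = res[2], res[3], res[0]
    assert np.all(np.abs(mu.mean(axis=0)) < 0.25)
    assert np.all(mu.std(axis=0) > 1.25) and np.all(mu.std(axis=0) < 1.6)
    assert sig.mean() == pytest.approx(4.0, abs=0.5)
    np.testing.assert_allclose(phi0.mean(axis=0), 0.25, atol=0.03)


def test_convergence_warning_on_short_run(small_truth):
    """Very short chains on weakly informed parameters should warn, not fail."""
    cfg = McmcConfig(n_chains=2, n_iter=260, n_burnin=60, thin=1, seed=1)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        draws = sample_posterior(small_truth.data, config=cfg, block="A")
    assert draws.n_draws == 400
    assert any(issubclass(w.category, ConvergenceWarning) for w in caught)


def test_npz_round_trip(small_fit, tmp_path):
    path = save_npz(small_fit, tmp_path / "draws.npz")
    back = load_npz(path)
    assert back.block == small_fit.block
    assert back.territory_ids == small_fit.territory_ids
    np.testing.assert_array_equal(back.z, small_fit.z)
    np.testing.assert_array_equal(back.mu_trans, small_fit.mu_trans)
    assert back.config == small_fit.config


def test_posterior_tracks_dominant_transitions(small_truth, small_fit):
    """Posterior mean TPM at hyper-means should correlate with the truth's."""
    truth_tpm = build_tpm(small_truth.config.trans_mu)
    post_tpm = np.mean(
        [build_tpm(mu) for mu in small_fit.mu_trans.reshape(-1, 4, 3)[::20]], axis=0
    )
    # occupied-state rows are well informed; demand positive association
    corr = np.corrcoef(truth_tpm[2:].ravel(), post_tpm[2:].ravel())[0, 1]
    assert corr > 0.5
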