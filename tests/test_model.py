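import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msodyn.model import (
    LatentStates,
    build_dpm_from_coeffs,
    build_tpm,
    build_tpm_row,
    complete_data_loglik,
    marginal_loglik_territory,
    state_marginals,
)
from oracles import (
    enumerate_marginal_loglik,
    naive_state_marginals,
    random_params,
    random_visits,
)

finite_effects = st.floats(-30, 30, allow_nan=False)


def test_tpm_row_symmetry_and_limits():
    np.testing.assert_allclose(build_tpm_row(np.zeros(3)), np.full(4, 0.25))
    near_baseline = build_tpm_row(np.array([-1e6, -1e6, -1e6]))
    np.testing.assert_allclose(near_baseline, [1, 0, 0, 0], atol=1e-12)


def test_tpm_row_direct_evaluation():
    row = build_tpm_row(np.log([2.0, 3.0, 4.0]))
    np.testing.assert_allclose(row, [0.1, 0.2, 0.3, 0.4], rtol=1e-14)


def test_tpm_row_rejects_nonfinite():
    with pytest.raises(ValueError):
        build_tpm_row(np.array([np.nan, 0.0, 0.0]))


@given(st.lists(finite_effects, min_size=12, max_size=12))
@settings(max_examples=200, deadline=None)
def test_tpm_rows_stochastic(betas):
    tpm = build_tpm(np.array(betas).reshape(4, 3))
    assert np.all(tpm >= 0) and np.all(tpm <= 1)
    np.testing.assert_allclose(tpm.sum(axis=1), 1.0, atol=1e-12)


def test_dpm_symmetric_cases():
    dpm = build_dpm_from_coeffs(np.zeros((3, 3, 3)), jd_std=1.7)
    np.testing.assert_allclose(dpm[0], [1, 0, 0, 0])
    np.testing.assert_allclose(dpm[1], [0.5, 0.5, 0, 0])
    np.testing.assert_allclose(dpm[2], [1 / 3, 1 / 3, 1 / 3, 0])
    np.testing.assert_allclose(dpm[3], [0.25, 0.25, 0.25, 0.25])


def test_dpm_direct_evaluation():
    # true state 4, only the state-2 linear date term nonzero, jd = ln 2
    coeffs = np.zeros((3, 3, 3))
    coeffs[2, 0, 1] = 1.0
    jd = np.log(2.0)
    dpm = build_dpm_from_coeffs(coeffs, jd)
    assert dpm[3, 1] == pytest.approx(2.0 / (1 + 2 + 1 + 1), rel=1e-14)


@given(st.lists(finite_effects, min_size=27, max_size=27), st.floats(-3, 3))
@settings(max_examples=200, deadline=None)
def test_dpm_rows_stochastic_and_constrained(alphas, jd):
    dpm = build_dpm_from_coeffs(np.array(alphas).reshape(3, 3, 3), jd)
    np.testing.assert_allclose(dpm.sum(axis=1), 1.0, atol=1e-12)
    for m in range(4):
        for n in range(4):
            if n > m:
                assert dpm[m, n] == 0.0


def test_state_marginals_identity_and_deterministic():
    phi0 = np.array([0.2, 0.3, 0.4, 0.1])
    eye = [np.eye(4)] * 3
    out = state_marginals(phi0, eye)
    for row in out:
        np.testing.assert_allclose(row, phi0)
    tpm = np.zeros((4, 4))
    tpm[:, 1] = 1.0
    out = state_marginals(np.array([1.0, 0, 0, 0]), [tpm])
    np.testing.assert_allclose(out[1], [0, 1, 0, 0])


def test_state_marginals_matches_naive_summation(rng):
    for _ in range(25):
        phi0 = rng.dirichlet(np.ones(4))
        tpms = [build_tpm(rng.normal(0, 2, (4, 3))) for _ in range(rng.integers(1, 6))]
        mine = state_marginals(phi0, tpms)
        naive = naive_state_marginals(phi0, tpms)
        np.testing.assert_allclose(mine, naive, atol=1e-12)
        np.testing.assert_allclose(mine.sum(axis=1), 1.0, atol=1e-12)


def _single_territory_design(visits, n_seasons):
    """BlockDesign-like container for one territory."""
    from msodyn.encounters import BlockDesign

    terr, season, jd, y = [], [], [], []
    for t, vs in enumerate(visits):
        for jd_std, obs in vs:
            terr.append(0)
            season.append(t)
            jd.append(jd_std)
            y.append(obs)
    order = np.argsort(season, kind="stable")
    season_arr = np.array(season, dtype=np.int32)[order] if season else np.empty(0, np.int32)
    return BlockDesign(
        block="A",
        territory_ids=["t0"],
        first_year=2000,
        n_seasons=n_seasons,
        visit_terr=np.array(terr, dtype=np.int32)[order] if terr else np.empty(0, np.int32),
        visit_season=season_arr,
        visit_jd=np.array(jd, dtype=float)[order] if jd else np.empty(0, float),
        visit_y=np.array(y, dtype=np.int32)[order] if y else np.empty(0, np.int32),
        season_offsets=np.searchsorted(season_arr, np.arange(n_seasons + 1)).astype(np.int64),
    )


def test_complete_data_loglik_single_term(rng):
    params = random_params(rng, n_seasons=1)
    design = _single_territory_design([[]], 1)
    z = LatentStates(z=np.array([[3]]))
    assert complete_data_loglik(z, design, params) == pytest.approx(np.log(params.phi0[2]))


def test_complete_data_loglik_impossible_observation(rng):
    params = random_params(rng, n_seasons=1)
    design = _single_territory_design([[(0.0, 4)]], 1)
    z = LatentStates(z=np.array([[2]]))
    assert complete_data_loglik(z, design, params) == -np.inf


def test_complete_data_loglik_term_by_term(rng):
    """2 territories × 3 seasons equals the hand-summed product of factors."""
    from msodyn.encounters import BlockDesign
    from msodyn.model import build_dpm_from_coeffs

    params = random_params(rng, n_seasons=3)
    visits = {(0, 0): [(0.3, 2)], (0, 2): [(-0.2, 1), (0.5, 3)], (1, 1): [(0.1, 2)]}
    zz = np.array([[3, 2, 4], [1, 2, 2]])
    rows = sorted(visits.items(), key=lambda kv: kv[0][1])
    terr = np.array([i for (i, t), vs in rows for _ in vs], dtype=np.int32)
    season = np.array([t for (i, t), vs in rows for _ in vs], dtype=np.int32)
    jd = np.array([v[0] for (_, _), vs in rows for v in vs])
    y = np.array([v[1] for (_, _), vs in rows for v in vs], dtype=np.int32)
    design = BlockDesign(
        block="A", territory_ids=["a", "b"], first_year=2000, n_seasons=3,
        visit_terr=terr, visit_season=season, visit_jd=jd, visit_y=y,
        season_offsets=np.searchsorted(season, np.arange(4)).astype(np.int64),
    )
    expected = 0.0
    tpms = params.transition.tpms()
    for i in range(2):
        expected += np.log(params.phi0[zz[i, 0] - 1])
        for t in range(2):
            expected += np.log(tpms[t][zz[i, t] - 1, zz[i, t + 1] - 1])
    for (i, t), vs in visits.items():
        for jd_std, obs in vs:
            dpm = build_dpm_from_coeffs(params.detection.coeffs[t], jd_std)
            expected += np.log(dpm[zz[i, t] - 1, obs - 1])
    got = complete_data_loglik(LatentStates(z=zz), design, params)
    assert got == pytest.approx(expected, rel=1e-12)


def test_marginal_loglik_no_visits_is_zero(rng):
    params = random_params(rng, n_seasons=1)
    assert marginal_loglik_territory([[]], params) == pytest.approx(0.0, abs=1e-12)
    params3 = random_params(rng, n_seasons=3)
    assert marginal_loglik_territory([[], [], []], params3) == pytest.approx(0.0, abs=1e-10)


def test_marginal_loglik_matches_enumeration(rng):
    for _ in range(30):
        T = int(rng.integers(1, 5))
        params = random_params(rng, n_seasons=T)
        visits = random_visits(rng, T)
        mine = marginal_loglik_territory(visits, params)
        brute = enumerate_marginal_loglik(visits, params)
        if np.isinf(brute):
            assert np.isinf(mine)
        else:
            assert mine == pytest.approx(brute, abs=1e-10)


def test_marginal_loglik_visit_order_invariance(rng):
    """True state is constant within a season, so visit order cannot matter."""
    for _ in range(10):
        params = random_params(rng, n_seasons=3)
        visits = random_visits(rng, 3, max_visits=4)
        shuffled = [list(vs) for vs in visits]
        for vs in shuffled:
            rng.shuffle(vs)
        assert marginal_loglik_territory(visits, params) == pytest.approx(
            marginal_loglik_territory(shuffled, params), rel=1e-12
        )


def test_marginal_loglik_perfect_nondetection_depends_only_on_chain(rng):
    """If every DPM row collapses to 'observe state 1', observations carry no
    information and the likelihood is 1 for any all-ones history."""
    params = random_params(rng, n_seasons=3)
    params.detection.coeffs[:] = 0.0
    params.detection.coeffs[:, :, :, 0] = -60.0  # detection pushed to zero
    visits = [[(0.4, 1)], [(0.0, 1), (0.2, 1)], []]
    assert marginal_loglik_territory(visits, params) == pytest.approx(0.0, abs=1e-9)
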