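"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's forward-algorithm and recursion code
paths: likelihoods are obtained by exhaustive enumeration over all latent
state paths, and matrix recursions by naive per-entry summation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from msodyn.model import ModelParams, build_dpm_from_coeffs


def enumerate_marginal_loglik(visits, params: ModelParams) -> float:
    """log Σ over all 4^T latent paths of the complete-data likelihood."""
    T = params.n_seasons
    tpms = params.transition.tpms()
    # per-season, per-true-state visit log-likelihoods
    L = np.zeros((T, 4))
    for t, season_visits in enumerate(visits):
        for jd, y in season_visits:
            dpm = build_dpm_from_coeffs(params.detection.coeffs[t], jd)
            for m in range(4):
                p = dpm[m, y - 1]
                L[t, m] += math.log(p) if p > 0 else -math.inf
    total = -math.inf
    for path in product(range(4), repeat=T):
        lp = math.log(params.phi0[path[0]]) + L[0, path[0]]
        for t in range(T - 1):
            lp += math.log(tpms[t][path[t], path[t + 1]]) + L[t + 1, path[t + 1]]
        total = np.logaddexp(total, lp)
    return float(total)


def enumerate_path_posterior(visits, params: ModelParams) -> dict[tuple[int, ...], float]:
    """Exact posterior probability of every latent path (1-based states)."""
    T = params.n_seasons
    tpms = params.transition.tpms()
    L = np.zeros((T, 4))
    for t, season_visits in enumerate(visits):
        for jd, y in season_visits:
            dpm = build_dpm_from_coeffs(params.detection.coeffs[t], jd)
            for m in range(4):
                p = dpm[m, y - 1]
                L[t, m] += math.log(p) if p > 0 else -math.inf
    logps = {}
    for path in product(range(4), repeat=T):
        lp = math.log(params.phi0[path[0]]) + L[0, path[0]]
        for t in range(T - 1):
            lp += math.log(tpms[t][path[t], path[t + 1]]) + L[t + 1, path[t + 1]]
        logps[tuple(s + 1 for s in path)] = lp
    mx = max(logps.values())
    ps = {k: math.exp(v - mx) for k, v in logps.items()}
    z = sum(ps.values())
    return {k: v / z for k, v in ps.items()}


def naive_state_marginals(phi0, tpms) -> np.ndarray:
    """ϕ_t by explicit per-entry summation Σ_m ϕ_{t−1}[m]·Φ[m,n]."""
    out = [np.asarray(phi0, dtype=float)]
    for tpm in tpms:
        prev = out[-1]
        nxt = np.zeros(4)
        for n in range(4):
            for m in range(4):
                nxt[n] += prev[m] * tpm[m][n]
        out.append(nxt)
    return np.array(out)


def random_params(rng: np.random.Generator, n_seasons: int, scale: float = 1.5) -> ModelParams:
    """A random valid parameter set (no hierarchy involved)."""
    from msodyn.model import DetectionEffects, TransitionEffects

    coeffs = rng.normal(0, scale, size=(n_seasons, 3, 3, 3))
    for mi in range(3):
        coeffs[:, mi, mi + 1 :, :] = 0.0
    return ModelParams(
        phi0=rng.dirichlet(np.ones(4)),
        transition=TransitionEffects(
            beta0=rng.normal(0, scale, size=(max(n_seasons - 1, 0), 4, 3)),
            mu=np.zeros((4, 3)),
            sigma=np.ones((4, 3)),
        ),
        detection=DetectionEffects(
            coeffs=coeffs, mu=np.zeros((3, 3, 3)), sigma=np.ones((3, 3, 3))
        ),
    )


def random_visits(rng: np.random.Generator, n_seasons: int, max_visits: int = 3):
    """Random per-season visit lists (jd_std, observed state)."""
    visits = []
    for _t in range(n_seasons):
        k = int(rng.integers(0, max_visits + 1))
        visits.append(
            [(float(rng.normal(0, 1)), int(rng.integers(1, 5))) for _ in range(k)]
        )
    return visits
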