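"""Synthetic survey data with the exact generative structure the model assumes.

The generator draws season effects from the hierarchical normal
distributions, propagates latent territory states through the yearly
transition matrices, draws visit counts and dates per territory-year, and
draws observed states from the detection matrix rows at standardized dates —
so every pipeline stage can be tested against known truth.

The default configuration emulates the monitoring design of the Mendocino
County northern spotted owl study: three blocks of 18, 62, and 24
territories, seasons 1990–2014 (block C truncated at 2006), 1–15 daytime
visits per territory-year with median 3, and visit dates between March 1 and
August 31. The default "true" hyperparameters are synthetic: they are chosen
so that all four states occur with non-negligible frequency and detection is
best for reproducing pairs, weakest for single owls, but they are not
estimates from any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encounters import DEFAULT_DATE_WINDOW, StudyData
from .model import (
    DetectionEffects,
    LatentStates,
    ModelParams,
    TransitionEffects,
    build_dpm_from_coeffs,
    build_tpm,
    state_marginals,
)

# multi-logit transition effects by origin state (rows 1..4, destinations 2..4):
# unoccupied territories mostly stay empty; pairs persist and trade places
# between the reproducing and non-reproducing states.
DEFAULT_TRANS_MU = np.array(
    [
        [-1.5, -2.5, -3.5],
        [0.5, -0.5, -1.5],
        [-0.3, 1.0, 0.5],
        [-0.5, 0.8, 1.2],
    ]
)
DEFAULT_TRANS_SIGMA = np.full((4, 3), 0.5)

# detection coefficient hyper-means [true m−2][obs n−2][intercept, JD, JD²]:
# detection strongest for reproducing pairs, weak for single owls (daytime
# visit-level detection of singles ≲ 0.25), with a mild mid/late-season peak.
DEFAULT_DET_MU = np.array(
    [
        [[-1.2, 0.2, -0.1], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
        [[-1.5, 0.0, 0.0], [0.3, 0.2, -0.1], [0.0, 0.0, 0.0]],
        [[-2.0, 0.0, 0.0], [-0.7, 0.0, 0.0], [1.2, 0.3, -0.15]],
    ]
)
DEFAULT_DET_SIGMA = np.stack(
    [np.full((3, 3), 0.4), np.full((3, 3), 0.2), np.full((3, 3), 0.1)], axis=-1
)

# mostly-occupied initial sample: monitoring programs begin from known sites
DEFAULT_PHI0 = np.array([0.10, 0.15, 0.35, 0.40])

# visit-count distribution over 1..15 visits: median 3, mean ≈ 3.5, range 1–15
DEFAULT_VISIT_PROBS = np.array(
    [0.13, 0.20, 0.27, 0.16, 0.10, 0.06, 0.03, 0.02, 0.01, 0.008, 0.005, 0.004, 0.002, 0.0006, 0.0004]
)
DEFAULT_VISIT_PROBS = DEFAULT_VISIT_PROBS / DEFAULT_VISIT_PROBS.sum()

_MIN_SIGMA = 1e-9  # effects containers require strictly positive SDs


@dataclass(frozen=True)
class BlockSpec:
    label: str
    n_territories: int
    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.n_territories < 1:
            raise ValueError("n_territories must be >= 1")
        if self.last_year < self.first_year:
            raise ValueError("last_year must be >= first_year")


@dataclass
class SimConfig:
    """Configuration of the generative model and survey design."""

    blocks: list[BlockSpec]
    visit_probs: np.ndarray = field(default_factory=lambda: DEFAULT_VISIT_PROBS.copy())
    date_window: tuple[int, int] = DEFAULT_DATE_WINDOW
    trans_mu: np.ndarray = field(default_factory=lambda: DEFAULT_TRANS_MU.copy())
    trans_sigma: np.ndarray = field(default_factory=lambda: DEFAULT_TRANS_SIGMA.copy())
    trans_mu_drift: np.ndarray | None = None  # (4, 3) added as drift·t to season-t effects
    trans_mu_by_season: np.ndarray | None = None  # (n_transitions, 4, 3) explicit season means
    det_mu: np.ndarray = field(default_factory=lambda: DEFAULT_DET_MU.copy())
    det_sigma: np.ndarray = field(default_factory=lambda: DEFAULT_DET_SIGMA.copy())
    phi0_true: np.ndarray = field(default_factory=lambda: DEFAULT_PHI0.copy())
    perfect_detection: bool = False
    april_june_dates: bool = False  # concentrate visit dates in April–June
    seed: int = 0

    def __post_init__(self) -> None:
        self.visit_probs = np.asarray(self.visit_probs, dtype=float)
        if self.visit_probs.ndim != 1 or np.any(self.visit_probs < 0):
            raise ValueError("visit_probs must be a non-negative vector over counts 1..K")
        self.visit_probs = self.visit_probs / self.visit_probs.sum()
        lo, hi = self.date_window
        if not (1 <= lo < hi <= 366):
            raise ValueError("date_window must satisfy 1 <= lo < hi <= 366")
        if hi - lo + 1 < len(self.visit_probs):
            raise ValueError("date window shorter than the maximum visit count")
        self.phi0_true = np.asarray(self.phi0_true, dtype=float)
        if abs(self.phi0_true.sum() - 1.0) > 1e-9 or np.any(self.phi0_true < 0):
            raise ValueError("phi0_true must be a probability vector")


@dataclass
class SimTruth:
    """A generated dataset together with the parameters and states behind it."""

    params: dict[str, ModelParams]
    z: dict[str, LatentStates]
    data: StudyData
    config: SimConfig

    def truth_json(self, path: str | Path | None = None) -> str:
        payload = {
            block: {
                "params": json.loads(p.to_json()),
                "z": self.z[block].z.tolist(),
                "territory_ids": self.z[block].territory_ids,
                "first_year": self.z[block].first_year,
            }
            for block, p in self.params.items()
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def mendocino_preset(seed: int = 0, **overrides) -> SimConfig:
    """Design preset for the Mendocino County study: 104 territories.

    Blocks A/B/C with 18/62/24 territories; seasons 1990–2014, block C
    surveyed only through 2006.
    """
    return SimConfig(
        blocks=[
            BlockSpec("A", 18, 1990, 2014),
            BlockSpec("B", 62, 1990, 2014),
            BlockSpec("C", 24, 1990, 2006),
        ],
        seed=seed,
        **overrides,
    )


def _draw_block_params(config: SimConfig, spec: BlockSpec, rng: np.random.Generator) -> ModelParams:
    T = spec.last_year - spec.first_year + 1
    n_trans = T - 1
    sig_t = np.maximum(config.trans_sigma, 0.0)
    if config.trans_mu_by_season is not None:
        means = np.asarray(config.trans_mu_by_season, dtype=float)
        if means.shape != (n_trans, 4, 3):
            raise ValueError(
                f"trans_mu_by_season must be ({n_trans}, 4, 3) for block "
                f"{spec.label}, got {means.shape}"
            )
    else:
        means = np.broadcast_to(config.trans_mu, (n_trans, 4, 3)).copy()
        if config.trans_mu_drift is not None:
            means = means + np.arange(n_trans)[:, None, None] * np.asarray(config.trans_mu_drift)
    beta = rng.normal(means, np.broadcast_to(sig_t, (n_trans, 4, 3)))
    sig_d = np.maximum(config.det_sigma, 0.0)
    coeffs = rng.normal(
        np.broadcast_to(config.det_mu, (T, 3, 3, 3)),
        np.broadcast_to(sig_d, (T, 3, 3, 3)),
    )
    # zero the structurally unused entries (observed state above true state)
    for mi in range(3):
        coeffs[:, mi, mi + 1 :, :] = 0.0
    return ModelParams(
        phi0=config.phi0_true,
        transition=TransitionEffects(
            beta0=beta,
            mu=config.trans_mu,
            sigma=np.maximum(config.trans_sigma, _MIN_SIGMA),
        ),
        detection=DetectionEffects(
            coeffs=coeffs,
            mu=config.det_mu,
            sigma=np.maximum(config.det_sigma, _MIN_SIGMA),
        ),
        block_id=spec.label,
    )


def _draw_states(params: ModelParams, n_territories: int, rng: np.random.Generator) -> np.ndarray:
    T = params.n_seasons
    z = np.empty((n_territories, T), dtype=int)
    z[:, 0] = rng.choice(4, size=n_territories, p=params.phi0) + 1
    for t in range(T - 1):
        tpm = params.transition.tpm(t)
        for i in range(n_territories):
            z[i, t + 1] = rng.choice(4, p=tpm[z[i, t] - 1]) + 1
    return z


def generate(config: SimConfig) -> SimTruth:
    """Generate a full synthetic dataset; fully reproducible given config.seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.date_window
    if config.april_june_dates:
        days = np.arange(91, 182)  # Apr 1 – Jun 30
    else:
        days = np.arange(lo, hi + 1)
    max_visits = len(config.visit_probs)

    params: dict[str, ModelParams] = {}
    latents: dict[str, LatentStates] = {}
    visit_rows: list[tuple[str, str, int, int, int, int]] = []  # block, terr, year, jd, t, zstate
    for spec in config.blocks:
        p = _draw_block_params(config, spec, rng)
        z = _draw_states(p, spec.n_territories, rng)
        terr_ids = [f"{spec.label}{i + 1:03d}" for i in range(spec.n_territories)]
        params[spec.label] = p
        latents[spec.label] = LatentStates(z=z, territory_ids=terr_ids, first_year=spec.first_year)
        counts = rng.choice(np.arange(1, max_visits + 1), size=z.shape, p=config.visit_probs)
        for i in range(spec.n_territories):
            for t in range(z.shape[1]):
                dates = np.sort(rng.choice(days, size=counts[i, t], replace=False))
                for jd in dates:
                    visit_rows.append(
                        (spec.label, terr_ids[i], spec.first_year + t, int(jd), t, z[i, t])
                    )

    jd_all = np.array([r[3] for r in visit_rows], dtype=float)
    center = float(jd_all.mean())
    scale = float(jd_all.std(ddof=1))

    obs = np.empty(len(visit_rows), dtype=int)
    for v, (block, _terr, _year, jd, t, zstate) in enumerate(visit_rows):
        if config.perfect_detection:
            obs[v] = zstate
            continue
        dpm = build_dpm_from_coeffs(
            params[block].detection.coeffs[t], (jd - center) / scale
        )
        obs[v] = rng.choice(4, p=dpm[zstate - 1]) + 1

    df = pd.DataFrame(
        {
            "block": [r[0] for r in visit_rows],
            "territory": [r[1] for r in visit_rows],
            "year": [r[2] for r in visit_rows],
            "julian_date": [r[3] for r in visit_rows],
            "observed_state": obs,
            "jd_std": (jd_all - center) / scale,
        }
    )
    data = StudyData(records=df, jd_center=center, jd_scale=scale)
    return SimTruth(params=params, z=latents, data=data, config=config)


def expected_state_counts(
    phi0: np.ndarray,
    trans_mu: np.ndarray,
    n_seasons: int,
    n_territories: int,
    trans_mu_drift: np.ndarray | None = None,
    state: int = 4,
) -> np.ndarray:
    """Expected per-season count of territories in ``state`` at zero hyper-SD.

    With the season effects pinned at their (possibly drifting) means, the
    yearly TPMs are deterministic and the expected count follows from the
    state-probability recursion.
    """
    tpms = []
    for t in range(n_seasons - 1):
        b = np.asarray(trans_mu, dtype=float)
        if trans_mu_drift is not None:
            b = b + t * np.asarray(trans_mu_drift)
        tpms.append(build_tpm(b))
    marg = state_marginals(np.asarray(phi0, dtype=float), tpms)
    return n_territories * marg[:, state - 1]


def trend_scenario(
    n_territories: int = 10,
    n_seasons: int = 15,
    slope: float = -0.5,
    p4_start: float = 0.85,
    seed: int = 0,
    label: str = "T",
    first_year: int = 2000,
) -> SimConfig:
    """A generator configuration with a built-in linear trend in state 4.

    The latent chain is made memoryless (all TPM rows equal each season) and
    the season-t share of state 4 is set to p4_start + t·slope/n, so the
    expected count of reproducing territories declines exactly linearly at
    ``slope`` territories per season. Remaining probability mass is split
    among states 1–3 in fixed proportions. Detection intercepts are raised
    relative to the defaults so imputation noise stays small compared to the
    built-in trend.
    """
    p4 = p4_start + np.arange(n_seasons) * slope / n_territories
    if p4.min() <= 0.01 or p4.max() >= 0.99:
        raise ValueError(
            "state-4 share leaves (0.01, 0.99); adjust p4_start, slope, or n"
        )
    weights = np.array([0.30, 0.25, 0.45])  # states 1..3 share of the rest
    probs = np.empty((n_seasons, 4))
    probs[:, 3] = p4
    probs[:, :3] = (1.0 - p4)[:, None] * weights
    logits = np.log(probs[:, 1:] / probs[:, :1])  # multi-logit vs state 1
    # TPM for the t -> t+1 transition realizes the season-(t+1) distribution
    by_season = np.repeat(logits[1:, None, :], 4, axis=1)  # rows identical
    det_mu = DEFAULT_DET_MU.copy()
    det_mu[:, :, 0] += 1.5
    return SimConfig(
        blocks=[BlockSpec(label, n_territories, first_year, first_year + n_seasons - 1)],
        trans_mu=logits.mean(axis=0)[None, :].repeat(4, axis=0),
        trans_sigma=np.zeros((4, 3)),
        trans_mu_by_season=by_season,
        det_mu=det_mu,
        phi0_true=probs[0],
        seed=seed,
    )


def prior_predictive_config(
    blocks: list[BlockSpec],
    priors=None,
    seed: int = 0,
) -> SimConfig:
    """A :class:`SimConfig` whose true hyperparameters are drawn from the priors.

    Used for simulation-based calibration: when each replicate's truth is a
    draw from the model's own priors, posterior credible intervals cover the
    truth at exactly their nominal rate if the sampler is correct.
    ``priors`` defaults to :class:`msodyn.inference.PriorSpec`.
    """
    from .inference import PriorSpec  # local import to avoid a cycle

    priors = priors or PriorSpec()
    rng = np.random.default_rng(seed)
    sd = priors.mean_prior_sd
    shape, rate = priors.re_sd_gamma_shape, priors.re_sd_gamma_rate

    def sd_draw(size):
        s = rng.gamma(shape, 1.0 / rate, size=size)
        return np.sqrt(s) if priors.sd_prior_on == "variance" else s

    det_mu = rng.normal(0.0, sd, size=(3, 3, 3))
    det_sigma = sd_draw((3, 3, 3))
    for mi in range(3):  # structurally unused entries
        det_mu[mi, mi + 1 :, :] = 0.0
    return SimConfig(
        blocks=blocks,
        trans_mu=rng.normal(0.0, sd, size=(4, 3)),
        trans_sigma=sd_draw((4, 3)),
        det_mu=det_mu,
        det_sigma=det_sigma,
        phi0_true=rng.dirichlet(np.asarray(priors.phi0_dirichlet, dtype=float)),
        seed=int(rng.integers(2**31)),
    )


def calibrate_drift(
    phi0: np.ndarray,
    trans_mu: np.ndarray,
    drift_direction: np.ndarray,
    n_seasons: int,
    n_territories: int,
    target_slope: float,
    state: int = 4,
    bracket: tuple[float, float] = (0.0, 2.0),
    tol: float = 1e-10,
) -> float:
    """Scale a drift direction so the expected count declines at a target rate.

    Finds the multiplier c (by bisection) such that the least-squares slope of
    the expected ``state`` counts under season effects μ + c·D·t equals
    ``target_slope`` territories per season. Used to construct synthetic
    datasets with a known built-in trend.
    """
    yrs = np.arange(n_seasons, dtype=float)
    d = yrs - yrs.mean()
    denom = (d * d).sum()

    def slope(c: float) -> float:
        counts = expected_state_counts(
            phi0, trans_mu, n_seasons, n_territories,
            trans_mu_drift=c * np.asarray(drift_direction), state=state,
        )
        return float(counts @ d / denom)

    lo, hi = bracket
    f_lo, f_hi = slope(lo) - target_slope, slope(hi) - target_slope
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target slope {target_slope} not bracketed: slopes "
            f"({slope(lo):.3f}, {slope(hi):.3f}) at multipliers {bracket}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = slope(mid) - target_slope
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)
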