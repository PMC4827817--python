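"""Four-state dynamic occupancy model: transition/detection matrices and likelihoods.

The latent state z_it of territory i in season t takes values in {1, 2, 3, 4}
(1 = unoccupied, 2 = single owl, 3 = pair, 4 = reproducing pair) and evolves as
a Markov chain with a season-specific row-stochastic transition probability
matrix (TPM). Each visit j yields an observed state y_itj drawn from the row
of a detection probability matrix (DPM) for the true state, under the
classification constraint that a state higher than the truth cannot be
observed: p[m, n] = 0 whenever n > m. Both matrices are built from
unconstrained real effects through a multi-logit (softmax) link with state 1
as the baseline category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

N_STATES = 4
#: valid (true m, observed n) detection entries above the baseline, 1-based
DETECTION_ENTRIES = tuple(
    (m, n) for m in (2, 3, 4) for n in (2, 3, 4) if n <= m
)


def _softmax_with_baseline(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax over [0, logits...] — baseline category prepended with logit 0.

    Log-sum-exp stabilized so large |logits| (plausible under vague
    hyperpriors) never overflow.
    """
    logits = np.asarray(logits, dtype=float)
    full = np.concatenate(
        [np.zeros(logits.shape[:-1] + (1,)), logits], axis=-1
    )
    full = np.moveaxis(full, -1, axis) if axis != -1 else full
    m = np.max(full, axis=axis, keepdims=True)
    e = np.exp(full - m)
    return e / e.sum(axis=axis, keepdims=True)


def build_tpm_row(beta_row: np.ndarray) -> np.ndarray:
    """Multi-logit transition row from 3 effects for destination states 2..4.

    Entry n (n = 2..4) is exp(β_n) / (1 + Σ_l exp(β_l)); entry 1 is the
    baseline 1 / (1 + Σ_l exp(β_l)).
    """
    beta_row = np.asarray(beta_row, dtype=float)
    if beta_row.shape != (3,):
        raise ValueError(f"expected 3 effects for destination states 2..4, got {beta_row.shape}")
    if not np.all(np.isfinite(beta_row)):
        raise ValueError("non-finite transition effects")
    return _softmax_with_baseline(beta_row)


def build_tpm(beta: np.ndarray) -> np.ndarray:
    """Full 4×4 TPM from a (4, 3) array of effects (rows = origin states)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_STATES, 3):
        raise ValueError(f"expected (4, 3) transition effects, got {beta.shape}")
    return np.vstack([build_tpm_row(beta[m]) for m in range(N_STATES)])


def build_dpm_from_coeffs(alpha_t: np.ndarray, jd_std: float) -> np.ndarray:
    """4×4 DPM at one standardized visit date from one season's coefficients.

    ``alpha_t`` has shape (3, 3, 3): [true state m−2][observed state n−2]
    [intercept, linear, quadratic]. Row 1 is (1, 0, 0, 0): nothing can be
    observed at an unoccupied territory on a daytime visit. For true state m,
    the linear predictor of observed state n (2 ≤ n ≤ m) is
    α0 + α1·JD + α2·JD², and observed state 1 (no detection) is the baseline.
    """
    alpha_t = np.asarray(alpha_t, dtype=float)
    if alpha_t.shape != (3, 3, 3):
        raise ValueError(f"expected (3, 3, 3) detection coefficients, got {alpha_t.shape}")
    if not np.isfinite(jd_std):
        raise ValueError("non-finite standardized date")
    dpm = np.zeros((N_STATES, N_STATES))
    dpm[0, 0] = 1.0
    x = np.array([1.0, jd_std, jd_std**2])
    for mi in range(3):  # true state m = mi + 2
        eta = alpha_t[mi, : mi + 1] @ x  # observed states 2..m
        row = _softmax_with_baseline(eta)
        dpm[mi + 1, 0] = row[0]
        dpm[mi + 1, 1 : mi + 2] = row[1:]
    return dpm


@dataclass
class TransitionEffects:
    """Season-varying multi-logit transition effects with their hyperparameters.

    ``beta0[t, m, k]`` is the effect for the season-t transition from state
    m+1 to state k+2; each β is a draw from N(mu[m, k], sigma[m, k]²).
    """

    beta0: np.ndarray  # (n_transitions, 4, 3)
    mu: np.ndarray  # (4, 3)
    sigma: np.ndarray  # (4, 3)

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.beta0.ndim != 3 or self.beta0.shape[1:] != (N_STATES, 3):
            raise ValueError(f"beta0 must be (n_transitions, 4, 3), got {self.beta0.shape}")
        if np.any(self.sigma <= 0):
            raise ValueError("transition hyper-SDs must be strictly positive")

    @property
    def n_transitions(self) -> int:
        return self.beta0.shape[0]

    def tpm(self, t: int) -> np.ndarray:
        """TPM governing the transition from season t to season t+1."""
        return build_tpm(self.beta0[t])

    def tpms(self) -> np.ndarray:
        if self.n_transitions == 0:
            return np.empty((0, N_STATES, N_STATES))
        return np.stack([self.tpm(t) for t in range(self.n_transitions)])


@dataclass
class DetectionEffects:
    """Season-varying detection coefficients (intercept, date, date²) and hypers.

    ``coeffs[t, mi, n, k]``: season t, true state mi+2, observed state n+2,
    coefficient k ∈ {0: intercept, 1: linear, 2: quadratic date term}. Each
    coefficient is a draw from N(mu[mi, n, k], sigma[mi, n, k]²). Entries with
    observed state above the true state are structurally unused.
    """

    coeffs: np.ndarray  # (n_seasons, 3, 3, 3)
    mu: np.ndarray  # (3, 3, 3)
    sigma: np.ndarray  # (3, 3, 3)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[1:] != (3, 3, 3):
            raise ValueError(f"coeffs must be (n_seasons, 3, 3, 3), got {self.coeffs.shape}")
        if np.any(self.sigma <= 0):
            raise ValueError("detection hyper-SDs must be strictly positive")

    @property
    def n_seasons(self) -> int:
        return self.coeffs.shape[0]

    @property
    def alpha0(self) -> np.ndarray:
        return self.coeffs[..., 0]

    @property
    def alpha1(self) -> np.ndarray:
        return self.coeffs[..., 1]

    @property
    def alpha2(self) -> np.ndarray:
        return self.coeffs[..., 2]

    def dpm(self, t: int, jd_std: float) -> np.ndarray:
        return build_dpm_from_coeffs(self.coeffs[t], jd_std)


def build_dpm(effects: DetectionEffects, season: int, jd_std: float) -> np.ndarray:
    """DPM for one season at one standardized visit date."""
    return effects.dpm(season, jd_std)


@dataclass
class ModelParams:
    """All latent parameters of one block's model."""

    phi0: np.ndarray  # (4,) initial state probabilities
    transition: TransitionEffects
    detection: DetectionEffects
    block_id: str = "A"

    def __post_init__(self) -> None:
        self.phi0 = np.asarray(self.phi0, dtype=float)
        if self.phi0.shape != (N_STATES,):
            raise ValueError("phi0 must have length 4")
        if np.any(self.phi0 < 0) or abs(self.phi0.sum() - 1.0) > 1e-12:
            raise ValueError("phi0 must be a probability vector summing to 1")
        if self.detection.n_seasons != self.transition.n_transitions + 1:
            raise ValueError(
                "detection must cover n_transitions + 1 seasons "
                f"({self.detection.n_seasons} vs {self.transition.n_transitions})"
            )

    @property
    def n_seasons(self) -> int:
        return self.detection.n_seasons

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "block_id": self.block_id,
            "phi0": self.phi0.tolist(),
            "transition": {
                "beta0": self.transition.beta0.tolist(),
                "mu": self.transition.mu.tolist(),
                "sigma": self.transition.sigma.tolist(),
            },
            "detection": {
                "coeffs": self.detection.coeffs.tolist(),
                "mu": self.detection.mu.tolist(),
                "sigma": self.detection.sigma.tolist(),
            },
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            phi0=np.array(d["phi0"]),
            transition=TransitionEffects(
                beta0=np.array(d["transition"]["beta0"]),
                mu=np.array(d["transition"]["mu"]),
                sigma=np.array(d["transition"]["sigma"]),
            ),
            detection=DetectionEffects(
                coeffs=np.array(d["detection"]["coeffs"]),
                mu=np.array(d["detection"]["mu"]),
                sigma=np.array(d["detection"]["sigma"]),
            ),
            block_id=d["block_id"],
        )


@dataclass
class LatentStates:
    """Imputed true states z[i, t] ∈ {1..4} over a block's full season range."""

    z: np.ndarray  # (n_territories, n_seasons) int
    territory_ids: list[str] = field(default_factory=list)
    first_year: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        if self.z.ndim != 2:
            raise ValueError("z must be 2-D (territory × season)")
        if self.z.size and (self.z.min() < 1 or self.z.max() > N_STATES):
            raise ValueError("latent states must lie in {1,2,3,4}")
        if not self.territory_ids:
            self.territory_ids = [f"T{i:03d}" for i in range(self.z.shape[0])]


def state_marginals(phi0: np.ndarray, tpms: Sequence[np.ndarray]) -> np.ndarray:
    """Season state probabilities by the recursion ϕ_t = ϕ_{t−1} Φ_{t−1}.

    Returns an array of shape (len(tpms) + 1, 4) whose first row is ϕ0.
    """
    phi0 = np.asarray(phi0, dtype=float)
    if phi0.shape != (N_STATES,):
        raise ValueError("phi0 must have length 4")
    out = np.empty((len(tpms) + 1, N_STATES))
    out[0] = phi0
    for t, tpm in enumerate(tpms):
        tpm = np.asarray(tpm, dtype=float)
        if tpm.shape != (N_STATES, N_STATES):
            raise ValueError(f"TPM {t} has shape {tpm.shape}, expected (4, 4)")
        out[t + 1] = out[t] @ tpm
    return out


def _visit_log_probs(params: ModelParams, season: int, jd_std: float) -> np.ndarray:
    """log p(y | m) for one visit, shape (4 true, 4 observed); −inf where impossible."""
    dpm = params.detection.dpm(season, jd_std)
    with np.errstate(divide="ignore"):
        return np.log(dpm)


def complete_data_loglik(
    z: LatentStates,
    design,
    params: ModelParams,
) -> float:
    """Joint log density of latent trajectories and observations given parameters.

    ``design`` is a :class:`msodyn.encounters.BlockDesign`. Seasons with no
    visits contribute only their transition factor; an observation that is
    impossible under the constraint (y > z) yields −inf.
    """
    zz = z.z
    if zz.shape != (design.n_territories, design.n_seasons):
        raise ValueError("latent state array does not match the design")
    ll = 0.0
    with np.errstate(divide="ignore"):
        log_phi0 = np.log(params.phi0)
        log_tpms = np.log(params.transition.tpms())
    ll += float(log_phi0[zz[:, 0] - 1].sum())
    for t in range(design.n_seasons - 1):
        ll += float(log_tpms[t, zz[:, t] - 1, zz[:, t + 1] - 1].sum())
    for v in range(len(design.visit_y)):
        i, t = design.visit_terr[v], design.visit_season[v]
        lp = _visit_log_probs(params, t, design.visit_jd[v])
        ll += float(lp[zz[i, t] - 1, design.visit_y[v] - 1])
    return ll


def detection_logliks(
    params: ModelParams,
    visits: Sequence[Sequence[tuple[float, int]]],
) -> np.ndarray:
    """log p(all visits in season t | z_t = m) for one territory, shape (T, 4).

    ``visits[t]`` is a list of ``(jd_std, observed_state)`` pairs for season t.
    """
    T = params.n_seasons
    L = np.zeros((T, N_STATES))
    for t, season_visits in enumerate(visits):
        for jd_std, y in season_visits:
            L[t] += _visit_log_probs(params, t, jd_std)[:, y - 1]
    return L


def marginal_loglik_territory(
    visits: Sequence[Sequence[tuple[float, int]]],
    params: ModelParams,
) -> float:
    """Marginal log likelihood of one territory's visit history.

    Forward algorithm over the 4-state chain: the latent trajectory is summed
    out exactly, so this equals log Σ_paths exp(complete-data log likelihood).
    Computed with per-season rescaling for numerical stability.
    """
    T = params.n_seasons
    if len(visits) != T:
        raise ValueError(f"need visit lists for all {T} seasons (empty lists allowed)")
    L = detection_logliks(params, visits)
    tpms = params.transition.tpms()
    logc = 0.0
    f = params.phi0 * np.exp(L[0] - L[0].max())
    logc += L[0].max()
    for t in range(1, T):
        s = f.sum()
        if s == 0.0:
            return -np.inf
        logc += np.log(s)
        f = (f / s) @ tpms[t - 1]
        f = f * np.exp(L[t] - L[t].max())
        logc += L[t].max()
    s = f.sum()
    if s == 0.0:
        return -np.inf
    return float(logc + np.log(s))
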