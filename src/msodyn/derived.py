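"""Posterior summaries: imputed state counts, trends, and averaged transitions.

Because the sampler imputes every territory's true state in every season,
population-level quantities — the number of territories in a state set, and
linear or polynomial trends in that number — are posterior functionals: they
are computed per retained draw and then summarized by the posterior mean and
equal-tailed credible interval (default 90%: 5th/95th sample quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import build_tpm_row


@dataclass
class StateCountDraws:
    """Per-draw, per-season counts of territories whose state is in a set."""

    counts: np.ndarray  # (n_draws, n_seasons)
    years: np.ndarray  # (n_seasons,)
    block: str
    state_set: frozenset[int]

    @property
    def n_draws(self) -> int:
        return self.counts.shape[0]

    def summary(self, level: float = 0.90) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return pd.DataFrame(
            {
                "year": self.years,
                "mean": self.counts.mean(axis=0),
                f"q{lo * 100:g}": np.quantile(self.counts, lo, axis=0),
                f"q{hi * 100:g}": np.quantile(self.counts, hi, axis=0),
            }
        )


@dataclass
class TrendEstimate:
    """Posterior mean and credible interval of a per-year trend in counts."""

    posterior_mean: float
    cri_lower: float
    cri_upper: float
    year_range: tuple[int, int]
    state_set: frozenset[int]
    level: float = 0.90
    draws: np.ndarray | None = None  # per-draw trend values

    def __post_init__(self) -> None:
        if not (self.cri_lower <= self.posterior_mean <= self.cri_upper):
            raise ValueError("credible interval must bracket the posterior mean")


def count_states(
    draws: PosteriorDraws,
    state_set: set[int] | frozenset[int],
    years: tuple[int, int] | None = None,
) -> StateCountDraws:
    """Per-draw count N_t of territories imputed in ``state_set`` each season.

    ``years`` restricts to an inclusive (first, last) window within the
    block's fitted range.
    """
    state_set = frozenset(int(s) for s in state_set)
    if not state_set:
        raise ValueError("state_set must be non-empty")
    if not state_set <= {1, 2, 3, 4}:
        raise ValueError(f"states must be in {{1,2,3,4}}, got {sorted(state_set)}")
    z = draws.z_stacked()  # (S, I, T)
    all_years = draws.years
    if years is not None:
        first, last = years
        if first < all_years[0] or last > all_years[-1]:
            raise ValueError(
                f"window {years} outside fitted seasons "
                f"({all_years[0]}–{all_years[-1]})"
            )
        sel = (all_years >= first) & (all_years <= last)
        z = z[:, :, sel]
        all_years = all_years[sel]
    member = np.isin(z, sorted(state_set))
    return StateCountDraws(
        counts=member.sum(axis=1).astype(float),
        years=all_years.copy(),
        block=draws.block,
        state_set=state_set,
    )


def _slope_per_draw(counts: np.ndarray, years: np.ndarray) -> np.ndarray:
    yr = years.astype(float)
    d = yr - yr.mean()
    denom = float((d * d).sum())
    if denom == 0.0:
        raise ValueError("trend undefined: need at least 2 distinct seasons")
    return counts @ d / denom


def linear_trend(
    counts: StateCountDraws,
    years: tuple[int, int] | None = None,
    level: float = 0.90,
) -> TrendEstimate:
    """Posterior linear trend in imputed counts (territories per year).

    For each retained draw s the least-squares slope
    T_L^(s) = Σ_t N_t^(s)(Yr_t − Ȳr) / Σ_t (Yr_t − Ȳr)² is evaluated; the
    estimate is the average over draws and the CRI its equal-tailed sample
    quantiles. A value of −1.0 means an average loss of one territory per
    year over the window.
    """
    yrs = counts.years
    c = counts.counts
    if years is not None:
        first, last = years
        sel = (yrs >= first) & (yrs <= last)
        if not sel.any():
            raise ValueError(f"window {years} outside count seasons")
        yrs, c = yrs[sel], c[:, sel]
    if yrs.size < 2:
        raise ValueError("trend undefined for a single season")
    slopes = _slope_per_draw(c, yrs)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return TrendEstimate(
        posterior_mean=float(slopes.mean()),
        cri_lower=float(np.quantile(slopes, lo)),
        cri_upper=float(np.quantile(slopes, hi)),
        year_range=(int(yrs[0]), int(yrs[-1])),
        state_set=counts.state_set,
        level=level,
        draws=slopes,
    )


def _orthonormal_poly(years: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial contrast vectors (constant column dropped).

    Columns are the degree-1..degree contrasts: orthogonal to the constant
    and to each other, scaled to unit norm (the QR construction used by
    standard polynomial-contrast routines).
    """
    x = years.astype(float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs so each contrast correlates positively with x^k
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q[:, 1:] * signs[1:]


def polynomial_trend(
    counts: StateCountDraws,
    years: tuple[int, int] | None = None,
    degree: int = 1,
    level: float = 0.90,
) -> list[TrendEstimate]:
    """Orthogonal-polynomial contrasts of imputed counts, one per degree.

    Contrast k (k = 1..degree) is c_k·N^(s) with c_k the orthonormal
    degree-k contrast over the window's years. The degree-1 contrast equals
    the linear slope times ‖Yr − Ȳr‖ (its normalization constant), so it
    reproduces :func:`linear_trend` up to that documented factor.
    """
    yrs = counts.years
    c = counts.counts
    if years is not None:
        first, last = years
        sel = (yrs >= first) & (yrs <= last)
        yrs, c = yrs[sel], c[:, sel]
    if yrs.size < degree + 1:
        raise ValueError(f"need at least {degree + 1} seasons for degree {degree}")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    contrasts = _orthonormal_poly(yrs, degree)
    out = []
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    for k in range(degree):
        vals = c @ contrasts[:, k]
        out.append(
            TrendEstimate(
                posterior_mean=float(vals.mean()),
                cri_lower=float(np.quantile(vals, lo)),
                cri_upper=float(np.quantile(vals, hi)),
                year_range=(int(yrs[0]), int(yrs[-1])),
                state_set=counts.state_set,
                level=level,
                draws=vals,
            )
        )
    return out


@dataclass
class TransitionSummary:
    """Posterior summary of an across-year transition probability."""

    from_state: int
    to_state: int
    posterior_mean: float
    cri_lower: float
    cri_upper: float
    draws: np.ndarray


def mean_transition_probs(
    draws: PosteriorDraws,
    from_state: int,
    to_state: int,
    level: float = 0.90,
) -> TransitionSummary:
    """Across-year transition probability evaluated at the hyper-means.

    Per retained draw, the multi-logit link is applied to the hyper-mean
    row μ^[m,·], giving the 'average year' probability of moving from
    ``from_state`` to ``to_state``; the posterior of that functional is then
    summarized. E.g. (4, 4) is the probability a reproducing territory
    reproduces again in an average year.
    """
    if from_state not in (1, 2, 3, 4) or to_state not in (1, 2, 3, 4):
        raise ValueError("states must be in {1,2,3,4}")
    mu = draws.mu_trans.reshape(-1, 4, 3)[:, from_state - 1, :]  # (S, 3)
    probs = np.array([build_tpm_row(row)[to_state - 1] for row in mu])
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return TransitionSummary(
        from_state=from_state,
        to_state=to_state,
        posterior_mean=float(probs.mean()),
        cri_lower=float(np.quantile(probs, lo)),
        cri_upper=float(np.quantile(probs, hi)),
        draws=probs,
    )


def trend_table(
    draws: PosteriorDraws,
    windows: list[tuple[int, int]],
    state_sets: dict[str, set[int]] | None = None,
    level: float = 0.90,
) -> pd.DataFrame:
    """Trend estimates per (window, state set) — one block's trend table.

    Default state sets: ``{"reproductive pairs only": {4},
    "pairs and reproductive pairs": {3, 4}}``. Windows beyond the block's
    fitted seasons raise.
    """
    state_sets = state_sets or {
        "reproductive pairs only": {4},
        "pairs and reproductive pairs": {3, 4},
    }
    rows = []
    for label, sset in state_sets.items():
        counts = count_states(draws, sset)
        for first, last in windows:
            est = linear_trend(counts, years=(first, last), level=level)
            rows.append(
                {
                    "block": draws.block,
                    "years": f"{first}-{last}",
                    "state": label,
                    "mean": est.posterior_mean,
                    f"q{(1 - level) / 2 * 100:g}": est.cri_lower,
                    f"q{(1 + level) / 2 * 100:g}": est.cri_upper,
                }
            )
    return pd.DataFrame(rows)
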