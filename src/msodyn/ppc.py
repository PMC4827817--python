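"""Posterior predictive checks against observed detection patterns.

For each retained posterior draw, a replicated dataset is simulated at the
real survey design (same territories, seasons, and visit dates) from the
draw's detection coefficients and imputed latent states. Discrepancy
statistics computed on detected states are compared between replicate and
observation; the posterior predictive p-value (ppp) is the fraction of draws
whose replicate statistic is at least the observed one. Values near 0 or 1
flag aspects of the data the model fails to reproduce.

The statistic set covers visit-level, yearly, and territory-level
aggregation of detected states. It is a generic reconstruction of standard
replicate-and-compare checking for this model class, not a re-implementation
of any particular published diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encounters import BlockDesign
from .inference import PosteriorDraws
from .model import LatentStates, ModelParams, build_dpm_from_coeffs

EXTREME_BOUNDS = (0.05, 0.95)

STATISTIC_NAMES = ("visit_state_freq", "yearly_state_counts", "naive_best_state")


@dataclass
class PpcResult:
    """One scalar discrepancy statistic with its replicate distribution."""

    statistic_name: str
    observed: float
    replicated: np.ndarray
    ppp: float

    @property
    def extreme(self) -> bool:
        lo, hi = EXTREME_BOUNDS
        return not (lo <= self.ppp <= hi)


def simulate_replicate(
    params: ModelParams,
    z: LatentStates,
    design: BlockDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicated observed states at the real visit design, shape (n_visits,).

    Each visit's state is drawn from the detection matrix row of the imputed
    true state at that visit's standardized date, so replicates always
    satisfy the classification constraint (no observation above the truth).
    """
    zz = z.z
    if zz.shape != (design.n_territories, design.n_seasons):
        raise ValueError("latent draw does not match the design")
    V = len(design.visit_y)
    out = np.empty(V, dtype=int)
    for v in range(V):
        t = design.visit_season[v]
        m = zz[design.visit_terr[v], t]
        if m == 1:
            out[v] = 1
            continue
        dpm = build_dpm_from_coeffs(params.detection.coeffs[t], design.visit_jd[v])
        out[v] = rng.choice(4, p=dpm[m - 1]) + 1
    return out


def _stat_values(design: BlockDesign, y: np.ndarray, which: str) -> dict[str, float]:
    if which == "visit_state_freq":
        return {
            f"visit_freq_state_{n}": float(np.count_nonzero(y == n)) for n in (1, 2, 3, 4)
        }
    if which == "yearly_state_counts":
        T = design.n_seasons
        out = {}
        for n in (1, 2, 3, 4):
            per_year = np.bincount(design.visit_season[y == n], minlength=T).astype(float)
            out[f"yearly_count_sd_state_{n}"] = float(per_year.std(ddof=1)) if T > 1 else 0.0
        return out
    if which == "naive_best_state":
        best: dict[tuple[int, int], int] = {}
        for v in range(len(y)):
            key = (int(design.visit_terr[v]), int(design.visit_season[v]))
            if y[v] > best.get(key, 0):
                best[key] = int(y[v])
        vals = np.array(list(best.values()))
        return {
            f"naive_best_state_{n}": float(np.count_nonzero(vals == n)) for n in (1, 2, 3, 4)
        }
    raise KeyError(f"unknown statistic {which!r}; choose from {STATISTIC_NAMES}")


def ppc_check(
    design: BlockDesign,
    draws: PosteriorDraws,
    statistics: tuple[str, ...] = STATISTIC_NAMES,
    max_draws: int = 500,
    seed: int = 0,
) -> list[PpcResult]:
    """Replicate-and-compare checks over the retained draws.

    Requires at least 100 retained draws. Every scalar statistic in each
    requested family yields one :class:`PpcResult`; results with
    ppp outside [0.05, 0.95] are flagged via :attr:`PpcResult.extreme`.
    """
    if draws.n_draws < 100:
        raise ValueError(f"need >= 100 retained draws for PPC, have {draws.n_draws}")
    for which in statistics:
        if which not in STATISTIC_NAMES:
            raise KeyError(f"unknown statistic {which!r}; choose from {STATISTIC_NAMES}")
    rng = np.random.default_rng(seed)
    observed: dict[str, float] = {}
    for which in statistics:
        observed.update(_stat_values(design, design.visit_y, which))

    C, S = draws.n_chains, draws.n_draws_per_chain
    total = C * S
    use = min(total, max_draws)
    picks = np.linspace(0, total - 1, use).astype(int)
    rep_values: dict[str, list[float]] = {k: [] for k in observed}
    for flat in picks:
        c, s = divmod(int(flat), S)
        params = draws.params_at(c, s)
        zdraw = LatentStates(
            z=draws.z[c, s],
            territory_ids=list(draws.territory_ids),
            first_year=draws.first_year,
        )
        y_rep = simulate_replicate(params, zdraw, design, rng)
        for which in statistics:
            for k, val in _stat_values(design, y_rep, which).items():
                rep_values[k].append(val)

    results = []
    for name, obs_val in observed.items():
        rep = np.asarray(rep_values[name])
        ppp = float(np.mean(rep >= obs_val))
        results.append(
            PpcResult(statistic_name=name, observed=obs_val, replicated=rep, ppp=ppp)
        )
    return results


def ppc_frame(results: list[PpcResult]) -> pd.DataFrame:
    """Tabular PPC report: statistic, observed, replicate quantiles, ppp, flag."""
    return pd.DataFrame(
        {
            "statistic": [r.statistic_name for r in results],
            "observed": [r.observed for r in results],
            "rep_q05": [float(np.quantile(r.replicated, 0.05)) for r in results],
            "rep_median": [float(np.median(r.replicated)) for r in results],
            "rep_q95": [float(np.quantile(r.replicated, 0.95)) for r in results],
            "ppp": [r.ppp for r in results],
            "extreme": [r.extreme for r in results],
        }
    )
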