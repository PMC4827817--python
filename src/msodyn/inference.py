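"""Priors, MCMC driver, posterior containers, and convergence diagnostics.

The sampler is a blocked Gibbs scheme that mirrors the latent-variable
structure of the model: latent trajectories are refreshed by exact
forward-filtering backward-sampling, the initial state probabilities by a
conjugate Dirichlet update, and the multi-logit random effects and their
hyperparameters by adaptive Metropolis-within-Gibbs (see
:mod:`msodyn._kernel`). One block of territories is fitted per call — every
parameter of the model varies by block.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import _kernel
from .encounters import BlockDesign, StudyData, block_arrays
from .model import DetectionEffects, ModelParams, TransitionEffects


class ConvergenceWarning(UserWarning):
    """Emitted when the Gelman–Rubin diagnostic exceeds its threshold."""


@dataclass
class PriorSpec:
    """Prior specification for one block's model.

    Defaults: Dirichlet(1,1,1,1) on the initial state probabilities; N(0, 2)
    on every random-effect hyper-mean, read as variance 2 (the JAGS
    ``dnorm(0, 0.5)`` precision convention); Gamma(shape 2, rate 0.5) on
    every random-effect SD. ``mean_prior_scale_is_variance=False`` reads the
    2 as an SD instead; ``sd_prior_on="variance"`` moves the gamma prior to
    σ².
    """

    phi0_dirichlet: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    re_mean_scale: float = 2.0
    mean_prior_scale_is_variance: bool = True
    re_sd_gamma_shape: float = 2.0
    re_sd_gamma_rate: float = 0.5
    sd_prior_on: str = "sd"  # or "variance"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.phi0_dirichlet):
            raise ValueError("Dirichlet concentrations must be positive")
        if self.re_sd_gamma_shape <= 0 or self.re_sd_gamma_rate <= 0:
            raise ValueError("gamma shape and rate must be positive")
        if self.sd_prior_on not in ("sd", "variance"):
            raise ValueError("sd_prior_on must be 'sd' or 'variance'")

    @property
    def mean_prior_sd(self) -> float:
        s = self.re_mean_scale
        return sqrt(s) if self.mean_prior_scale_is_variance else s


@dataclass
class McmcConfig:
    """Chain configuration. The default mirrors the full analysis protocol:
    3 chains × 55,000 iterations, 5,000 burn-in, thinning 1/100 → 1,500
    retained draws. Reduced configs are appropriate for small synthetic fits.
    """

    n_chains: int = 3
    n_iter: int = 55_000
    n_burnin: int = 5_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorDraws:
    """Thinned posterior draws for one block, with a leading chain axis.

    ``z`` holds imputed latent states (1-based) for every retained draw;
    hyper-level arrays follow the layout of :class:`msodyn.model`
    (0-based origin state m−1, destination/observed index n−2).
    """

    block: str
    territory_ids: list[str]
    first_year: int
    phi0: np.ndarray  # (C, S, 4)
    beta: np.ndarray  # (C, S, T-1, 4, 3)
    mu_trans: np.ndarray  # (C, S, 4, 3)
    sigma_trans: np.ndarray  # (C, S, 4, 3)
    alpha: np.ndarray  # (C, S, T, 3, 3, 3)
    mu_det: np.ndarray  # (C, S, 3, 3, 3)
    sigma_det: np.ndarray  # (C, S, 3, 3, 3)
    z: np.ndarray  # (C, S, I, T) int8
    acceptance: np.ndarray  # (C, 4)
    config: McmcConfig = field(default_factory=McmcConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)

    @property
    def n_chains(self) -> int:
        return self.phi0.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.phi0.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    @property
    def n_seasons(self) -> int:
        return self.z.shape[3]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_seasons)

    def z_stacked(self) -> np.ndarray:
        """All chains' latent-state draws stacked: (C·S, territories, seasons)."""
        C, S, I, T = self.z.shape
        return self.z.reshape(C * S, I, T)

    def params_at(self, chain: int, draw: int) -> ModelParams:
        """Reassemble one retained draw as a :class:`ModelParams`."""
        return ModelParams(
            phi0=self.phi0[chain, draw],
            transition=TransitionEffects(
                beta0=self.beta[chain, draw],
                mu=self.mu_trans[chain, draw],
                sigma=self.sigma_trans[chain, draw],
            ),
            detection=DetectionEffects(
                coeffs=self.alpha[chain, draw],
                mu=self.mu_det[chain, draw],
                sigma=self.sigma_det[chain, draw],
            ),
            block_id=self.block,
        )

    def hyperparam_frame(self) -> pd.DataFrame:
        """Long DataFrame of hyper-level draws (for CSV persistence)."""
        rows = []
        C, S = self.n_chains, self.n_draws_per_chain
        for c in range(C):
            for s in range(S):
                row: dict[str, float | int] = {"chain": c, "draw": s}
                for k in range(4):
                    row[f"phi0[{k + 1}]"] = self.phi0[c, s, k]
                for m in range(4):
                    for n in range(3):
                        row[f"mu_trans[{m + 1},{n + 2}]"] = self.mu_trans[c, s, m, n]
                        row[f"sigma_trans[{m + 1},{n + 2}]"] = self.sigma_trans[c, s, m, n]
                for mi in range(3):
                    for n in range(mi + 1):
                        for k in range(3):
                            row[f"mu_det[{mi + 2},{n + 2},{k}]"] = self.mu_det[c, s, mi, n, k]
                            row[f"sigma_det[{mi + 2},{n + 2},{k}]"] = self.sigma_det[c, s, mi, n, k]
                rows.append(row)
        return pd.DataFrame(rows)

    def latent_state_frame(self) -> pd.DataFrame:
        """Compact long table of imputed states (chain, draw, territory, year, state)."""
        C, S, I, T = self.z.shape
        years = self.years
        c_idx, s_idx, i_idx, t_idx = np.meshgrid(
            np.arange(C), np.arange(S), np.arange(I), np.arange(T), indexing="ij"
        )
        return pd.DataFrame(
            {
                "chain": c_idx.ravel(),
                "draw": s_idx.ravel(),
                "territory": np.asarray(self.territory_ids)[i_idx.ravel()],
                "year": years[t_idx.ravel()],
                "state": self.z.ravel(),
            }
        )


def sample_posterior(
    data: StudyData,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    block: str | None = None,
    design: BlockDesign | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of one block's parameters and latent states.

    ``data`` must be date-standardized (see
    :func:`msodyn.encounters.standardize_dates`). Either ``block`` (a label in
    the data) or a pre-compiled ``design`` must be given. Runs are fully
    reproducible given ``config.seed``; chains receive distinct sub-seeds.

    A :class:`ConvergenceWarning` is raised (not an error) when any monitored
    hyperparameter has a Gelman–Rubin statistic above 1.1.
    """
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    if design is None:
        if block is None:
            raise ValueError("pass either block or design")
        design = block_arrays(data, block)

    chain_seeds = [
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(config.n_chains) % (2**31)
    ]
    results = []
    for seed in chain_seeds:
        results.append(
            _kernel.run_chain(
                seed,
                config.n_iter,
                config.n_burnin,
                config.thin,
                design.n_territories,
                design.n_seasons,
                design.visit_terr,
                design.visit_season,
                design.visit_jd,
                design.visit_y,
                design.season_offsets,
                np.asarray(priors.phi0_dirichlet, dtype=float),
                priors.mean_prior_sd,
                priors.re_sd_gamma_shape,
                priors.re_sd_gamma_rate,
                priors.sd_prior_on == "variance",
            )
        )
    stack = lambda j: np.stack([r[j] for r in results])  # noqa: E731
    draws = PosteriorDraws(
        block=design.block,
        territory_ids=list(design.territory_ids),
        first_year=design.first_year,
        phi0=stack(0),
        beta=stack(1),
        mu_trans=stack(2),
        sigma_trans=stack(3),
        alpha=stack(4),
        mu_det=stack(5),
        sigma_det=stack(6),
        z=stack(7),
        acceptance=stack(8),
        config=config,
        priors=priors,
    )
    if config.n_chains >= 2 and draws.n_draws_per_chain >= 10:
        table = rhat_table(draws)
        worst = table["rhat"].max()
        if worst > 1.1:
            bad = table.loc[table["rhat"].idxmax(), "parameter"]
            warnings.warn(
                f"Gelman-Rubin statistic {worst:.3f} > 1.1 for {bad}; "
                "chains may not have converged — inspect rhat_table()",
                ConvergenceWarning,
                stacklevel=2,
            )
    return draws


_NAME_RE = re.compile(r"^(\w+)\[([\d,\s]+)\]$")


def extract_parameter(draws: PosteriorDraws, name: str) -> np.ndarray:
    """Scalar parameter draws by name, shape (chains, draws).

    Names use 1-based state labels: ``phi0[m]``, ``mu_trans[m,n]``,
    ``sigma_trans[m,n]``, ``beta[t,m,n]`` (t a 0-based transition index),
    ``mu_det[m,n,k]``, ``sigma_det[m,n,k]`` with coefficient k ∈ {0,1,2}.
    """
    match = _NAME_RE.match(name.strip())
    if not match:
        raise KeyError(f"cannot parse parameter name {name!r}")
    base, idx_s = match.groups()
    idx = [int(x) for x in idx_s.replace(" ", "").split(",")]
    if base == "phi0" and len(idx) == 1:
        return draws.phi0[:, :, idx[0] - 1]
    if base in ("mu_trans", "sigma_trans") and len(idx) == 2:
        m, n = idx
        return getattr(draws, base)[:, :, m - 1, n - 2]
    if base == "beta" and len(idx) == 3:
        t, m, n = idx
        return draws.beta[:, :, t, m - 1, n - 2]
    if base in ("mu_det", "sigma_det") and len(idx) == 3:
        m, n, k = idx
        return getattr(draws, base)[:, :, m - 2, n - 2, k]
    raise KeyError(f"unknown parameter {name!r}")


def gelman_rubin(
    draws: PosteriorDraws | np.ndarray,
    parameter: str | None = None,
    split: bool = False,
) -> float:
    """Potential scale reduction factor (R-hat) for one scalar parameter.

    Computed on retained (post-burn-in, thinned) draws with the standard
    between/within-chain variance ratio:

        W = mean of within-chain variances, B/S = variance of chain means,
        R̂ = sqrt(((S−1)/S · W + B/S) / W).

    ``split=True`` halves each chain first (the split-chain variant).
    Accepts either a :class:`PosteriorDraws` plus a parameter name or a raw
    (chains, draws) array.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        chains = extract_parameter(draws, parameter)
    else:
        chains = np.asarray(draws, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    C, S = chains.shape
    if C < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if S < 2:
        raise ValueError("need at least 2 retained draws per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_S = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    var_hat = (S - 1) / S * W + B_over_S
    return float(np.sqrt(var_hat / W))


def default_monitor_names(draws: PosteriorDraws) -> list[str]:
    names = [f"phi0[{m}]" for m in (1, 2, 3, 4)]
    names += [f"mu_trans[{m},{n}]" for m in (1, 2, 3, 4) for n in (2, 3, 4)]
    names += [f"sigma_trans[{m},{n}]" for m in (1, 2, 3, 4) for n in (2, 3, 4)]
    names += [
        f"mu_det[{m},{n},{k}]"
        for m in (2, 3, 4)
        for n in range(2, m + 1)
        for k in (0, 1, 2)
    ]
    return names


def rhat_table(draws: PosteriorDraws, names: Iterable[str] | None = None) -> pd.DataFrame:
    """Gelman–Rubin statistics for the monitored hyper-level parameters."""
    names = list(names) if names is not None else default_monitor_names(draws)
    rows = [
        {"parameter": n, "rhat": gelman_rubin(draws, n)}
        for n in names
    ]
    return pd.DataFrame(rows)


def save_draws(draws: PosteriorDraws, outdir: str | Path) -> dict[str, Path]:
    """Persist hyper-level draws and imputed states as CSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hyperparams": outdir / f"posterior_{draws.block}_hyperparams.csv",
        "latent": outdir / f"posterior_{draws.block}_latent_states.csv",
    }
    draws.hyperparam_frame().to_csv(paths["hyperparams"], index=False)
    draws.latent_state_frame().to_csv(paths["latent"], index=False)
    return paths


def save_npz(draws: PosteriorDraws, path: str | Path) -> Path:
    """Persist the full draw arrays (for downstream summarize/ppc commands)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        block=np.array(draws.block),
        territory_ids=np.array(draws.territory_ids),
        first_year=np.array(draws.first_year),
        phi0=draws.phi0,
        beta=draws.beta,
        mu_trans=draws.mu_trans,
        sigma_trans=draws.sigma_trans,
        alpha=draws.alpha,
        mu_det=draws.mu_det,
        sigma_det=draws.sigma_det,
        z=draws.z,
        acceptance=draws.acceptance,
        config=np.array(
            [
                draws.config.n_chains,
                draws.config.n_iter,
                draws.config.n_burnin,
                draws.config.thin,
                draws.config.seed,
            ]
        ),
    )
    return path


def load_npz(path: str | Path) -> PosteriorDraws:
    """Load draws persisted by :func:`save_npz`."""
    with np.load(path, allow_pickle=False) as f:
        cfg = f["config"]
        return PosteriorDraws(
            block=str(f["block"]),
            territory_ids=[str(t) for t in f["territory_ids"]],
            first_year=int(f["first_year"]),
            phi0=f["phi0"],
            beta=f["beta"],
            mu_trans=f["mu_trans"],
            sigma_trans=f["sigma_trans"],
            alpha=f["alpha"],
            mu_det=f["mu_det"],
            sigma_det=f["sigma_det"],
            z=f["z"],
            acceptance=f["acceptance"],
            config=McmcConfig(
                n_chains=int(cfg[0]),
                n_iter=int(cfg[1]),
                n_burnin=int(cfg[2]),
                thin=int(cfg[3]),
                seed=int(cfg[4]),
            ),
        )
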