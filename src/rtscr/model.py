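"""Bayesian inference for random-thinning spatial capture-recapture.

The model: activity centers s_i uniform over the state space S; membership
indicators z_i ~ Bernoulli(ψ) embed the unknown population size N = Σz in a
fixed superpopulation of size M (data augmentation); encounters are Poisson,

    y_full[i,j] | z_i ~ Poisson(λ0 · exp(−d_ij²/2σ²) · E_j · z_i),

with E_j the per-trap effort (active occasions); each encounter keeps its
individual identity independently with probability θ, so

    y_id[i,j] | y_full[i,j] ~ Binomial(y_full[i,j], θ),

and unidentified encounters are observed only through the trap sums
n_noID[j] = Σ_i (y_full − y_id)[i,j]. Standard SCR is the special case
θ = 1 with no unidentified counts.

:func:`fit_rtscr` samples the posterior by Metropolis-within-Gibbs with an
exact multinomial Gibbs step for the latent allocation of unidentified
counts (see :mod:`rtscr._mcmc`). Densities are reported per 100 km².
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _mcmc
from .data_model import CaptureData, Dataset, StateSpace, TrapArray

__all__ = [
    "Priors",
    "MCMCConfig",
    "LatentState",
    "PosteriorSamples",
    "encounter_rate",
    "log_complete_likelihood",
    "update_allocation",
    "fit_rtscr",
    "fit_scr",
    "load_posterior",
]


@dataclass
class Priors:
    """Vague priors for the rt-SCR parameters.

    ``lambda0`` and ``sigma`` are Uniform(lo, hi) tuples; ``theta`` and
    ``psi`` are Beta(a, b) tuples. The σ upper bound defaults to the
    state-space buffer width at fit time when left at ``None``.
    """

    lambda0: tuple = (0.0, 5.0)
    sigma: tuple | None = None
    theta: tuple = (1.0, 1.0)
    psi: tuple = (1.0, 1.0)

    def resolved(self, state_space: StateSpace) -> "Priors":
        sig = self.sigma
        if sig is None:
            xmin, ymin, xmax, ymax = state_space.bounds
            upper = state_space.buffer_width
            if upper <= 0:
                upper = 0.5 * max(xmax - xmin, ymax - ymin)
            sig = (0.0, float(upper))
        if sig[1] <= sig[0]:
            raise ValueError("sigma prior upper bound must exceed lower bound")
        if self.lambda0[1] <= self.lambda0[0] or self.lambda0[0] < 0:
            raise ValueError("invalid lambda0 prior support")
        if min(self.theta) <= 0 or min(self.psi) <= 0:
            raise ValueError("Beta prior parameters must be positive")
        return Priors(lambda0=self.lambda0, sigma=sig, theta=self.theta, psi=self.psi)


@dataclass
class MCMCConfig:
    """Sampler configuration.

    ``M`` is the data-augmentation size; ``None`` means 4× the number of
    identified individuals, with a floor of 50.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 5_000
    thin: int = 10
    M: int | None = None
    seed: int = 0
    adapt: bool = True
    retain_latent: bool = True

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class LatentState:
    """One complete-data state of the model (single chain, collapsed J)."""

    lambda0: float
    sigma: float
    theta: float
    psi: float
    z: np.ndarray          # (M,)
    s: np.ndarray          # (M, 2)
    y_full: np.ndarray     # (M, J)


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from every chain.

    ``params`` maps parameter name → (n_chains, n_draws) array for
    lambda0, sigma, theta, psi, N and D (per 100 km²). ``s`` and ``z``
    are the retained latent traces used for activity-center surfaces and
    posterior-predictive checks.
    """

    params: dict
    s: np.ndarray | None
    z: np.ndarray | None
    area_km2: float
    M: int
    config: MCMCConfig
    priors: Priors
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one 1-D draw vector."""
        return self.params[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame({k: v[c] for k, v in self.params.items()})
            df.insert(0, "chain", c)
            df.insert(1, "iteration", np.arange(self.n_draws))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_inference_data(self):
        """Convert to an :class:`arviz.InferenceData` for downstream use."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.params.items()})

    def save(self, directory: str | Path) -> None:
        """One CSV per chain plus a run-metadata JSON."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            df = pd.DataFrame(
                {
                    "iteration": np.arange(self.n_draws),
                    "lambda0": self.params["lambda0"][c],
                    "sigma_m": self.params["sigma"][c],
                    "theta": self.params["theta"][c],
                    "psi": self.params["psi"][c],
                    "N": self.params["N"][c],
                    "D_per100km2": self.params["D"][c],
                }
            )
            df.to_csv(d / f"chain_{c}.csv", index=False)
        meta = {
            "area_km2": self.area_km2,
            "M": self.M,
            "seed": self.config.seed,
            "n_chains": self.config.n_chains,
            "n_iter": self.config.n_iter,
            "n_burnin": self.config.n_burnin,
            "thin": self.config.thin,
            "priors": {
                "lambda0": list(self.priors.lambda0),
                "sigma": list(self.priors.sigma) if self.priors.sigma else None,
                "theta": list(self.priors.theta),
                "psi": list(self.priors.psi),
            },
            "meta": self.meta,
        }
        (d / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
        if self.s is not None:
            np.savez_compressed(d / "latent_traces.npz", s=self.s, z=self.z)


def load_posterior(directory: str | Path) -> PosteriorSamples:
    """Reload a posterior written by :meth:`PosteriorSamples.save`."""
    d = Path(directory)
    meta = json.loads((d / "run_meta.json").read_text())
    chains = sorted(d.glob("chain_*.csv"), key=lambda p: int(p.stem.split("_")[1]))
    if not chains:
        raise FileNotFoundError(f"no chain CSVs under {d}")
    cols = {"lambda0": "lambda0", "sigma": "sigma_m", "theta": "theta",
            "psi": "psi", "N": "N", "D": "D_per100km2"}
    per_chain = [pd.read_csv(p) for p in chains]
    params = {
        k: np.stack([df[col].to_numpy() for df in per_chain]) for k, col in cols.items()
    }
    s = z = None
    if (d / "latent_traces.npz").exists():
        with np.load(d / "latent_traces.npz") as npz:
            s, z = npz["s"], npz["z"]
    pri = meta["priors"]
    priors = Priors(
        lambda0=tuple(pri["lambda0"]),
        sigma=tuple(pri["sigma"]) if pri["sigma"] else None,
        theta=tuple(pri["theta"]),
        psi=tuple(pri["psi"]),
    )
    config = MCMCConfig(
        n_chains=meta["n_chains"], n_iter=meta["n_iter"], n_burnin=meta["n_burnin"],
        thin=meta["thin"], M=meta["M"], seed=meta["seed"],
    )
    return PosteriorSamples(
        params=params, s=s, z=z, area_km2=meta["area_km2"], M=meta["M"],
        config=config, priors=priors, meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def encounter_rate(d, lambda0: float, sigma: float):
    """Half-normal encounter rate λ(d) = λ0·exp(−d²/2σ²).

    ``d`` may be a scalar or an array of AC-trap distances (meters);
    λ0 is the rate at distance zero, σ the spatial scale.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if lambda0 <= 0:
        raise ValueError("lambda0 must be > 0")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    return lambda0 * np.exp(-(d**2) / (2.0 * sigma**2))


def _log_poisson(y, mu):
    # Poisson log-pmf with the 0·log0 convention handled
    out = np.zeros_like(mu, dtype=float)
    pos = mu > 0
    yp = y[pos]
    out[pos] = yp * np.log(mu[pos]) - mu[pos] - gammaln(yp + 1)
    zero_rate = ~pos
    out[zero_rate] = np.where(y[zero_rate] > 0, -np.inf, 0.0)
    return out


def log_complete_likelihood(
    state: LatentState,
    data: CaptureData,
    traps: TrapArray,
    state_space: StateSpace,
    priors: Priors | None = None,
) -> float:
    """Complete-data log posterior density (up to the uniform-s constant).

    Sums effort-masked Poisson log-mass for ``y_full``, Binomial log-mass
    for ``y_id | y_full``, Bernoulli(ψ) for z, and the log prior densities.
    States violating any invariant (y_full < y_id, constraint mismatch,
    AC outside the state space, z=0 with detections) return ``-inf`` so MH
    proposals to them are rejected rather than raising.
    """
    priors = (priors or Priors()).resolved(state_space)
    M, J = state.y_full.shape
    y_id3 = data.y_id
    y_id = np.zeros((M, J), dtype=np.int64)
    y_id[: y_id3.shape[0]] = y_id3.sum(axis=2)
    n_noid_j = data.n_noid.sum(axis=1)
    effort = traps.effort

    lam0, sig, th, psi = state.lambda0, state.sigma, state.theta, state.psi
    if not (priors.lambda0[0] < lam0 < priors.lambda0[1]):
        return -np.inf
    if not (priors.sigma[0] < sig < priors.sigma[1]):
        return -np.inf
    if not (0.0 <= th <= 1.0 and 0.0 < psi < 1.0):
        return -np.inf
    z = np.asarray(state.z)
    yf = np.asarray(state.y_full)
    if (yf < y_id).any() or (yf < 0).any():
        return -np.inf
    if (yf.sum(axis=0) - y_id.sum(axis=0) != n_noid_j).any():
        return -np.inf
    if ((z == 0) & (yf.sum(axis=1) > 0)).any():
        return -np.inf
    if not state_space.contains(state.s[:, 0], state.s[:, 1]).all():
        return -np.inf

    d2 = ((state.s[:, None, :] - traps.xy[None, :, :]) ** 2).sum(-1)
    mu = lam0 * np.exp(-d2 / (2 * sig**2)) * effort[None, :] * z[:, None]
    ll = _log_poisson(yf, mu).sum()
    # Binomial(y_id; y_full, theta)
    if th in (0.0, 1.0):
        y_noid = yf - y_id
        if th == 1.0 and y_noid.sum() > 0:
            return -np.inf
        if th == 0.0 and y_id.sum() > 0:
            return -np.inf
    else:
        ll += (
            gammaln(yf + 1)
            - gammaln(y_id + 1)
            - gammaln(yf - y_id + 1)
            + y_id * np.log(th)
            + (yf - y_id) * np.log1p(-th)
        ).sum()
    ll += (z * np.log(psi) + (1 - z) * np.log1p(-psi)).sum()
    # log priors: uniforms are flat on support; Beta terms
    ta, tb = priors.theta
    pa, pb = priors.psi
    if 0.0 < th < 1.0:
        ll += (ta - 1) * np.log(th) + (tb - 1) * np.log1p(-th)
    pa_, pb_ = pa, pb
    ll += (pa_ - 1) * np.log(psi) + (pb_ - 1) * np.log1p(-psi)
    return float(ll)


def update_allocation(
    state: LatentState,
    data: CaptureData,
    traps: TrapArray,
    rng: np.random.Generator,
    method: str = "gibbs",
    n_mh_moves: int | None = None,
) -> LatentState:
    """Resample the latent allocation of unidentified counts.

    ``method="gibbs"`` draws each trap's allocation from the exact
    multinomial full conditional (weights ∝ z_i·λ_ij); this is what the
    fitter uses. ``method="mh"`` instead performs single-count
    Metropolis-Hastings moves between individuals, kept for cross-checking
    the Gibbs step. Either way the constraint Σ_i y_noID = n_noID holds on
    exit; a trap whose weights all vanish keeps its current allocation.
    """
    M, J = state.y_full.shape
    y_id = np.zeros((M, J), dtype=np.int64)
    y_id[: data.y_id.shape[0]] = data.y_id.sum(axis=2)
    n_noid_j = data.n_noid.sum(axis=1)
    d2 = ((state.s[:, None, :] - traps.xy[None, :, :]) ** 2).sum(-1)
    lam = state.lambda0 * np.exp(-d2 / (2 * state.sigma**2)) * traps.effort[None, :]
    w = state.z[:, None] * lam
    y_extra = state.y_full - y_id

    if method == "gibbs":
        y_extra = np.zeros((M, J), dtype=np.int64)
        for j in np.nonzero(n_noid_j)[0]:
            wj = w[:, j]
            tot = wj.sum()
            if tot <= 0:
                y_extra[:, j] = state.y_full[:, j] - y_id[:, j]
                continue
            y_extra[:, j] = rng.multinomial(int(n_noid_j[j]), wj / tot)
    elif method == "mh":
        moves = n_mh_moves if n_mh_moves is not None else max(1, int(n_noid_j.sum()))
        traps_with = np.nonzero(n_noid_j)[0]
        for _ in range(moves):
            j = traps_with[rng.integers(len(traps_with))]
            holders = np.nonzero(y_extra[:, j] > 0)[0]
            active = np.nonzero(state.z)[0]
            if holders.size == 0 or active.size == 0:
                continue
            i_from = holders[rng.integers(holders.size)]
            i_to = active[rng.integers(active.size)]
            if i_from == i_to:
                continue
            x_from = y_extra[i_from, j]
            x_to = y_extra[i_to, j]
            # multinomial-kernel target ratio for moving one count i_from -> i_to,
            # with proposal asymmetry from the changing holder set
            if w[i_to, j] <= 0:
                continue
            log_t = np.log(w[i_to, j]) - np.log(w[i_from, j]) + np.log(x_from) - np.log(
                x_to + 1.0
            )
            n_holders = holders.size
            n_holders_new = n_holders - (1 if x_from == 1 else 0) + (
                1 if x_to == 0 else 0
            )
            log_q = np.log(n_holders) - np.log(n_holders_new)
            if np.log(rng.random()) < log_t + log_q:
                y_extra[i_from, j] -= 1
                y_extra[i_to, j] += 1
    else:
        raise ValueError("method must be 'gibbs' or 'mh'")

    new = LatentState(
        lambda0=state.lambda0,
        sigma=state.sigma,
        theta=state.theta,
        psi=state.psi,
        z=state.z.copy(),
        s=state.s.copy(),
        y_full=y_id + y_extra,
    )
    assert (new.y_full.sum(axis=0) - y_id.sum(axis=0) == n_noid_j).all()
    return new


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _prepare(data: Dataset, priors: Priors | None, config: MCMCConfig | None,
             drop_noid: bool):
    cfg = config or MCMCConfig()
    pri = (priors or Priors()).resolved(data.state_space)
    cap = data.captures
    n_obs = cap.n_individuals
    M = cfg.M if cfg.M is not None else max(50, 4 * n_obs)
    if M < n_obs:
        raise ValueError("augmentation size M must be >= identified individuals")
    J = data.traps.n_traps
    n_id = np.zeros((M, J), dtype=np.int64)
    if n_obs:
        n_id[:n_obs] = cap.y_id.sum(axis=2)
    else:
        warnings.warn("no identified individuals; fitting on unidentified counts only",
                      stacklevel=3)
    n_noid_j = np.zeros(J, dtype=np.int64) if drop_noid else cap.n_noid.sum(axis=1)
    cfg = MCMCConfig(**{**cfg.__dict__, "M": M})
    return cfg, pri, n_id, n_noid_j


def fit_rtscr(
    data: Dataset,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    sites: np.ndarray | None = None,
    init: dict | None = None,
    update_params: bool = True,
) -> PosteriorSamples:
    """Fit the random-thinning SCR model by Metropolis-within-Gibbs.

    Runs ``config.n_chains`` chains jointly (vectorized), discards
    ``n_burnin`` iterations, thins by ``thin``, and returns draws of
    (λ0, σ, θ, ψ, N = Σz, D = 100·N/area). Proposal scales adapt toward a
    25-45% acceptance rate during burn-in only. Non-convergence is not
    silenced: compute R̂ with :func:`rtscr.summaries.gelman_rubin`.
    """
    return _fit(data, priors, config, model="rtscr", sites=sites, init=init,
                update_params=update_params)


def fit_scr(
    data: Dataset,
    priors: Priors | None = None,
    config: MCMCConfig | None = None,
    sites: np.ndarray | None = None,
    init: dict | None = None,
    update_params: bool = True,
) -> PosteriorSamples:
    """Standard SCR fit: θ fixed at 1, unidentified counts ignored."""
    return _fit(data, priors, config, model="scr", sites=sites, init=init,
                update_params=update_params)


def _fit(data, priors, config, model, sites, init, update_params):
    cfg, pri, n_id, n_noid_j = _prepare(data, priors, config, drop_noid=model == "scr")
    out, s_draws, z_draws, meta = _mcmc.run_chains(
        n_id=n_id,
        n_noid_j=n_noid_j,
        effort=data.traps.effort,
        trap_xy=data.traps.xy,
        space=data.state_space,
        priors=pri,
        config=cfg,
        model=model,
        sites=sites,
        init=init,
        update_params=update_params,
    )
    area = data.state_space.area_km2
    out["D"] = 100.0 * out["N"] / area
    ppost = cfg.retain_latent
    samples = PosteriorSamples(
        params=out,
        s=s_draws if ppost else None,
        z=z_draws if ppost else None,
        area_km2=area,
        M=cfg.M,
        config=cfg,
        priors=pri,
        meta=meta,
    )
    if meta.get("alloc_fallbacks"):
        warnings.warn(
            f"{meta['alloc_fallbacks']} allocation events used the uniform fallback",
            stacklevel=3,
        )
    return samples
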