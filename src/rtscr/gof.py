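"""Posterior-predictive goodness-of-fit checks.

Three discrepancy statistics summarize a capture dataset:

* T1 — total detections (identified + unidentified),
* T2 — number of individuals with at least one identified detection,
* T3 — number of camera traps visited (any detection).

For each retained posterior draw, a replicate dataset is simulated from that
draw's (λ0, σ, θ, z, s) under the observed effort, the statistics are
recomputed, and the Bayesian p-value is Pr(T_rep ≥ T_obs) (ties counted in
favor of the model). Values near 0 or 1 indicate misfit. T2 is computed on
the identified replicate counts only — the observable quantity — while T1
and T3 use all detections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CaptureData, Dataset
from .model import PosteriorSamples

__all__ = ["GoFResult", "gof_statistics", "posterior_predictive_gof"]

STAT_NAMES = ("total_detections", "detected_individuals", "visited_traps")


@dataclass
class GoFResult:
    """Observed statistics, per-draw replicated statistics, Bayesian p-values."""

    observed: dict
    replicated: pd.DataFrame
    bayes_p: dict
    n_rep: int
    seed: int

    def save(self, path: str | Path, per_draw: bool = False) -> None:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(
            json.dumps(
                {
                    "observed": self.observed,
                    "bayes_p": self.bayes_p,
                    "n_rep": self.n_rep,
                    "seed": self.seed,
                },
                indent=2,
            )
        )
        if per_draw:
            self.replicated.to_csv(p.with_suffix(".replicates.csv"), index=False)

    def plot(self, path: str | Path) -> None:
        """Histogram panel of replicated statistics with observed lines."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, name in zip(axes, STAT_NAMES):
            ax.hist(self.replicated[name], bins=30, color="steelblue", alpha=0.8)
            ax.axvline(self.observed[name], color="red", lw=2)
            ax.set_title(f"{name}\nBayesian p = {self.bayes_p[name]:.2f}")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def gof_statistics(data: CaptureData) -> tuple[int, int, int]:
    """(T1, T2, T3): total detections, detected individuals, visited traps."""
    t1 = int(data.y_id.sum() + data.n_noid.sum())
    t2 = int((data.y_id.sum(axis=(1, 2)) > 0).sum())
    visited = (data.y_id.sum(axis=(0, 2)) + data.n_noid.sum(axis=1)) > 0
    t3 = int(visited.sum())
    return t1, t2, t3


def posterior_predictive_gof(
    samples: PosteriorSamples,
    data: Dataset,
    n_rep: int = 1000,
    seed: int = 0,
) -> GoFResult:
    """Posterior-predictive check of the three discrepancy statistics.

    Draws are taken evenly across the retained (chain-stacked) posterior;
    ``n_rep`` larger than the retained draw count uses all draws with a
    warning. Requires latent (z, s) traces (``retain_latent=True`` at fit
    time).
    """
    if samples.s is None or samples.z is None:
        raise ValueError("samples lack latent (z, s) traces; refit with retain_latent")
    rng = np.random.default_rng(seed)
    C, n_draws, M, _ = samples.s.shape
    total = C * n_draws
    if n_rep > total:
        warnings.warn(f"n_rep={n_rep} exceeds retained draws ({total}); using all",
                      stacklevel=2)
        n_rep = total
    pick = np.linspace(0, total - 1, n_rep).astype(int)

    s_all = samples.s.reshape(total, M, 2)
    z_all = samples.z.reshape(total, M)
    l0 = samples.stacked("lambda0")
    sg = samples.stacked("sigma")
    th = samples.stacked("theta")

    trap_xy = data.traps.xy
    effort = data.traps.effort
    obs = dict(zip(STAT_NAMES, gof_statistics(data.captures)))

    rows = np.empty((n_rep, 3), dtype=np.int64)
    for r, t in enumerate(pick):
        d2 = ((s_all[t, :, None, :].astype(float) - trap_xy[None, :, :]) ** 2).sum(-1)
        mu = l0[t] * np.exp(-d2 / (2 * sg[t] ** 2)) * effort[None, :]
        mu *= z_all[t][:, None]
        y_full = rng.poisson(mu)
        y_id = rng.binomial(y_full, th[t])
        rows[r, 0] = y_full.sum()
        rows[r, 1] = (y_id.sum(axis=1) > 0).sum()
        rows[r, 2] = (y_full.sum(axis=0) > 0).sum()

    rep = pd.DataFrame(rows, columns=list(STAT_NAMES))
    bayes_p = {
        name: float((rep[name].to_numpy() >= obs[name]).mean()) for name in STAT_NAMES
    }
    return GoFResult(observed=obs, replicated=rep, bayes_p=bayes_p,
                     n_rep=n_rep, seed=seed)
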