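"""Vectorized Metropolis-within-Gibbs engine for the rt-SCR model.

All chains run simultaneously as the leading axis of every state array
(shape (C, M, J) for counts/rates), so one numpy program advances every
chain per sweep. A sweep updates, in order:

1. allocation of unidentified trap counts to individuals — exact multinomial
   Gibbs full conditional (weights ∝ z_i·λ_ij; Poisson thinning makes the
   allocation conditionally multinomial given the trap sums);
2. membership z — Gibbs for individuals with no current detections, forced
   to 1 otherwise;
3. ψ — conjugate Beta Gibbs given Σz;
4. activity centers s — random-walk MH for active individuals, exact
   uniform redraw (prior = full conditional) for inactive ones; in
   discrete-site mode, exact categorical Gibbs over the candidate sites;
5. λ0 and σ — log-scale random-walk MH with adaptation during burn-in;
6. θ — conjugate Beta Gibbs (its full conditional depends only on the fixed
   identified/unidentified totals).

Occasions are collapsed to per-trap effort E_j (sufficient under a
time-constant rate); the trap-cell constraint Σ_i y_noID = n_noID is
asserted at every retained draw.
"""

from __future__ import annotations


import numpy as np

__all__ = ["run_chains"]


def _integrated_init(n_id, effort, trap_xy, space, theta_hat, priors):
    """Coarse grid search of the identified-data integrated likelihood.

    Marginalizes each detected individual's activity center over a lattice
    of candidate locations and scans a log-spaced (λ0, σ) grid; returns the
    maximizing pair. Crude but reliable as a chain initializer.
    """
    obs = n_id[n_id.sum(axis=1) > 0]
    xmin, ymin, xmax, ymax = space.bounds
    extent = max(xmax - xmin, ymax - ymin)
    if obs.shape[0] == 0:
        return 0.1 * min(1.0, priors.lambda0[1]), extent / 8.0
    gx = np.linspace(xmin, xmax, 16)
    gy = np.linspace(ymin, ymax, 16)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    sites = np.column_stack([X.ravel(), Y.ravel()])
    inside = space.contains(sites[:, 0], sites[:, 1])
    sites = sites[inside]
    d2 = ((sites[:, None, :] - trap_xy[None, :, :]) ** 2).sum(-1)  # (G, J)

    counts = obs.astype(float)
    row_tot = counts.sum(axis=1)
    l0_base = row_tot.sum() / (obs.shape[0] * max(effort.mean(), 1.0))
    l0_grid = np.geomspace(l0_base / 10, min(l0_base * 10, priors.lambda0[1]), 10)
    sig_grid = np.geomspace(extent / 60, extent / 3, 12)
    sig_grid = sig_grid[(sig_grid > priors.sigma[0]) & (sig_grid < priors.sigma[1])]
    if sig_grid.size == 0:
        sig_grid = np.array([0.5 * (priors.sigma[0] + priors.sigma[1])])

    best = (-np.inf, l0_grid[0], sig_grid[0])
    theta_hat = max(theta_hat, 1e-6)
    for sig in sig_grid:
        logK = -d2 / (2 * sig**2)                       # (G, J)
        cross = counts @ logK.T                          # (n_obs, G)
        Ksum = (np.exp(logK) * effort[None, :]).sum(1)   # (G,)
        for l0 in l0_grid:
            rate = theta_hat * l0
            ll_ig = cross + row_tot[:, None] * np.log(rate) - rate * Ksum[None, :]
            m = ll_ig.max(axis=1, keepdims=True)
            li = m[:, 0] + np.log(np.exp(ll_ig - m).mean(axis=1))
            tot = li.sum()
            if tot > best[0]:
                best = (tot, l0, sig)
    return best[1], best[2]


def run_chains(
    n_id,
    n_noid_j,
    effort,
    trap_xy,
    space,
    priors,
    config,
    model="rtscr",
    sites=None,
    init=None,
    update_params=True,
):
    """Run ``config.n_chains`` chains and return draw arrays + metadata.

    Parameters
    ----------
    n_id : (M, J) int array
        Identified counts per augmented individual (observed rows first,
        zero-padded to M).
    n_noid_j : (J,) int array
        Unidentified trap totals (ignored when ``model='scr'``).
    sites : (G, 2) array, optional
        Discrete candidate activity-center sites; when given, the s-update
        is an exact categorical Gibbs step over these sites.
    init : dict, optional
        Fixed initial values for any of lambda0/sigma/theta/psi; with
        ``update_params=False`` they are held constant (used by the
        enumeration cross-check).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    C, M = cfg.n_chains, cfg.M
    J = trap_xy.shape[0]
    n_id = np.asarray(n_id, dtype=np.int64)
    if n_id.shape != (M, J):
        raise ValueError("n_id must be (M, J)")
    effort = np.asarray(effort, dtype=float)
    scr = model == "scr"
    n_noid_j = np.zeros(J, dtype=np.int64) if scr else np.asarray(n_noid_j, np.int64)
    init = dict(init or {})

    n_obs = int((n_id.sum(axis=1) > 0).sum())
    A_id = float(n_id.sum())
    B_noid = float(n_noid_j.sum())
    ta, tb = priors.theta
    pa, pb = priors.psi

    # ---- parameter initialization -------------------------------------
    if scr:
        theta0 = 1.0
    else:
        theta0 = init.get("theta", (ta + A_id) / (ta + tb + A_id + B_noid))
    if "lambda0" in init and "sigma" in init:
        l0_init, sig_init = init["lambda0"], init["sigma"]
    else:
        l0_init, sig_init = _integrated_init(n_id, effort, trap_xy, space, theta0, priors)
        l0_init = init.get("lambda0", l0_init)
        sig_init = init.get("sigma", sig_init)
    psi0 = init.get("psi", (n_obs + 1.0) / (M + 2.0))

    jitter = 0.25 if update_params else 0.0
    lam0 = np.clip(l0_init * np.exp(jitter * rng.standard_normal(C)),
                   priors.lambda0[0] + 1e-12, priors.lambda0[1] - 1e-12)
    sig = np.clip(sig_init * np.exp(jitter * rng.standard_normal(C)),
                  priors.sigma[0] + 1e-9, priors.sigma[1] * (1 - 1e-12))
    theta = np.full(C, theta0)
    psi = np.clip(np.full(C, psi0), 1e-6, 1 - 1e-6)

    # pre-drawn theta Gibbs draws (full conditional is data-constant)
    if not scr and update_params:
        theta_all = rng.beta(ta + A_id, tb + B_noid, size=(cfg.n_iter, C))
    else:
        theta_all = None

    # ---- latent state initialization ----------------------------------
    z = np.zeros((C, M), dtype=np.int8)
    forced = n_id.sum(axis=1) > 0
    z[:, forced] = 1
    free0 = ~forced
    z[:, free0] = (rng.random((C, int(free0.sum()))) < psi0).astype(np.int8)
    if not scr and B_noid > 0 and (z.sum(axis=1) == 0).any():
        z[z.sum(axis=1) == 0, 0] = 1   # someone must hold the unidentified counts

    s = np.empty((C, M, 2))
    if n_obs:
        w = n_id[forced].astype(float)
        cent = (w @ trap_xy) / w.sum(axis=1, keepdims=True)
        s[:, forced] = cent[None, :, :] + 100.0 * rng.standard_normal((C, n_obs, 2))
        bad = ~space.contains(s[:, forced, 0].ravel(), s[:, forced, 1].ravel())
        if bad.any():
            flat = s[:, forced].reshape(-1, 2)
            flat[bad] = np.repeat(cent[None, :, :], C, 0).reshape(-1, 2)[bad]
            s[:, forced] = flat.reshape(C, n_obs, 2)
    n_aug = M - n_obs
    if n_aug:
        s[:, ~forced] = space.sample_uniform(C * n_aug, rng).reshape(C, n_aug, 2)

    D2 = ((s[:, :, None, :] - trap_xy[None, None, :, :]) ** 2).sum(-1)  # (C,M,J)
    Knl = np.exp(-D2 / (2 * sig[:, None, None] ** 2))

    # allocation bookkeeping
    j_ev = np.repeat(np.arange(J), n_noid_j)
    n_ev = j_ev.size
    cc_flat = np.repeat(np.arange(C), n_ev)
    jj_flat = np.tile(j_ev, C)
    y_extra = np.zeros((C, M, J), dtype=np.int64)
    if n_ev:
        _allocate(y_extra, z, Knl, effort, j_ev, cc_flat, jj_flat, rng)
        z[:] = np.where((n_id[None] + y_extra).sum(-1) > 0, 1, z)
    y_full = n_id[None] + y_extra

    # ---- adaptation state ---------------------------------------------
    step_l0 = np.full(C, 0.3)
    step_sig = np.full(C, 0.15)
    step_s = np.full(C, max(sig_init / 2, 1e-3))
    acc = {k: np.zeros(C) for k in ("l0", "sig")}
    acc_s = np.zeros(C)
    prop_s = np.zeros(C)
    n_win = {k: 0 for k in ("l0", "sig")}

    n_draws = (cfg.n_iter - cfg.n_burnin) // cfg.thin
    out = {k: np.empty((C, n_draws)) for k in ("lambda0", "sigma", "theta", "psi", "N")}
    s_draws = np.empty((C, n_draws, M, 2), dtype=np.float32)
    z_draws = np.empty((C, n_draws, M), dtype=np.uint8)
    alloc_fallbacks = 0
    constraint_checks = 0
    d = 0

    if sites is not None:
        sites = np.asarray(sites, dtype=float)
        d2_sites = ((sites[:, None, :] - trap_xy[None, :, :]) ** 2).sum(-1)  # (G,J)

    xmin, ymin, xmax, ymax = space.bounds

    effort_b = effort[None, None, :]
    KEs = (Knl * effort_b).sum(-1)          # (C,M) cached Σ_j K_ij E_j
    for it in range(cfg.n_iter):
        # -- 1. allocation Gibbs ---------------------------------------
        if n_ev:
            alloc_fallbacks += _allocate(
                y_extra, z, Knl, effort, j_ev, cc_flat, jj_flat, rng
            )
            y_full = n_id[None] + y_extra

        # -- 2. z Gibbs -------------------------------------------------
        row_tot = y_full.sum(-1)                       # (C,M)
        Rsum = lam0[:, None] * KEs
        with np.errstate(over="ignore"):
            p1 = psi[:, None] * np.exp(-Rsum)
        p1 = p1 / (p1 + (1 - psi[:, None]))
        free = row_tot == 0
        znew = (rng.random((C, M)) < p1).astype(np.int8)
        z = np.where(free, znew, 1).astype(np.int8)

        # -- 3. psi Gibbs ----------------------------------------------
        zsum = z.sum(axis=1)
        psi = rng.beta(pa + zsum, pb + M - zsum)

        # -- 4. s update ------------------------------------------------
        yf = y_full.astype(float)
        if sites is None:
            prop = s + step_s[:, None, None] * rng.standard_normal((C, M, 2))
            uni = space.sample_uniform(C * M, rng).reshape(C, M, 2)
            zb = z.astype(bool)
            prop = np.where(zb[:, :, None], prop, uni)
            inside = space.contains(prop[..., 0].ravel(), prop[..., 1].ravel())
            inside = inside.reshape(C, M)
            D2p = ((prop[:, :, None, :] - trap_xy[None, None, :, :]) ** 2).sum(-1)
            inv2s2 = 1.0 / (2 * sig[:, None, None] ** 2)
            Kp = np.exp(-D2p * inv2s2)
            KEp = (Kp * effort_b).sum(-1)
            yD2p = (yf * D2p).sum(-1)
            yD2 = (yf * D2).sum(-1)
            llp = -yD2p * inv2s2[:, :, 0] - lam0[:, None] * KEp
            llc = -yD2 * inv2s2[:, :, 0] - lam0[:, None] * KEs
            logr = np.where(zb, llp - llc, np.inf)
            accept = inside & (np.log(rng.random((C, M))) < logr)
            am = accept[:, :, None]
            s = np.where(am, prop, s)
            D2 = np.where(am, D2p, D2)
            Knl = np.where(am, Kp, Knl)
            KEs = np.where(accept, KEp, KEs)
            yD2 = np.where(accept, yD2p, yD2)
            acc_s += (accept & zb).sum(axis=1)
            prop_s += zb.sum(axis=1)
        else:
            inv2s2 = 1.0 / (2 * sig**2)                     # (C,)
            logKs = -d2_sites[None, :, :] * inv2s2[:, None, None]   # (C,G,J)
            Tsite = lam0[:, None] * (np.exp(logKs) * effort[None, None, :]).sum(-1)
            ll = np.einsum("cmj,cgj->cmg", yf, logKs) - Tsite[:, None, :]
            ll = ll * z[:, :, None]
            g = rng.gumbel(size=ll.shape)
            idx = (ll + g).argmax(axis=2)                    # (C,M)
            s = sites[idx]
            D2 = d2_sites[idx]
            Knl = np.exp(-D2 / (2 * sig[:, None, None] ** 2))
            KEs = (Knl * effort_b).sum(-1)
            yD2 = (yf * D2).sum(-1)

        # -- 5. lambda0, sigma MH --------------------------------------
        if update_params:
            zf = z.astype(float)
            S_y = (row_tot * zf).sum(axis=1)
            T_cur = (KEs * zf).sum(axis=1)

            l0p = lam0 * np.exp(step_l0 * rng.standard_normal(C))
            ok = (l0p > priors.lambda0[0]) & (l0p < priors.lambda0[1])
            logr = (
                S_y * (np.log(l0p) - np.log(lam0))
                - (l0p - lam0) * T_cur
                + np.log(l0p / lam0)
            )
            a = ok & (np.log(rng.random(C)) < logr)
            lam0 = np.where(a, l0p, lam0)
            acc["l0"] += a

            S_yd = (yD2 * zf).sum(axis=1)
            sigp = sig * np.exp(step_sig * rng.standard_normal(C))
            ok = (sigp > priors.sigma[0]) & (sigp < priors.sigma[1])
            Kp = np.exp(-D2 / (2 * sigp[:, None, None] ** 2))
            KEp = (Kp * effort_b).sum(-1)
            T_p = (KEp * zf).sum(axis=1)
            logr = (
                -S_yd / (2 * sigp**2)
                + S_yd / (2 * sig**2)
                - lam0 * (T_p - T_cur)
                + np.log(sigp / sig)
            )
            a = ok & (np.log(rng.random(C)) < logr)
            sig = np.where(a, sigp, sig)
            Knl = np.where(a[:, None, None], Kp, Knl)
            KEs = np.where(a[:, None], KEp, KEs)
            acc["sig"] += a
            n_win["l0"] += 1
            n_win["sig"] += 1

        # -- 6. theta ---------------------------------------------------
        if theta_all is not None:
            theta = theta_all[it]

        # -- adaptation (burn-in only) ---------------------------------
        if update_params and cfg.adapt and it < cfg.n_burnin and (it + 1) % 50 == 0:
            for key, step in (("l0", step_l0), ("sig", step_sig)):
                rate = acc[key] / n_win[key]
                step *= np.where(rate > 0.45, 1.25, np.where(rate < 0.25, 0.8, 1.0))
                acc[key][:] = 0
                n_win[key] = 0
            with np.errstate(invalid="ignore"):
                rate_s = np.where(prop_s > 0, acc_s / np.maximum(prop_s, 1), 0.35)
            step_s *= np.where(rate_s > 0.45, 1.25, np.where(rate_s < 0.25, 0.8, 1.0))
            step_s = np.clip(step_s, 1e-2, max(xmax - xmin, ymax - ymin))
            acc_s[:] = 0
            prop_s[:] = 0

        # -- record -----------------------------------------------------
        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and d < n_draws:
            if n_ev:
                viol = np.abs(y_extra.sum(axis=1) - n_noid_j[None, :]).max()
                if viol:
                    raise AssertionError(
                        f"allocation constraint violated at iteration {it}: "
                        f"max |Σ y_noID − n_noID| = {viol}"
                    )
                constraint_checks += 1
            out["lambda0"][:, d] = lam0
            out["sigma"][:, d] = sig
            out["theta"][:, d] = theta
            out["psi"][:, d] = psi
            out["N"][:, d] = z.sum(axis=1)
            s_draws[:, d] = s
            z_draws[:, d] = z
            d += 1

    meta = {
        "n_obs": n_obs,
        "init": {"lambda0": float(l0_init), "sigma": float(sig_init),
                 "theta": float(theta0), "psi": float(psi0)},
        "steps": {"lambda0": step_l0.tolist(), "sigma": step_sig.tolist(),
                  "s": step_s.tolist()},
        "alloc_fallbacks": int(alloc_fallbacks),
        "constraint_checks": int(constraint_checks),
        "model": model,
    }
    return out, s_draws, z_draws, meta


def _allocate(y_extra, z, Knl, effort, j_ev, cc_flat, jj_flat, rng):
    """Multinomial Gibbs reallocation of unidentified counts (in place).

    Each unidentified event at trap j is assigned to individual i with
    probability ∝ z_i·λ_ij. Returns the number of events that needed the
    uniform fallback (all weights underflowed to zero).
    """
    C, M, J = y_extra.shape
    n_ev = j_ev.size
    W = z[:, :, None] * Knl * effort[None, None, :]
    P = W[:, :, j_ev]                        # (C, M, n_ev)
    cum = np.cumsum(P, axis=1)
    tot = cum[:, -1, :]                      # (C, n_ev)
    fallbacks = 0
    bad = tot <= 0
    if bad.any():
        fallbacks = int(bad.sum())
        zc = np.cumsum(z.astype(float), axis=1)          # (C, M)
        cum = np.where(bad[:, None, :], zc[:, :, None], cum)
        tot = cum[:, -1, :]
        still = tot <= 0
        if still.any():                       # no active individual at all
            flat = np.broadcast_to(
                np.arange(1.0, M + 1)[None, :, None], cum.shape
            )
            cum = np.where(still[:, None, :], flat, cum)
            tot = cum[:, -1, :]
    u = rng.random((C, n_ev)) * tot
    idx = (cum < u[:, None, :]).sum(axis=1)
    np.clip(idx, 0, M - 1, out=idx)
    y_extra[:] = 0
    np.add.at(y_extra, (cc_flat, idx.ravel(), jj_flat), 1)
    return fallbacks
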