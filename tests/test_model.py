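"""Tests for likelihood primitives, latent updates, and the fitters."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import binom, poisson

from rtscr import (
    CaptureData,
    Dataset,
    LatentState,
    MCMCConfig,
    Priors,
    TrapArray,
    TruthParams,
    build_state_space,
    encounter_rate,
    fit_rtscr,
    fit_scr,
    load_posterior,
    log_complete_likelihood,
    simulate_dataset,
    update_allocation,
)


# ---------------------------------------------------------------------------
# encounter rate
# ---------------------------------------------------------------------------


def test_encounter_rate_values():
    # at d = sigma the rate is lambda0 * exp(-1/2)
    assert encounter_rate(3050.0, 0.047, 3050.0) == pytest.approx(
        0.047 * np.exp(-0.5)
    )
    assert encounter_rate(0.0, 0.047, 3050.0) == pytest.approx(0.047)
    d = np.array([0.0, 1000.0, 1e7])
    out = encounter_rate(d, 0.5, 1000.0)
    assert out.shape == (3,)
    assert out[0] == pytest.approx(0.5)
    assert out[1] == pytest.approx(0.5 * np.exp(-0.5))
    assert out[2] == pytest.approx(0.0, abs=1e-300)
    # monotone decreasing in distance
    dd = np.linspace(0, 5000, 50)
    assert (np.diff(encounter_rate(dd, 0.3, 1200.0)) < 0).all()


def test_encounter_rate_validation():
    with pytest.raises(ValueError):
        encounter_rate(100.0, 0.5, 0.0)
    with pytest.raises(ValueError):
        encounter_rate(100.0, -0.5, 1000.0)
    with pytest.raises(ValueError):
        encounter_rate(-1.0, 0.5, 1000.0)


# ---------------------------------------------------------------------------
# priors / config
# ---------------------------------------------------------------------------


def test_priors_sigma_defaults_to_buffer(small_traps):
    space = build_state_space(small_traps, 2000.0)
    pri = Priors().resolved(space)
    assert pri.sigma == (0.0, 2000.0)


def test_priors_sigma_defaults_to_half_extent_without_buffer(small_traps):
    space = build_state_space(small_traps, 0.0)
    pri = Priors().resolved(space)
    assert pri.sigma == (0.0, 1000.0)   # half of the 2 km bbox extent


def test_priors_validation(small_traps):
    space = build_state_space(small_traps, 2000.0)
    with pytest.raises(ValueError):
        Priors(sigma=(100.0, 50.0)).resolved(space)
    with pytest.raises(ValueError):
        Priors(lambda0=(1.0, 0.5)).resolved(space)
    with pytest.raises(ValueError):
        Priors(theta=(0.0, 1.0)).resolved(space)


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(n_iter=100, n_burnin=100)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)
    with pytest.raises(ValueError):
        MCMCConfig(n_chains=0)


# ---------------------------------------------------------------------------
# complete-data likelihood vs an independent scipy oracle
# ---------------------------------------------------------------------------


def _random_state(rng, data, traps, space, M):
    """A random latent state satisfying every model invariant."""
    J = traps.n_traps
    n_obs = data.y_id.shape[0]
    y_id = np.zeros((M, J), dtype=np.int64)
    y_id[:n_obs] = data.y_id.sum(axis=2)
    n_noid_j = data.n_noid.sum(axis=1)
    z = (rng.random(M) < 0.7).astype(np.int64)
    z[y_id.sum(axis=1) > 0] = 1
    y_extra = np.zeros((M, J), dtype=np.int64)
    active = np.nonzero(z)[0]
    for j in range(J):
        for _ in range(int(n_noid_j[j])):
            y_extra[rng.choice(active), j] += 1
    return LatentState(
        lambda0=float(rng.uniform(0.1, 1.0)),
        sigma=float(rng.uniform(500.0, 1800.0)),
        theta=float(rng.uniform(0.3, 0.95)),
        psi=float(rng.uniform(0.2, 0.8)),
        z=z,
        s=space.sample_uniform(M, rng),
        y_full=y_id + y_extra,
    )


def _oracle_loglik(state, data, traps, priors):
    """Independent complete-data log density via scipy distributions."""
    M, J = state.y_full.shape
    y_id = np.zeros((M, J), dtype=np.int64)
    y_id[: data.y_id.shape[0]] = data.y_id.sum(axis=2)
    d = np.sqrt(((state.s[:, None, :] - traps.xy[None, :, :]) ** 2).sum(-1))
    mu = (
        state.lambda0
        * np.exp(-(d**2) / (2 * state.sigma**2))
        * traps.effort[None, :]
        * state.z[:, None]
    )
    ll = poisson.logpmf(state.y_full, mu).sum()
    ll += binom.logpmf(y_id, state.y_full, state.theta).sum()
    ll += np.where(state.z == 1, np.log(state.psi), np.log1p(-state.psi)).sum()
    ll += beta_dist.logpdf(state.theta, *priors.theta)
    ll += beta_dist.logpdf(state.psi, *priors.psi)
    return float(ll)


def test_log_complete_likelihood_matches_oracle_differences(tiny_dataset):
    """Pairwise differences agree with scipy (additive constants cancel)."""
    traps = tiny_dataset.traps
    space = tiny_dataset.state_space
    data = tiny_dataset.captures
    priors = Priors(theta=(2.0, 1.5), psi=(1.0, 1.0)).resolved(space)
    rng = np.random.default_rng(42)
    states = [_random_state(rng, data, traps, space, M=6) for _ in range(6)]
    ours = [log_complete_likelihood(s, data, traps, space, priors) for s in states]
    oracle = [_oracle_loglik(s, data, traps, priors) for s in states]
    for i in range(1, len(states)):
        assert ours[i] - ours[0] == pytest.approx(oracle[i] - oracle[0], abs=1e-8)


def test_log_complete_likelihood_invariant_violations(tiny_dataset):
    traps = tiny_dataset.traps
    space = tiny_dataset.state_space
    data = tiny_dataset.captures
    rng = np.random.default_rng(1)
    good = _random_state(rng, data, traps, space, M=6)
    assert np.isfinite(log_complete_likelihood(good, data, traps, space))

    def clone(**over):
        kw = dict(
            lambda0=good.lambda0, sigma=good.sigma, theta=good.theta, psi=good.psi,
            z=good.z.copy(), s=good.s.copy(), y_full=good.y_full.copy(),
        )
        kw.update(over)
        return LatentState(**kw)

    # negative encounter count
    bad = clone()
    bad.y_full[0, 0] = -1
    assert log_complete_likelihood(bad, data, traps, space) == -np.inf
    # allocation constraint broken
    bad = clone()
    bad.y_full[-1, 0] += 1
    assert log_complete_likelihood(bad, data, traps, space) == -np.inf
    # z = 0 but counts present
    i_active = np.nonzero(good.y_full.sum(axis=1) > 0)[0][0]
    bad = clone()
    bad.z[i_active] = 0
    assert log_complete_likelihood(bad, data, traps, space) == -np.inf
    # activity center outside the state space
    bad = clone()
    bad.s[0] = [1e7, 1e7]
    assert log_complete_likelihood(bad, data, traps, space) == -np.inf
    # parameters outside prior support
    assert log_complete_likelihood(clone(sigma=-5.0), data, traps, space) == -np.inf
    assert log_complete_likelihood(clone(lambda0=99.0), data, traps, space) == -np.inf


# ---------------------------------------------------------------------------
# latent allocation updates
# ---------------------------------------------------------------------------


def _alloc_setup():
    """Two active individuals, one trap holding 3 unidentified counts."""
    traps = TrapArray(
        station_id=["t0"], xy=[[0.0, 0.0]], operation=np.ones((1, 4), dtype=np.int8)
    )
    space = build_state_space(traps, 3000.0)
    y_id = np.zeros((0, 1, 4), dtype=np.int64)
    n_noid = np.array([[1, 1, 1, 0]], dtype=np.int64)
    data = CaptureData(y_id=y_id, n_noid=n_noid, individual_ids=[])
    s = np.array([[500.0, 0.0], [1500.0, 0.0]])
    state = LatentState(
        lambda0=0.5, sigma=1000.0, theta=0.6, psi=0.5,
        z=np.ones(2, dtype=np.int64), s=s,
        y_full=np.array([[3], [0]], dtype=np.int64),
    )
    lam = 0.5 * np.exp(-np.array([500.0, 1500.0]) ** 2 / (2 * 1000.0**2))
    p0 = lam[0] / lam.sum()    # multinomial weight of individual 0
    return state, data, traps, space, p0


def test_gibbs_allocation_marginal_is_binomial():
    state, data, traps, _, p0 = _alloc_setup()
    rng = np.random.default_rng(0)
    n_draw = 4000
    counts = np.zeros(4)
    for _ in range(n_draw):
        new = update_allocation(state, data, traps, rng, method="gibbs")
        assert new.y_full.sum() == 3
        counts[new.y_full[0, 0]] += 1
    emp = counts / n_draw
    exact = binom.pmf(np.arange(4), 3, p0)
    assert 0.5 * np.abs(emp - exact).sum() < 0.03


def test_mh_allocation_agrees_with_gibbs():
    state, data, traps, _, p0 = _alloc_setup()
    rng = np.random.default_rng(1)
    counts = np.zeros(4)
    cur = state
    for it in range(4000):
        cur = update_allocation(cur, data, traps, rng, method="mh", n_mh_moves=10)
        assert cur.y_full.sum() == 3
        if it >= 200:
            counts[cur.y_full[0, 0]] += 1
    emp = counts / counts.sum()
    exact = binom.pmf(np.arange(4), 3, p0)
    assert 0.5 * np.abs(emp - exact).sum() < 0.05


def test_allocation_unknown_method(tiny_dataset):
    rng = np.random.default_rng(0)
    st = _random_state(rng, tiny_dataset.captures, tiny_dataset.traps,
                       tiny_dataset.state_space, M=6)
    with pytest.raises(ValueError):
        update_allocation(st, tiny_dataset.captures, tiny_dataset.traps, rng,
                          method="nope")


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------


def test_theta_posterior_matches_analytic_beta(quick_sim, quick_fit):
    """theta's full conditional is Beta(a + sum y_id, b + sum n_noid): exact."""
    cap = quick_sim.dataset.captures
    a = 1.0 + cap.y_id.sum()
    b = 1.0 + cap.n_noid.sum()
    th = quick_fit.stacked("theta")
    mean = a / (a + b)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    assert abs(th.mean() - mean) < 5 * sd / np.sqrt(th.size)
    assert th.std(ddof=1) == pytest.approx(sd, rel=0.15)


def test_fit_deterministic_under_seed(quick_sim):
    cfg = MCMCConfig(n_chains=2, n_iter=1200, n_burnin=400, thin=4, seed=3)
    a = fit_rtscr(quick_sim.dataset, config=cfg)
    b = fit_rtscr(quick_sim.dataset, config=cfg)
    c = fit_rtscr(quick_sim.dataset, config=MCMCConfig(**{**cfg.__dict__, "seed": 4}))
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    assert not np.array_equal(a.params["lambda0"], c.params["lambda0"])


def test_fit_scr_fixes_theta_and_ignores_unidentified(quick_sim):
    cfg = MCMCConfig(n_chains=2, n_iter=1200, n_burnin=400, thin=4, seed=7)
    with_noid = quick_sim.dataset
    scr_a = fit_scr(with_noid, config=cfg)
    assert (scr_a.stacked("theta") == 1.0).all()

    # zeroing the unidentified counts must not change the SCR posterior
    cap = with_noid.captures
    cap2 = CaptureData(
        y_id=cap.y_id,
        n_noid=np.zeros_like(cap.n_noid),
        individual_ids=cap.individual_ids,
    )
    without = Dataset(traps=with_noid.traps, captures=cap2,
                      state_space=with_noid.state_space)
    scr_b = fit_scr(without, config=cfg)
    for k in ("lambda0", "sigma", "N"):
        assert np.array_equal(scr_a.params[k], scr_b.params[k])


def test_fit_posterior_shapes_and_density(quick_fit):
    assert set(quick_fit.params) == {"lambda0", "sigma", "theta", "psi", "N", "D"}
    n_expected = (4000 - 1000) // 5
    assert quick_fit.params["N"].shape == (3, n_expected)
    assert np.allclose(
        quick_fit.params["D"],
        100.0 * quick_fit.params["N"] / quick_fit.area_km2,
    )
    # N draws stay within [identified individuals, M]
    assert quick_fit.params["N"].min() >= 0
    assert quick_fit.params["N"].max() <= quick_fit.M
    assert quick_fit.s.shape[2] == quick_fit.M


def test_augmentation_size_validation(quick_sim):
    n_obs = quick_sim.dataset.captures.n_individuals
    with pytest.raises(ValueError, match="augmentation"):
        fit_rtscr(quick_sim.dataset,
                  config=MCMCConfig(n_iter=200, n_burnin=50, M=n_obs - 1))


def test_fit_warns_without_identified_individuals(small_traps):
    space = build_state_space(small_traps, 2000.0)
    J, K = small_traps.n_traps, small_traps.n_occasions
    n_noid = np.zeros((J, K), dtype=np.int64)
    n_noid[0, 0] = 2
    cap = CaptureData(y_id=np.zeros((0, J, K), dtype=np.int64), n_noid=n_noid,
                      individual_ids=[])
    ds = Dataset(traps=small_traps, captures=cap, state_space=space)
    with pytest.warns(UserWarning, match="no identified"):
        fit_rtscr(ds, config=MCMCConfig(n_chains=2, n_iter=300, n_burnin=100,
                                        thin=2, M=20, seed=0))


def test_discrete_site_mode_restricts_support(tiny_dataset):
    g = np.linspace(-1000.0, 3000.0, 4)
    X, Y = np.meshgrid(g, g, indexing="ij")
    sites = np.column_stack([X.ravel(), Y.ravel()])
    cfg = MCMCConfig(n_chains=2, n_iter=400, n_burnin=100, thin=2, M=5, seed=2)
    out = fit_rtscr(tiny_dataset, config=cfg, sites=sites,
                    init=dict(lambda0=0.4, sigma=1000.0, theta=0.7),
                    update_params=False)
    # parameters held fixed; activity centers only ever on the site lattice
    assert (out.stacked("lambda0") == 0.4).all()
    assert (out.stacked("sigma") == 1000.0).all()
    # s traces are stored float32: compare with tolerance to the lattice
    s = out.s.reshape(-1, 2).astype(float)
    dist = np.abs(s[:, :, None] - g[None, None, :]).min(axis=2)
    assert (dist < 0.01).all()


def test_posterior_save_load_round_trip(quick_fit, tmp_path):
    quick_fit.save(tmp_path)
    back = load_posterior(tmp_path)
    for k in quick_fit.params:
        assert np.allclose(back.params[k], quick_fit.params[k])
    assert back.area_km2 == pytest.approx(quick_fit.area_km2)
    assert back.M == quick_fit.M
    assert np.allclose(back.s, quick_fit.s)
    assert (back.z == quick_fit.z).all()


def test_fit_study_scale_smoke():
    """A short fit at the full study design runs end to end."""
    from rtscr import study_design, study_state_space

    traps = study_design()
    space = study_state_space(traps)
    sim = simulate_dataset(TruthParams(seed=3), traps, space)
    cfg = MCMCConfig(n_chains=2, n_iter=1500, n_burnin=500, thin=5, seed=3)
    out = fit_rtscr(sim.dataset, config=cfg)
    assert np.isfinite(out.stacked("sigma")).all()
    assert out.stacked("N").min() >= sim.dataset.captures.n_individuals
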