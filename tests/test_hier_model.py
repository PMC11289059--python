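"""Hierarchical-model tests: log-posterior oracle, sampler behaviour, R-hat."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtr

from prtddm import hier_model, pipeline, preprocess as prep, wfpt
from prtddm.hier_model import (
    FAMILIES,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    _SUPPORT,
    build_model,
    cohort_bias_interval,
    extract_subject_params,
    fit,
    rhat,
)
from prtddm.task_sim import TaskConfig


def _tiny_trials(n_sub=2, n_blocks=2, n_per_cond=4, seed=0):
    """Hand-sized trial table with valid RTs in every (participant, block)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        for b in range(1, n_blocks + 1):
            for stim in ("rich", "lean"):
                for _ in range(n_per_cond):
                    rows.append({
                        "participant_id": f"p{s + 1}",
                        "group": "star",
                        "block": b,
                        "stimulus": stim,
                        "correct": bool(rng.random() < 0.75),
                        "rt": float(rng.uniform(0.45, 1.5)),
                        "training": False,
                    })
    return pd.DataFrame(rows)


def _point(model, rng=None):
    """A valid parameter point (arrays ind, mu, sigma) for a model."""
    rng = rng or np.random.default_rng(1)
    S, B, F = model.n_sub, model.n_block, len(FAMILIES)
    ind = np.zeros((S, B, F))
    ind[:, :, 0] = rng.uniform(0.8, 1.2, (S, B))
    ind[:, :, 1] = rng.uniform(0.7, 1.1, (S, B))
    ind[:, :, 2] = rng.uniform(1.1, 1.5, (S, B))
    ind[:, :, 3] = rng.uniform(1.1, 1.5, (S, B))
    ind[:, :, 4] = rng.uniform(0.2, 0.35, (S, B))
    ind[:, :, 5] = rng.uniform(0.2, 0.35, (S, B))
    ind[:, :, 6] = rng.uniform(-0.3, 0.3, (S, B))
    G = model.n_group
    mu = np.zeros((G, B, F))
    sigma = np.zeros((G, B, F))
    mu[:, :, :] = [1.0, 0.9, 1.3, 1.3, 0.28, 0.28, 0.05]
    sigma[:, :, :] = [0.4, 0.4, 0.15, 0.15, 0.05, 0.05, 0.2]
    return ind, mu, sigma


# ---------------------------------------------------------------------------
# build_model / log-posterior
# ---------------------------------------------------------------------------


def test_log_posterior_finite_at_prior_centre():
    trials = _tiny_trials(n_sub=1, n_blocks=1)
    model = build_model(trials)
    ind, mu, sigma = _point(model)
    lp = model.log_posterior(ind, mu, sigma)
    assert np.isfinite(lp)


def test_log_posterior_matches_independent_oracle():
    """Term-by-term recomputation with scipy distributions and the public
    WFPT density."""
    trials = _tiny_trials()
    prior = PriorSpec()
    model = build_model(trials, prior)
    ind, mu, sigma = _point(model)
    lp = model.log_posterior(ind, mu, sigma)

    expected = 0.0
    # group-level priors
    for gi in range(model.n_group):
        for bi in range(model.n_block):
            for fi, fam in enumerate(FAMILIES):
                m, sd = mu[gi, bi, fi], sigma[gi, bi, fi]
                bounds = prior.mu_bounds(fi)
                if bounds is None:
                    expected += stats.norm.logpdf(m, 0.0, 10.0)
                else:
                    expected += stats.uniform.logpdf(m, bounds[0],
                                                     bounds[1] - bounds[0])
                expected += stats.halfcauchy.logpdf(sd, scale=2.5)
                # individual-level truncated normals
                lo, hi = _SUPPORT[fi]
                a_, b_ = (lo - m) / sd, (hi - m) / sd
                for si in range(model.n_sub):
                    expected += stats.truncnorm.logpdf(ind[si, bi, fi], a_, b_,
                                                       loc=m, scale=sd)
    # trial likelihood via the public density
    for si, pid in enumerate(model.participants):
        for bi, b in enumerate(model.blocks):
            sub = trials[(trials["participant_id"] == pid) & (trials["block"] == b)]
            th = ind[si, bi]
            for _, row in sub.iterrows():
                rich = row["stimulus"] == "rich"
                params = wfpt.DDMParams(
                    v=th[0] if rich else th[1],
                    a=th[2] if rich else th[3],
                    t=th[4] if rich else th[5],
                    z_raw=th[6] if rich else -th[6],
                )
                boundary = "upper" if row["correct"] else "lower"
                expected += wfpt.wfpt_logpdf(row["rt"], boundary, params)

    assert lp == pytest.approx(expected, rel=1e-9)


def test_log_posterior_additivity_under_duplication():
    trials = _tiny_trials(n_sub=2, n_blocks=1)
    model1 = build_model(trials)
    dup = pd.concat([
        trials,
        trials[trials["participant_id"] == "p1"],
    ], ignore_index=True)
    model2 = build_model(dup)
    assert model1.participants == model2.participants
    ind, mu, sigma = _point(model1)
    lp1 = model1.log_posterior(ind, mu, sigma)
    lp2 = model2.log_posterior(ind, mu, sigma)
    # duplication adds exactly p1's likelihood term, nothing else
    si = model1.participants.index("p1")
    lik_p1 = sum(
        hier_model._cell_part_loglik(model1.cells[(si, 0)], ind[si, 0], cond,
                                     model1.s, model1.eps)
        for cond in ("rich", "lean")
    )
    assert lp2 - lp1 == pytest.approx(lik_p1, rel=1e-9)


def test_empty_block_lists_offenders():
    trials = _tiny_trials(n_sub=2, n_blocks=2)
    broken = trials[~((trials["participant_id"] == "p2") & (trials["block"] == 2))]
    with pytest.raises(ValueError, match="p2/block2"):
        build_model(broken)


def test_missing_columns_rejected():
    with pytest.raises(ValueError, match="missing columns"):
        build_model(pd.DataFrame({"participant_id": ["a"], "rt": [0.5]}))


def test_out_of_support_point_is_impossible():
    trials = _tiny_trials(n_sub=1, n_blocks=1)
    model = build_model(trials)
    ind, mu, sigma = _point(model)
    bad_mu = mu.copy()
    bad_mu[0, 0, 2] = 50.0  # boundary mean outside its uniform prior
    assert model.log_posterior(ind, bad_mu, sigma) == -np.inf


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_fit():
    trials = _tiny_trials(n_sub=2, n_blocks=2, n_per_cond=6)
    spec = ModelSpec.reduced(chains=2, warmup=80, draws=80, sweeps=1)
    model = build_model(trials, PriorSpec(), spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws, diag = fit(model, seed=5)
    return model, draws, diag


def test_fit_deterministic(tiny_fit):
    model, draws, _ = tiny_fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws2, _ = fit(model, seed=5)
    np.testing.assert_array_equal(draws.values, draws2.values)


def test_fit_respects_truncations(tiny_fit):
    _, draws, _ = tiny_fit
    for fi, fam in enumerate(FAMILIES):
        lo, hi = _SUPPORT[fi]
        for name in draws.names:
            if name.startswith(fam + "["):
                v = draws.get(name)
                assert np.all(v >= lo) and np.all(v <= hi)
    # SDs strictly positive
    for name in draws.names:
        if name.startswith("sigma_"):
            assert np.all(draws.get(name) > 0)


def test_fit_draw_shapes(tiny_fit):
    model, draws, diag = tiny_fit
    assert draws.values.shape == (2, 80, len(model.param_names))
    assert set(diag.rhat) == set(model.param_names)
    assert diag.max_rhat >= 1.0 or math.isnan(diag.max_rhat)


def test_prior_only_fit_centres_drift_at_zero():
    model = build_model(None, PriorSpec(),
                        ModelSpec.reduced(chains=2, warmup=1000, draws=2000))
    draws, diag = fit(model, seed=2)
    pooled = np.concatenate(
        [draws.get(n).reshape(-1) for n in draws.names if n.startswith("mu_v_")])
    assert abs(pooled.mean()) < 1.5  # prior is centred at 0 with scale 10


def test_single_subject_convergence():
    """Easy data, generous draws: every R-hat at or below 1.01."""
    cfg = TaskConfig(trials_per_block=334, n_training_trials=0)
    trials, _ = pipeline.simulate_recovery_cohort(1, cfg, seed=9)
    filtered, _, _ = prep.preprocess(trials)
    spec = ModelSpec.reduced(chains=2, warmup=1000, draws=1000, sweeps=6)
    model = build_model(filtered, PriorSpec(), spec)
    draws, diag = fit(model, seed=5)
    assert diag.max_rhat <= 1.01
    assert diag.converged


def test_shrinkage_toward_group_mean():
    """A sparse participant's posterior mean sits closer to the group mean
    than its trial-only maximum-likelihood estimate."""
    rng = np.random.default_rng(30)
    cfg = TaskConfig(n_blocks=1, trials_per_block=96, n_training_trials=0)
    from prtddm.task_sim import AgentSpec, BlockParams, simulate_agent, trials_to_frame

    def agent(pid, v_rich, seed):
        bp = BlockParams(v_rich=v_rich, v_lean=1.0, a_rich=1.3, a_lean=1.3,
                         t_rich=0.28, t_lean=0.28, z_raw=0.0)
        return AgentSpec(pid, "star", {1: bp}, seed)

    frames = [trials_to_frame(simulate_agent(agent(f"p{i}", 1.0, 100 + i), cfg))
              for i in range(1, 7)]
    # sparse outlier: true drift far from the group's, only 5 rich trials kept
    sparse = trials_to_frame(simulate_agent(agent("p7", 3.0, 999), cfg))
    sparse_rich = sparse[sparse["stimulus"] == "rich"].head(5)
    sparse_lean = sparse[sparse["stimulus"] == "lean"].head(5)
    trials = pd.concat(frames + [sparse_rich, sparse_lean], ignore_index=True)

    model = build_model(trials, PriorSpec(),
                        ModelSpec.reduced(chains=2, warmup=400, draws=400))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws, diag = fit(model, seed=8)

    post = draws.mean("v_rich[p7,b1]")
    group_mean = draws.mean("mu_v_rich[star,b1]")

    # trial-only MLE of the sparse cell
    cell = model.cells[(model.participants.index("p7"), 0)]
    from scipy.optimize import minimize

    def nll(theta):
        tot = 0.0
        for cond in ("rich", "lean"):
            ll = hier_model._cell_part_loglik(cell, theta, cond, 1.0, 1e-7)
            if not np.isfinite(ll):
                return 1e9
            tot -= ll
        return tot

    x0 = np.array([1.5, 1.0, 1.3, 1.3, 0.28, 0.28, 0.0])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-8})
    mle_v = res.x[0]
    assert abs(post - group_mean) < abs(mle_v - group_mean)


# ---------------------------------------------------------------------------
# R-hat
# ---------------------------------------------------------------------------


def test_rhat_iid_chains_near_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 2000))
    for variant in ("rank", "classic"):
        r = rhat(x, variant=variant)["param"]
        assert r == pytest.approx(1.0, abs=0.01)


def test_rhat_detects_nonmixing():
    x = np.vstack([np.zeros(200), np.ones(200)])
    assert rhat(x, variant="classic")["param"] > 1.1
    assert rhat(x, variant="rank")["param"] > 1.1


def test_rhat_single_chain_rejected():
    with pytest.raises(ValueError):
        rhat(np.random.default_rng(0).normal(size=(1, 100)))


@pytest.mark.parametrize("variant,az_method", [("rank", "rank"),
                                               ("classic", "split")])
def test_rhat_matches_arviz(variant, az_method):
    import arviz as az
    rng = np.random.default_rng(42)
    # mildly autocorrelated chains on purpose
    x = rng.normal(size=(4, 500)).cumsum(axis=1) * 0.01 + rng.normal(size=(4, 500))
    mine = rhat(x, variant=variant)["param"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = float(az.rhat(x[None].transpose(1, 2, 0)[..., 0], method=az_method))
    assert mine == pytest.approx(ref, rel=1e-10)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _const_draws(value=0.7):
    names = []
    for fam in FAMILIES:
        names.append(f"{fam}[p1,b1]")
        names.append(f"mu_{fam}[g,b1]")
        names.append(f"sigma_{fam}[g,b1]")
    vals = np.full((2, 10, len(names)), value)
    return PosteriorDraws(names=names, values=vals,
                          metadata={"participants": ["p1"], "blocks": [1],
                                    "groups": ["g"]})


def test_extract_constant_draws():
    draws = _const_draws(0.7)
    est = extract_subject_params(draws)
    assert est.loc[0, "v_rich"] == pytest.approx(0.7)
    assert est.loc[0, "z_rich"] == pytest.approx(float(ndtr(0.7)))


def test_extract_bias_columns(tiny_fit):
    _, draws, diag = tiny_fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = extract_subject_params(draws, diag)
    assert ((est["z_rich"] > 0) & (est["z_rich"] < 1)).all()
    np.testing.assert_allclose(est["z_lean"], 1.0 - est["z_rich"], atol=0)


def test_extract_warns_when_not_converged(tiny_fit):
    _, draws, diag = tiny_fit
    if diag.converged:
        pytest.skip("tiny fit converged unexpectedly")
    with pytest.warns(RuntimeWarning, match="not converged"):
        extract_subject_params(draws, diag)


def test_cohort_bias_interval_bounds():
    draws = _const_draws(0.2)
    lo, hi, mean = cohort_bias_interval(draws, "g")
    assert lo == pytest.approx(hi) == pytest.approx(float(ndtr(0.2)))
    assert 0 < mean < 1
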