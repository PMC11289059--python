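"""Hierarchical Bayesian drift-diffusion model of PRT data.

Structure
---------
For every (feedback group x block) cell the model places group-level
distributions over seven parameter families: condition-specific drift
(v_rich, v_lean), boundary separation (a_rich, a_lean) and non-decision time
(t_rich, t_lean), plus a single raw starting bias z_raw whose phi-mapped
value is used on rich trials and its complement (1 - z) on lean trials.

Priors: group-level drift means are Normal(0, 10); group-level means of a, t
and z_raw are uniform over (0.1, 10), (0.1, 1) and (-4, 4) respectively; all
group-level SDs are half-Cauchy(2.5).  Individual per-block parameters are
normal around their group mean/SD, truncated to each family's support
(a > 0, t in [0, 1], z_raw in [-4, 4]; drift unbounded).

Inference is adaptive Metropolis-within-Gibbs: scalar random-walk updates of
every individual parameter (with the trial-level Wiener first-passage-time
likelihood) and every group-level mean/SD (prior terms only), with proposal
scales adapted toward a 0.44 acceptance rate during warmup.  Convergence is
assessed with split-chain R-hat (rank-normalised by default).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .wfpt import _logpdf as _wfpt_logpdf_kernel

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "PosteriorDraws",
    "FitDiagnostics",
    "HierarchicalDDM",
    "FAMILIES",
    "build_model",
    "fit",
    "extract_subject_params",
    "cohort_bias_interval",
    "rhat",
]

FAMILIES = ("v_rich", "v_lean", "a_rich", "a_lean", "t_rich", "t_lean", "z_raw")
_RICH_FAM = (0, 2, 4)
_LEAN_FAM = (1, 3, 5)
_Z_FAM = 6

#: truncation supports of the individual-level parameters
_SUPPORT = np.array([
    [-np.inf, np.inf],   # v_rich
    [-np.inf, np.inf],   # v_lean
    [0.0, np.inf],       # a_rich
    [0.0, np.inf],       # a_lean
    [0.0, 1.0],          # t_rich
    [0.0, 1.0],          # t_lean
    [-4.0, 4.0],         # z_raw
])


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the hierarchy."""

    a_bounds: tuple = (0.1, 10.0)
    t_bounds: tuple = (0.1, 1.0)
    zraw_bounds: tuple = (-4.0, 4.0)
    v_mean_loc: float = 0.0
    v_mean_scale: float = 10.0
    sd_scale: float = 2.5  # half-Cauchy scale of all group-level SDs

    def __post_init__(self) -> None:
        for name in ("a_bounds", "t_bounds", "zraw_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered interval")
        if self.v_mean_scale <= 0 or self.sd_scale <= 0:
            raise ValueError("prior scales must be positive")

    def mu_bounds(self, fam_idx: int) -> tuple:
        """Uniform-prior bounds of the group-level mean for a family
        (None for drift, whose mean prior is normal)."""
        if fam_idx in (0, 1):
            return None
        if fam_idx in (2, 3):
            return self.a_bounds
        if fam_idx in (4, 5):
            return self.t_bounds
        return self.zraw_bounds


@dataclass(frozen=True)
class ModelSpec:
    """MCMC layout: grouping is (feedback type x block); v/a/t split by
    rich/lean; lean bias is the complement of the rich bias."""

    chains: int = 4
    warmup: int = 2000
    draws: int = 2000
    sweeps: int = 3  # full update scans per stored draw (internal thinning)
    rhat_variant: str = "rank"  # or "classic"

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains")
        if self.warmup < 1 or self.draws < 1:
            raise ValueError("warmup and draws must be >= 1")
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")

    @classmethod
    def reduced(cls, chains: int = 2, warmup: int = 500, draws: int = 500,
                **kw) -> "ModelSpec":
        """Reduced-scale settings for tests and desk-scale recovery runs."""
        return cls(chains=chains, warmup=warmup, draws=draws, **kw)

    @classmethod
    def paper_scale(cls) -> "ModelSpec":
        return cls(chains=4, warmup=2000, draws=2000)


@dataclass
class PosteriorDraws:
    """MCMC output: array (chains, draws, n_params) plus parameter names."""

    names: list
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.names):
            raise ValueError("values must be (chains, draws, n_params)")
        self._index = {n: i for i, n in enumerate(self.names)}

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, draws)."""
        return self.values[:, :, self._index[name]]

    def mean(self, name: str) -> float:
        return float(self.get(name).mean())

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) table."""
        c, d, p = self.values.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d * p),
            "draw": np.tile(np.repeat(np.arange(d), p), c),
            "parameter": np.tile(self.names, c * d),
            "value": self.values.reshape(-1),
        })


@dataclass
class FitDiagnostics:
    rhat: dict
    ess: dict
    accept_rate: dict
    converged: bool
    max_rhat: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# numba likelihood kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _part_loglik(rts, upper, v, a, t, w, s, eps):
    """Summed WFPT log-likelihood over one condition's trials; -inf if any
    trial is impossible under the parameters."""
    total = 0.0
    for i in range(rts.shape[0]):
        ll = _wfpt_logpdf_kernel(rts[i], upper[i], v, a, t, w, s, eps)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def _phi(x):
    return ndtr(x)


def _cell_part_loglik(cell, theta, cond: str, s: float, eps: float) -> float:
    """Likelihood of one (participant, block) cell's rich or lean trials."""
    w = float(ndtr(theta[_Z_FAM]))
    if cond == "rich":
        return _part_loglik(cell["rt_rich"], cell["up_rich"],
                            theta[0], theta[2], theta[4], w, s, eps)
    return _part_loglik(cell["rt_lean"], cell["up_lean"],
                        theta[1], theta[3], theta[5], 1.0 - w, s, eps)


# ---------------------------------------------------------------------------
# prior densities
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _log_normal(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI


def _log_half_cauchy(x, scale):
    if x <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale * (1.0 + (x / scale) ** 2)))


def _log_truncnorm_sum(x, mu, sd, lo, hi):
    """Sum of truncated-normal log-densities over an array of individuals."""
    x = np.asarray(x, dtype=float)
    if np.any((x < lo) | (x > hi)):
        return -np.inf
    if np.isinf(lo) and np.isinf(hi):
        log_z = 0.0
    else:
        alpha = -np.inf if np.isinf(lo) else (lo - mu) / sd
        beta = np.inf if np.isinf(hi) else (hi - mu) / sd
        z = (1.0 if np.isinf(hi) else ndtr(beta)) - (0.0 if np.isinf(lo) else ndtr(alpha))
        if z <= 0:
            return -np.inf
        log_z = math.log(z)
    return float(np.sum(-0.5 * ((x - mu) / sd) ** 2) - x.size * (math.log(sd) + _LOG_SQRT_2PI + log_z))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class HierarchicalDDM:
    """Assembled model: data arrays, prior spec, and the log-posterior."""

    def __init__(self, trials, prior: PriorSpec, spec: ModelSpec,
                 s: float = 1.0, eps: float = 1e-7,
                 groups=None, blocks=None):
        self.prior = prior
        self.spec = spec
        self.s = float(s)
        self.eps = float(eps)

        if trials is None or len(trials) == 0:
            # prior-only model: group-level cells but no individuals
            self.participants = []
            self.part_group = []
            self.groups = list(groups) if groups else ["all"]
            self.blocks = list(blocks) if blocks else [1, 2, 3]
            self.cells = {}
            self.data_hash = "prior-only"
        else:
            required = {"participant_id", "block", "stimulus", "correct", "rt"}
            missing = required - set(trials.columns)
            if missing:
                raise ValueError(f"trial table missing columns: {sorted(missing)}")
            trials = trials.copy()
            if "group" not in trials.columns:
                trials["group"] = "all"
            if "training" in trials.columns:
                trials = trials[~trials["training"].astype(bool)]
            self.participants = sorted(trials["participant_id"].unique())
            self.blocks = sorted(int(b) for b in trials["block"].unique())
            gmap = trials.drop_duplicates("participant_id").set_index(
                "participant_id")["group"].to_dict()
            self.part_group = [gmap[p] for p in self.participants]
            self.groups = sorted(set(self.part_group))

            offenders = []
            self.cells = {}
            for si, pid in enumerate(self.participants):
                psub = trials[trials["participant_id"] == pid]
                for bi, b in enumerate(self.blocks):
                    sub = psub[psub["block"] == b]
                    if len(sub) == 0:
                        offenders.append((pid, b))
                        continue
                    rich = sub["stimulus"].to_numpy() == "rich"
                    rt = sub["rt"].to_numpy(dtype=float)
                    up = sub["correct"].to_numpy(dtype=bool)
                    self.cells[(si, bi)] = {
                        "rt_rich": np.ascontiguousarray(rt[rich]),
                        "up_rich": np.ascontiguousarray(up[rich]),
                        "rt_lean": np.ascontiguousarray(rt[~rich]),
                        "up_lean": np.ascontiguousarray(up[~rich]),
                    }
            if offenders:
                raise ValueError(
                    "participants with empty blocks: "
                    + ", ".join(f"{p}/block{b}" for p, b in offenders)
                )
            h = hashlib.sha256(
                pd.util.hash_pandas_object(
                    trials[sorted(trials.columns)].reset_index(drop=True),
                    index=False).to_numpy().tobytes()
            ).hexdigest()
            self.data_hash = h[:16]

        self.n_sub = len(self.participants)
        self.n_block = len(self.blocks)
        self.n_group = len(self.groups)
        self.group_index = {g: i for i, g in enumerate(self.groups)}
        self.sub_gidx = np.array(
            [self.group_index[g] for g in self.part_group], dtype=int
        ) if self.n_sub else np.zeros(0, dtype=int)

        self.param_names = self._build_names()

    # -- naming ------------------------------------------------------------

    def _build_names(self):
        names = []
        for gi, g in enumerate(self.groups):
            for bi, b in enumerate(self.blocks):
                for f in FAMILIES:
                    names.append(f"mu_{f}[{g},b{b}]")
                    names.append(f"sigma_{f}[{g},b{b}]")
        for si, pid in enumerate(self.participants):
            for bi, b in enumerate(self.blocks):
                for f in FAMILIES:
                    names.append(f"{f}[{pid},b{b}]")
        return names

    def pack(self, ind, mu, sigma):
        """Flatten (ind, mu, sigma) arrays into the named parameter vector."""
        out = np.empty(len(self.param_names))
        k = 0
        for gi in range(self.n_group):
            for bi in range(self.n_block):
                for fi in range(len(FAMILIES)):
                    out[k] = mu[gi, bi, fi]
                    out[k + 1] = sigma[gi, bi, fi]
                    k += 2
        for si in range(self.n_sub):
            for bi in range(self.n_block):
                for fi in range(len(FAMILIES)):
                    out[k] = ind[si, bi, fi]
                    k += 1
        return out

    # -- log-posterior -----------------------------------------------------

    def log_likelihood(self, ind) -> float:
        total = 0.0
        for (si, bi), cell in self.cells.items():
            theta = ind[si, bi]
            total += _cell_part_loglik(cell, theta, "rich", self.s, self.eps)
            total += _cell_part_loglik(cell, theta, "lean", self.s, self.eps)
        return total

    def log_prior(self, ind, mu, sigma) -> float:
        total = 0.0
        for gi in range(self.n_group):
            for bi in range(self.n_block):
                for fi in range(len(FAMILIES)):
                    m, sd = mu[gi, bi, fi], sigma[gi, bi, fi]
                    bounds = self.prior.mu_bounds(fi)
                    if bounds is None:
                        total += _log_normal(m, self.prior.v_mean_loc,
                                             self.prior.v_mean_scale)
                    else:
                        if not bounds[0] <= m <= bounds[1]:
                            return -np.inf
                        total += -math.log(bounds[1] - bounds[0])
                    hc = _log_half_cauchy(sd, self.prior.sd_scale)
                    if not np.isfinite(hc):
                        return -np.inf
                    total += hc
                    members = np.flatnonzero(self.sub_gidx == gi)
                    if members.size:
                        lo, hi = _SUPPORT[fi]
                        total += _log_truncnorm_sum(
                            ind[members, bi, fi], m, sd, lo, hi)
        return total

    def log_posterior(self, ind, mu, sigma) -> float:
        """Evaluable at any parameter point; -inf outside the support."""
        lp = self.log_prior(ind, mu, sigma)
        if not np.isfinite(lp):
            return lp
        return lp + self.log_likelihood(ind)


def build_model(trials, prior: PriorSpec | None = None,
                spec: ModelSpec | None = None, **kw) -> HierarchicalDDM:
    """Assemble the hierarchical DDM over a preprocessed trial table.

    Pass ``trials=None`` (with optional ``groups``/``blocks``) for a
    prior-only model.  Raises if any participant has a block without valid
    trials, listing the offenders.
    """
    return HierarchicalDDM(trials, prior or PriorSpec(), spec or ModelSpec(), **kw)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _init_state(model: HierarchicalDDM, rng):
    S, B, F = model.n_sub, model.n_block, len(FAMILIES)
    ind = np.zeros((S, B, F))
    for (si, bi), cell in model.cells.items():
        rts = np.concatenate([cell["rt_rich"], cell["rt_lean"]])
        tmin = rts.min() if rts.size else 0.5
        ind[si, bi, 0] = rng.normal(1.0, 0.3)
        ind[si, bi, 1] = rng.normal(1.0, 0.3)
        ind[si, bi, 2] = math.exp(rng.normal(math.log(1.3), 0.1))
        ind[si, bi, 3] = math.exp(rng.normal(math.log(1.3), 0.1))
        t0 = min(tmin, 1.0) * rng.uniform(0.4, 0.7)
        ind[si, bi, 4] = t0
        ind[si, bi, 5] = t0
        ind[si, bi, 6] = np.clip(rng.normal(0.0, 0.2), -3.5, 3.5)
    G = model.n_group
    mu = np.zeros((G, B, F))
    sigma = np.zeros((G, B, F))
    defaults = np.array([1.0, 1.0, 1.3, 1.3, 0.4, 0.4, 0.0])
    sig0 = np.array([0.5, 0.5, 0.2, 0.2, 0.1, 0.1, 0.3])
    for gi in range(G):
        members = np.flatnonzero(model.sub_gidx == gi)
        for bi in range(B):
            for fi in range(F):
                if members.size:
                    m = float(ind[members, bi, fi].mean())
                else:
                    m = defaults[fi]
                bounds = model.prior.mu_bounds(fi)
                if bounds is not None:
                    m = float(np.clip(m, bounds[0] + 1e-3, bounds[1] - 1e-3))
                mu[gi, bi, fi] = m
                sigma[gi, bi, fi] = sig0[fi]
    return ind, mu, sigma


def _run_chain(model: HierarchicalDDM, seed: int, warmup: int, draws: int,
               sweeps: int = 3):
    rng = np.random.default_rng(seed)
    S, B, F = model.n_sub, model.n_block, len(FAMILIES)
    G = model.n_group
    ind, mu, sigma = _init_state(model, rng)

    # cached per-cell condition likelihoods
    ll_rich = np.zeros((S, B))
    ll_lean = np.zeros((S, B))
    for (si, bi), cell in model.cells.items():
        ll_rich[si, bi] = _cell_part_loglik(cell, ind[si, bi], "rich",
                                            model.s, model.eps)
        ll_lean[si, bi] = _cell_part_loglik(cell, ind[si, bi], "lean",
                                            model.s, model.eps)

    ind_scale = np.full((S, B, F), 0.25)
    ind_scale[:, :, (4, 5)] = 0.05   # t moves on a tighter scale
    ind_scale[:, :, 6] = 0.15
    mu_scale = np.full((G, B, F), 0.2)
    sig_scale = np.full((G, B, F), 0.4)  # log-scale RW

    acc = {"ind": np.zeros((S, B, F)), "mu": np.zeros((G, B, F)),
           "sigma": np.zeros((G, B, F))}
    tries = {k: np.zeros_like(v) for k, v in acc.items()}
    ADAPT_EVERY = 25

    n_iter = warmup + draws
    out = np.empty((draws, len(model.param_names)))

    def _update_individual():
        for (si, bi), cell in model.cells.items():
            gi = model.sub_gidx[si]
            theta = ind[si, bi]
            for fi in range(F):
                x = theta[fi]
                prop = x + ind_scale[si, bi, fi] * rng.standard_normal()
                tries["ind"][si, bi, fi] += 1
                lo, hi = _SUPPORT[fi]
                if not lo < prop < hi:
                    continue
                m, sd = mu[gi, bi, fi], sigma[gi, bi, fi]
                d_prior = (-0.5 * ((prop - m) / sd) ** 2
                           + 0.5 * ((x - m) / sd) ** 2)
                theta_new = theta.copy()
                theta_new[fi] = prop
                d_lik = 0.0
                new_r, new_l = ll_rich[si, bi], ll_lean[si, bi]
                if fi in _RICH_FAM or fi == _Z_FAM:
                    new_r = _cell_part_loglik(cell, theta_new, "rich",
                                              model.s, model.eps)
                    d_lik += new_r - ll_rich[si, bi]
                if fi in _LEAN_FAM or fi == _Z_FAM:
                    new_l = _cell_part_loglik(cell, theta_new, "lean",
                                              model.s, model.eps)
                    d_lik += new_l - ll_lean[si, bi]
                if not np.isfinite(d_lik):
                    continue
                if math.log(rng.random()) < d_prior + d_lik:
                    theta[fi] = prop
                    ll_rich[si, bi], ll_lean[si, bi] = new_r, new_l
                    acc["ind"][si, bi, fi] += 1

    def _update_group():
        for gi in range(G):
            members = np.flatnonzero(model.sub_gidx == gi)
            for bi in range(B):
                for fi in range(F):
                    lo, hi = _SUPPORT[fi]
                    xs = ind[members, bi, fi] if members.size else np.empty(0)
                    m, sd = mu[gi, bi, fi], sigma[gi, bi, fi]

                    # mean update
                    tries["mu"][gi, bi, fi] += 1
                    prop = m + mu_scale[gi, bi, fi] * rng.standard_normal()
                    bounds = model.prior.mu_bounds(fi)
                    ok = True
                    if bounds is None:
                        d_hyper = (_log_normal(prop, model.prior.v_mean_loc,
                                               model.prior.v_mean_scale)
                                   - _log_normal(m, model.prior.v_mean_loc,
                                                 model.prior.v_mean_scale))
                    elif bounds[0] <= prop <= bounds[1]:
                        d_hyper = 0.0
                    else:
                        ok = False
                    if ok:
                        delta = d_hyper + (
                            _log_truncnorm_sum(xs, prop, sd, lo, hi)
                            - _log_truncnorm_sum(xs, m, sd, lo, hi)
                        ) if xs.size else d_hyper
                        if np.isfinite(delta) and math.log(rng.random()) < delta:
                            mu[gi, bi, fi] = prop
                            m = prop
                            acc["mu"][gi, bi, fi] += 1

                    # SD update (random walk on log sigma, with Jacobian)
                    tries["sigma"][gi, bi, fi] += 1
                    lprop = math.log(sd) + sig_scale[gi, bi, fi] * rng.standard_normal()
                    sprop = math.exp(lprop)
                    delta = (_log_half_cauchy(sprop, model.prior.sd_scale)
                             - _log_half_cauchy(sd, model.prior.sd_scale)
                             + (lprop - math.log(sd)))
                    if xs.size:
                        delta += (_log_truncnorm_sum(xs, m, sprop, lo, hi)
                                  - _log_truncnorm_sum(xs, m, sd, lo, hi))
                    if np.isfinite(delta) and math.log(rng.random()) < delta:
                        sigma[gi, bi, fi] = sprop
                        acc["sigma"][gi, bi, fi] += 1

    for it in range(n_iter):
        for _ in range(sweeps):
            _update_individual()
            _update_group()

        # --- adaptation (warmup only) --------------------------------------
        if it < warmup and (it + 1) % ADAPT_EVERY == 0:
            for key, scale in (("ind", ind_scale), ("mu", mu_scale),
                               ("sigma", sig_scale)):
                with np.errstate(invalid="ignore"):
                    rate = np.where(tries[key] > 0, acc[key] / np.maximum(tries[key], 1), 0.44)
                scale *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                np.clip(scale, 1e-4, 10.0, out=scale)
                acc[key][:] = 0.0
                tries[key][:] = 0.0

        if it >= warmup:
            out[it - warmup] = model.pack(ind, mu, sigma)

    total_acc = {k: float(acc[k].sum() / max(tries[k].sum(), 1))
                 for k in acc}
    return out, total_acc


def fit(model: HierarchicalDDM, seed: int,
        spec: ModelSpec | None = None, progress: bool = False):
    """Run the MCMC; returns ``(PosteriorDraws, FitDiagnostics)``.

    Deterministic given ``seed``.  The convergence flag is set when the
    maximum R-hat over all parameters is <= 1.01.
    """
    spec = spec or model.spec
    chains = []
    accs = []
    for c in range(spec.chains):
        chain_seed = np.random.SeedSequence([int(seed), c]).generate_state(1)[0]
        draws_c, acc = _run_chain(model, int(chain_seed), spec.warmup,
                                  spec.draws, sweeps=spec.sweeps)
        chains.append(draws_c)
        accs.append(acc)
    values = np.stack(chains, axis=0)

    draws = PosteriorDraws(
        names=list(model.param_names),
        values=values,
        metadata={
            "seed": int(seed),
            "chains": spec.chains,
            "warmup": spec.warmup,
            "draws": spec.draws,
            "data_hash": model.data_hash,
            "groups": model.groups,
            "blocks": model.blocks,
            "participants": model.participants,
        },
    )
    _check_truncations(model, draws)

    rh = rhat(draws, variant=spec.rhat_variant)
    ess = _ess(draws)
    max_rhat = float(np.nanmax(list(rh.values()))) if rh else float("nan")
    diag = FitDiagnostics(
        rhat=rh,
        ess=ess,
        accept_rate={k: float(np.mean([a[k] for a in accs])) for k in accs[0]},
        converged=bool(max_rhat <= 1.01),
        max_rhat=max_rhat,
    )
    if all(a["ind"] == 0 for a in accs) and model.n_sub > 0:
        raise RuntimeError("sampler failure: no individual-level proposals accepted")
    return draws, diag


def _check_truncations(model: HierarchicalDDM, draws: PosteriorDraws) -> None:
    for fi, fam in enumerate(FAMILIES):
        lo, hi = _SUPPORT[fi]
        for name in draws.names:
            if name.startswith(fam + "["):
                vals = draws.get(name)
                if np.any(vals < lo) or np.any(vals > hi):
                    raise RuntimeError(f"draws of {name} violate truncation bounds")


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _split_chains(x: np.ndarray) -> np.ndarray:
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, half:half * 2]], axis=0)


def _rhat_base(x: np.ndarray) -> float:
    m, n = x.shape
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if w == 0:
        return 1.0 if var_plus == 0 else np.inf
    return float(np.sqrt(var_plus / w))


def _z_scale(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average").reshape(x.shape)
    return ndtri((r - 3.0 / 8.0) / (x.size - 2.0 * 3.0 / 8.0 + 1.0))


def _rhat_single(x: np.ndarray, variant: str) -> float:
    xs = _split_chains(np.asarray(x, dtype=float))
    if variant == "classic":
        return _rhat_base(xs)
    if variant == "rank":
        bulk = _rhat_base(_z_scale(xs))
        folded = _rhat_base(_z_scale(np.abs(xs - np.median(xs))))
        return max(bulk, folded)
    raise ValueError("variant must be 'rank' or 'classic'")


def rhat(draws, variant: str = "rank") -> dict:
    """Split-chain Gelman–Rubin statistic per parameter.

    variant="rank" (default) is the rank-normalised split statistic (max of
    bulk and folded); variant="classic" is the plain split-chain statistic.
    Accepts a PosteriorDraws or a (chains, draws) array (then returns a
    single-entry dict keyed "param").
    """
    if isinstance(draws, np.ndarray):
        if draws.ndim != 2 or draws.shape[0] < 2:
            raise ValueError("need a (chains >= 2, draws) array")
        return {"param": _rhat_single(draws, variant)}
    if draws.values.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains")
    return {name: _rhat_single(draws.get(name), variant)
            for name in draws.names}


def _ess(draws: PosteriorDraws) -> dict:
    import warnings
    import arviz as az
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in draws.names:
            out[name] = float(az.ess(np.asarray(draws.get(name))))
    return out


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_subject_params(draws: PosteriorDraws, diagnostics=None) -> pd.DataFrame:
    """Per-(participant, block) posterior-mean point estimates.

    Columns: v/a/t for rich and lean, the phi-mapped rich-trial bias
    ``z_rich`` (posterior mean of the mapped draws, guaranteed in (0, 1)) and
    ``z_lean = 1 - z_rich`` exactly.  A non-converged fit produces a warning
    but extraction proceeds.
    """
    if diagnostics is not None and not diagnostics.converged:
        import warnings
        warnings.warn(
            f"fit not converged (max R-hat {diagnostics.max_rhat:.3f}); "
            "point estimates may be unreliable", RuntimeWarning)
    meta = draws.metadata
    rows = []
    for pid in meta["participants"]:
        for b in meta["blocks"]:
            row = {"participant_id": pid, "block": b}
            for fam in FAMILIES[:-1]:
                row[fam] = draws.mean(f"{fam}[{pid},b{b}]")
            z_draws = ndtr(draws.get(f"z_raw[{pid},b{b}]"))
            row["z_rich"] = float(z_draws.mean())
            row["z_lean"] = 1.0 - row["z_rich"]
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_bias_interval(draws: PosteriorDraws, group: str,
                         level: float = 0.95):
    """Posterior interval of the cohort-mean mapped starting bias for one
    feedback group, averaging the mapped group-level bias means over blocks.

    Returns ``(lo, hi, posterior mean)``.
    """
    meta = draws.metadata
    per_draw = np.mean(
        [ndtr(draws.get(f"mu_z_raw[{group},b{b}]")) for b in meta["blocks"]],
        axis=0,
    ).reshape(-1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(per_draw, [alpha, 1.0 - alpha])
    return float(lo), float(hi), float(per_draw.mean())
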