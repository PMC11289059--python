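"""Wiener first-passage-time (WFPT) density, bias mapping, and process sampling.

This module is the likelihood core of the drift-diffusion model (DDM): a
numerically stable log-density of (choice, RT) pairs, the phi mapping of the
raw starting bias onto (0, 1), parameter validation against the model's
truncation bounds, and an exact-process Euler–Maruyama sampler used both as
the forward model for task simulation and as an independent oracle for the
density.

Conventions
-----------
* The density is parameterised by drift ``v`` (signed, evidence units per
  second), boundary separation ``a`` (> 0), non-decision time ``t`` (seconds),
  and the relative starting point ``w`` in (0, 1) measured from the lower
  boundary.
* Choice coding is *accuracy coding*: the upper boundary is the correct
  response on every trial.  A bias toward a particular response is expressed
  upstream by using ``w`` on trials where that response is correct and
  ``1 - w`` on the complementary trials.
* The diffusion scale ``s`` defaults to 1.0; ``s = 0.1`` is selectable for
  cross-checks against the older DDM literature.

The density switches between the small-time and large-time series expansions
of the first-passage distribution so that the absolute density error stays
below a configurable tolerance (default ``1e-7``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "WFPTOptions",
    "BiasRangeError",
    "BoundaryError",
    "NonDecisionTimeError",
    "map_bias",
    "validate_params",
    "wfpt_logpdf",
    "wfpt_pdf",
    "sample_ddm",
    "prob_upper",
]

Z_RAW_LO = -4.0
Z_RAW_HI = 4.0
T_LO = 0.0
T_HI = 1.0


class BoundaryError(ValueError):
    """Boundary separation must be strictly positive."""


class NonDecisionTimeError(ValueError):
    """Non-decision time out of its closed [0, 1] second bound, or rt <= t."""


class BiasRangeError(ValueError):
    """Raw starting bias out of its closed [-4, 4] bound."""


@dataclass(frozen=True)
class DDMParams:
    """One condition's evidence-accumulation parameters.

    ``z_raw`` lives on the unconstrained [-4, 4] scale; the relative starting
    point used by the likelihood is ``map_bias(z_raw)``.
    """

    v: float
    a: float
    t: float
    z_raw: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        validate_params(self)

    @property
    def z(self) -> float:
        """Mapped starting point in (0, 1)."""
        return map_bias(self.z_raw)


@dataclass(frozen=True)
class WFPTOptions:
    """Numerical options for the density evaluation."""

    tolerance: float = 1e-7
    choice_coding: str = "accuracy_coded"
    min_rt_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.choice_coding != "accuracy_coded":
            raise ValueError("only accuracy_coded choice coding is supported")


def map_bias(z_raw: float) -> float:
    """Map the raw bias from [-4, 4] to (0, 1) via the standard-normal CDF."""
    if not Z_RAW_LO <= z_raw <= Z_RAW_HI:
        raise BiasRangeError(f"z_raw={z_raw!r} outside [{Z_RAW_LO}, {Z_RAW_HI}]")
    return 0.5 * (1.0 + math.erf(z_raw / math.sqrt(2.0)))


def validate_params(params: DDMParams) -> DDMParams:
    """Enforce the truncation bounds; return ``params`` unchanged or raise."""
    if not params.a > 0:
        raise BoundaryError(f"boundary separation a={params.a!r} must be > 0")
    if not T_LO <= params.t <= T_HI:
        raise NonDecisionTimeError(
            f"non-decision time t={params.t!r} outside [{T_LO}, {T_HI}]"
        )
    if not Z_RAW_LO <= params.z_raw <= Z_RAW_HI:
        raise BiasRangeError(
            f"z_raw={params.z_raw!r} outside [{Z_RAW_LO}, {Z_RAW_HI}]"
        )
    if not params.s > 0:
        raise ValueError(f"diffusion scale s={params.s!r} must be > 0")
    return params


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ftt01w(tt: float, w: float, eps: float) -> float:
    """Density of the normalised (a=1, v=0) first passage through the lower
    boundary at normalised time ``tt``, start fraction ``w``.

    Chooses the series (small-time vs large-time) that needs fewer terms for
    absolute error < ``eps``.
    """
    # required number of small-time terms
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # required number of large-time terms
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-wk * wk / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(
                k * math.pi * w
            )
        p *= math.pi
    return p


@njit(cache=True)
def _logpdf_lower(rt: float, v: float, a: float, t: float, w: float,
                  s: float, eps: float) -> float:
    """Log-density of a lower-boundary crossing at time ``rt``.

    Returns -inf when rt <= t (the likelihood is zero there) or when the
    truncated series underflows to a non-positive value.
    """
    u = rt - t
    if u <= 0.0:
        return -np.inf
    # rescale to unit diffusion
    vs = v / s
    as_ = a / s
    tt = u / (as_ * as_)
    p = _ftt01w(tt, w, eps)
    if p <= 0.0:
        return -np.inf
    return (
        math.log(p)
        - 2.0 * math.log(as_)
        - vs * as_ * w
        - vs * vs * u / 2.0
    )


@njit(cache=True)
def _logpdf(rt: float, upper: bool, v: float, a: float, t: float, w: float,
            s: float, eps: float) -> float:
    # reflection: upper-boundary density equals lower-boundary with v -> -v,
    # w -> 1 - w
    if upper:
        return _logpdf_lower(rt, -v, a, t, 1.0 - w, s, eps)
    return _logpdf_lower(rt, v, a, t, w, s, eps)


@njit(cache=True)
def _sample_kernel(n: int, v: float, a: float, t: float, w: float, s: float,
                   dt: float, seed: int, max_time: float):
    """Euler–Maruyama first-passage sampler; choice 1=upper, 0=lower,
    -1=censored at max_time."""
    np.random.seed(seed)
    choices = np.empty(n, dtype=np.int8)
    rts = np.empty(n, dtype=np.float64)
    sq = s * math.sqrt(dt)
    max_steps = int(max_time / dt)
    for i in range(n):
        x = a * w
        step = 0
        while True:
            step += 1
            x += v * dt + sq * np.random.normal()
            if x >= a:
                choices[i] = 1
                rts[i] = t + step * dt
                break
            if x <= 0.0:
                choices[i] = 0
                rts[i] = t + step * dt
                break
            if step >= max_steps:
                choices[i] = -1
                rts[i] = t + max_time
                break
    return choices, rts


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_DEFAULT_OPTS = WFPTOptions()


def wfpt_logpdf(rt, boundary_hit, params: DDMParams,
                opts: WFPTOptions = _DEFAULT_OPTS):
    """Log-density of a (boundary, RT) observation under the DDM.

    Parameters
    ----------
    rt : float or array
        Response time in seconds; must exceed ``params.t``.
    boundary_hit : {"upper", "lower"}
        Which boundary was crossed.  Under accuracy coding "upper" is the
        correct response.
    params : DDMParams
        Validated parameters; the starting point used is
        ``map_bias(params.z_raw)``.
    opts : WFPTOptions
        Series truncation tolerance.

    Raises
    ------
    NonDecisionTimeError
        If any rt <= params.t (zero likelihood region).
    """
    validate_params(params)
    if boundary_hit not in ("upper", "lower"):
        raise ValueError(f"boundary_hit must be 'upper' or 'lower', got {boundary_hit!r}")
    upper = boundary_hit == "upper"
    w = map_bias(params.z_raw)
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    if np.any(rt_arr <= params.t + opts.min_rt_gap):
        raise NonDecisionTimeError(
            f"rt must exceed non-decision time t={params.t}; got min rt={rt_arr.min()}"
        )
    out = np.empty_like(rt_arr)
    for i, r in enumerate(rt_arr):
        out[i] = _logpdf(r, upper, params.v, params.a, params.t, w,
                         params.s, opts.tolerance)
    return out[0] if np.isscalar(rt) or np.ndim(rt) == 0 else out


def wfpt_pdf(rt, boundary_hit, params: DDMParams,
             opts: WFPTOptions = _DEFAULT_OPTS):
    """Density (not log) of a (boundary, RT) observation. See wfpt_logpdf."""
    return np.exp(wfpt_logpdf(rt, boundary_hit, params, opts))


def prob_upper(params: DDMParams) -> float:
    """Analytic probability of an upper-boundary crossing.

    P(upper) = (1 - exp(-2 v a w / s^2)) / (exp(2 v a (1-w) / s^2) - exp(-2 v a w / s^2))
    with the v -> 0 limit equal to w... (limit handled explicitly).
    """
    validate_params(params)
    w = map_bias(params.z_raw)
    vv = params.v * params.a / params.s**2
    if abs(vv) < 1e-10:
        return w
    # P(hit upper before lower) from start fraction w with drift v
    num = 1.0 - math.exp(-2.0 * vv * w)
    den = 1.0 - math.exp(-2.0 * vv)
    return num / den


def sample_ddm(params: DDMParams, n: int, seed: int, dt: float = 1e-4,
               max_time: float = 20.0):
    """Draw ``n`` (boundary_hit, rt) pairs by Euler–Maruyama simulation.

    Returns
    -------
    choices : int8 array
        1 = upper boundary, 0 = lower boundary, -1 = censored (no crossing
        within ``max_time`` seconds of accumulation); censored trials must be
        excluded from fits.
    rts : float array
        Crossing time plus non-decision time, seconds.
    """
    validate_params(params)
    if dt > 1e-3:
        raise ValueError(f"dt={dt} too coarse; require dt <= 1e-3 s")
    if n < 0:
        raise ValueError("n must be >= 0")
    w = map_bias(params.z_raw)
    return _sample_kernel(n, params.v, params.a, params.t, w, params.s,
                          dt, seed, max_time)
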