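"""Generative simulator of the probabilistic reward task (PRT).

Builds balanced rich/lean trial schedules, assigns reward feedback under the
skewed (75%/25% reward-on-correct) schedule, and simulates drift-diffusion
agents producing choices and RTs, yielding long-format synthetic cohorts with
the statistical structure the downstream analysis assumes.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import wfpt
from .wfpt import DDMParams, map_bias

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "BlockParams",
    "AgentSpec",
    "GROUPS",
    "build_schedule",
    "assign_feedback",
    "simulate_agent",
    "simulate_cohort",
    "trials_to_frame",
]

GROUPS = ("star", "verbal", "face", "thumbs")

DEFAULT_TIMING_MS = {"face": 500, "mouth": 100, "feedback": 1750, "iti": 500}


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one PRT session.

    Defaults reproduce the published design: three 96-trial blocks with equal
    rich/lean counts, ten training trials, and reward probabilities of 0.75
    (rich) and 0.25 (lean) conditional on a correct response.
    """

    n_blocks: int = 3
    trials_per_block: int = 96
    n_training_trials: int = 10
    p_reward_rich: float = 0.75
    p_reward_lean: float = 0.25
    timing_ms: dict = field(default_factory=lambda: dict(DEFAULT_TIMING_MS))
    reward_mode: str = "bernoulli"  # or "quota"

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be >= 1")
        if self.trials_per_block % 2 != 0:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} is odd: rich/lean "
                "counts cannot be balanced"
            )
        if not 0.0 <= self.p_reward_lean < self.p_reward_rich <= 1.0:
            raise ValueError(
                "require 0 <= p_reward_lean < p_reward_rich <= 1, got "
                f"lean={self.p_reward_lean}, rich={self.p_reward_rich}"
            )
        if any(d <= 0 for d in self.timing_ms.values()):
            raise ValueError("all event durations must be > 0 ms")
        if self.reward_mode not in ("bernoulli", "quota"):
            raise ValueError("reward_mode must be 'bernoulli' or 'quota'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrialRecord:
    """One task trial: stimulus identity, response, correctness, reward, RT."""

    participant_id: str
    group: str
    block: int  # 0 = training, 1..n_blocks = main task
    trial_index: int
    stimulus: str  # "rich" | "lean"
    mouth: str  # "short" | "long"
    response: str  # "rich" | "lean"
    correct: bool
    rewarded: bool
    rt: float  # seconds
    training: bool = False

    def __post_init__(self) -> None:
        if self.rewarded and not self.correct:
            raise ValueError("rewarded implies correct")
        if self.rt <= 0:
            raise ValueError("rt must be > 0")
        if self.correct != (self.response == self.stimulus):
            raise ValueError("correct must equal (response == stimulus)")


@dataclass(frozen=True)
class BlockParams:
    """Per-block DDM parameters of a simulated agent.

    Drift, boundary and non-decision time are condition-specific; the raw
    starting bias is shared, with the lean-trial starting point taken as the
    complement of the rich-trial one (z_lean = 1 - z_rich, i.e. the raw bias
    negated under the phi mapping).
    """

    v_rich: float
    v_lean: float
    a_rich: float
    a_lean: float
    t_rich: float
    t_lean: float
    z_raw: float
    s: float = 1.0

    def ddm_params(self, stimulus: str) -> DDMParams:
        if stimulus == "rich":
            return DDMParams(self.v_rich, self.a_rich, self.t_rich,
                             self.z_raw, self.s)
        if stimulus == "lean":
            # phi(-z_raw) == 1 - phi(z_raw)
            return DDMParams(self.v_lean, self.a_lean, self.t_lean,
                             -self.z_raw, self.s)
        raise ValueError(f"unknown stimulus {stimulus!r}")


@dataclass(frozen=True)
class AgentSpec:
    """A synthetic participant: per-block DDM parameters plus identity/seed."""

    participant_id: str
    group: str
    params: dict  # block (1-based) -> BlockParams
    seed: int

    def __post_init__(self) -> None:
        for b, bp in self.params.items():
            if not isinstance(bp, BlockParams):
                raise TypeError(f"params[{b}] must be BlockParams")


def _participant_index(participant_id) -> int:
    """Stable integer derived from a participant id, used for seeding and
    counterbalancing parity."""
    s = str(participant_id)
    digits = "".join(ch for ch in s if ch.isdigit())
    if digits:
        return int(digits)
    return zlib.crc32(s.encode())


def build_schedule(config: TaskConfig, participant_id, seed: int) -> list[tuple]:
    """Ordered trial slots ``(block, trial_index, stimulus, mouth)``.

    Training slots come first with block 0.  Every main block holds exactly
    ``trials_per_block/2`` rich and lean slots in seeded-random order.  The
    short/long mouth serving as the rich stimulus alternates with participant
    parity (counterbalancing across participants); the schedule is
    deterministic given ``(seed, participant_id)``.
    """
    pidx = _participant_index(participant_id)
    rng = np.random.default_rng([int(seed), pidx])
    rich_mouth = "short" if pidx % 2 == 0 else "long"
    lean_mouth = "long" if rich_mouth == "short" else "short"
    mouth_of = {"rich": rich_mouth, "lean": lean_mouth}

    slots: list[tuple] = []
    for j in range(config.n_training_trials):
        stim = "rich" if rng.random() < 0.5 else "lean"
        slots.append((0, j + 1, stim, mouth_of[stim]))
    half = config.trials_per_block // 2
    for b in range(1, config.n_blocks + 1):
        stims = np.array(["rich"] * half + ["lean"] * half)
        rng.shuffle(stims)
        for j, stim in enumerate(stims):
            slots.append((b, j + 1, str(stim), mouth_of[str(stim)]))
    return slots


def assign_feedback(stimulus: str, correct: bool, config: TaskConfig,
                    rng: np.random.Generator) -> bool:
    """Reward flag for one response: only correct responses are ever rewarded,
    with probability ``p_reward_rich`` (rich) or ``p_reward_lean`` (lean)."""
    if not correct:
        return False
    p = config.p_reward_rich if stimulus == "rich" else config.p_reward_lean
    return bool(rng.random() < p)


class _QuotaFeedback:
    """Optional controlled-quota reward scheduler: per block, targets
    round(p * n_correct_expected) rewards by drawing without replacement from
    a pre-committed reward sequence per stimulus."""

    def __init__(self, config: TaskConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        half = config.trials_per_block // 2
        self._pools: dict[str, list[bool]] = {}
        for stim, p in (("rich", config.p_reward_rich),
                        ("lean", config.p_reward_lean)):
            n_target = int(round(p * half))
            pool = [True] * n_target + [False] * (half - n_target)
            self.rng.shuffle(pool)
            self._pools[stim] = pool

    def __call__(self, stimulus: str, correct: bool) -> bool:
        if not correct:
            return False
        pool = self._pools[stimulus]
        if not pool:
            return False
        return pool.pop()


def simulate_agent(spec: AgentSpec, config: TaskConfig) -> list[TrialRecord]:
    """Simulate one agent through a full session.

    Choices and RTs are drawn from the DDM for the trial's (block, stimulus)
    cell via Euler–Maruyama sampling; rewards follow :func:`assign_feedback`.
    Training trials (block 0) use the block-1 parameters and are flagged.
    Reproducible given ``spec.seed``.
    """
    for b in range(1, config.n_blocks + 1):
        if b not in spec.params:
            raise ValueError(f"agent {spec.participant_id} missing params for block {b}")
    schedule = build_schedule(config, spec.participant_id, spec.seed)
    rng = np.random.default_rng([int(spec.seed), 7, _participant_index(spec.participant_id)])

    quota = None
    if config.reward_mode == "quota":
        quota_by_block = {}

    records: list[TrialRecord] = []
    # one sampler call per (block, stimulus) cell, consumed trial by trial
    counts: dict[tuple, int] = {}
    for block, _, stim, _ in schedule:
        counts[(block, stim)] = counts.get((block, stim), 0) + 1
    draws: dict[tuple, tuple] = {}
    for (block, stim), n in counts.items():
        bp = spec.params[block if block >= 1 else 1]
        params = bp.ddm_params(stim)
        sub_seed = int(
            np.random.default_rng(
                [int(spec.seed), _participant_index(spec.participant_id), block,
                 0 if stim == "rich" else 1]
            ).integers(0, 2**31 - 1)
        )
        choices, rts = wfpt.sample_ddm(params, n, seed=sub_seed)
        draws[(block, stim)] = [list(choices), list(rts)]

    for block, j, stim, mouth in schedule:
        choices, rts = draws[(block, stim)]
        choice, rt = choices.pop(0), rts.pop(0)
        if choice == -1:
            # censored walk: record at the guard time as an (implausibly slow)
            # incorrect response; preprocessing removes it via the RT window
            correct = False
        else:
            correct = bool(choice == 1)  # accuracy coding: upper == correct
        response = stim if correct else ("lean" if stim == "rich" else "rich")
        training = block == 0
        if training:
            rewarded = False  # training gives correct/incorrect info, not reward
        elif config.reward_mode == "quota":
            if block not in quota_by_block:
                quota_by_block[block] = _QuotaFeedback(config, rng)
            rewarded = quota_by_block[block](stim, correct)
        else:
            rewarded = assign_feedback(stim, correct, config, rng)
        records.append(
            TrialRecord(
                participant_id=str(spec.participant_id),
                group=spec.group,
                block=block,
                trial_index=j,
                stimulus=stim,
                mouth=mouth,
                response=response,
                correct=correct,
                rewarded=rewarded,
                rt=float(rt),
                training=training,
            )
        )
    return records


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long-format trial table, one row per TrialRecord."""
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: plausible cohort-level means used by default group distributions
_DEFAULT_FAMILY_DIST = {
    "v_rich": (1.05, 0.25),
    "v_lean": (0.95, 0.25),
    "a_rich": (1.28, 0.12),
    "a_lean": (1.27, 0.12),
    "t_rich": (0.28, 0.04),
    "t_lean": (0.28, 0.04),
    "z_raw": (0.075, 0.05),
}

_FAMILY_SUPPORT = {
    "v_rich": (-np.inf, np.inf),
    "v_lean": (-np.inf, np.inf),
    "a_rich": (1e-3, np.inf),
    "a_lean": (1e-3, np.inf),
    "t_rich": (0.0, 1.0),
    "t_lean": (0.0, 1.0),
    "z_raw": (-4.0, 4.0),
}

FAMILIES = tuple(_DEFAULT_FAMILY_DIST)


def _draw_truncated(rng, mean, sd, lo, hi):
    if sd < 0:
        raise ValueError("distribution sd must be >= 0")
    if not (lo <= mean <= hi):
        raise ValueError(f"distribution mean {mean} outside support [{lo}, {hi}]")
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise ValueError(f"could not draw within support [{lo}, {hi}] around {mean}")


def simulate_cohort(group_specs: dict, n_per_group: int, config: TaskConfig,
                    seed: int):
    """Simulate a multi-group cohort of DDM agents.

    Parameters
    ----------
    group_specs : dict
        ``group name -> {family: (mean, sd)}`` with families among
        ``FAMILIES``; omitted families fall back to package defaults.
        Individual per-block parameters are drawn i.i.d. from normal
        distributions truncated to each family's valid support.
    n_per_group : int
        Agents per group (>= 1).
    config : TaskConfig
    seed : int
        Global seed; all agent seeds derive from it.

    Returns
    -------
    trials : pandas.DataFrame
        Long-format trial table for all agents.
    truth : pandas.DataFrame
        True per-(participant, block) parameters, including the mapped bias
        (for recovery scoring).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    frames, truth_rows = [], []
    pnum = 0
    for group, fam_spec in group_specs.items():
        dists = dict(_DEFAULT_FAMILY_DIST)
        for fam, ms in (fam_spec or {}).items():
            if fam not in _FAMILY_SUPPORT:
                raise ValueError(f"unknown parameter family {fam!r}")
            dists[fam] = (float(ms[0]), float(ms[1]))
        for _ in range(n_per_group):
            pnum += 1
            pid = f"p{pnum:03d}"
            params = {}
            for b in range(1, config.n_blocks + 1):
                vals = {
                    fam: _draw_truncated(rng, *dists[fam], *_FAMILY_SUPPORT[fam])
                    for fam in FAMILIES
                }
                params[b] = BlockParams(**vals)
                truth_rows.append(
                    {"participant_id": pid, "group": group, "block": b,
                     **vals, "z_rich": map_bias(vals["z_raw"])}
                )
            agent_seed = int(rng.integers(0, 2**31 - 1))
            spec = AgentSpec(participant_id=pid, group=group, params=params,
                             seed=agent_seed)
            frames.append(trials_to_frame(simulate_agent(spec, config)))
    trials = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def write_cohort(trials: pd.DataFrame, truth: pd.DataFrame, config: TaskConfig,
                 path, sidecar_path=None, seed=None) -> None:
    """Write the trial table as CSV (RT with >= 4 decimals) plus a JSON
    sidecar holding the true agent parameters and the config."""
    trials = trials.copy()
    trials["rt"] = trials["rt"].map(lambda x: f"{x:.6f}")
    trials.to_csv(path, index=False)
    if sidecar_path is not None:
        payload = {
            "config": config.to_dict(),
            "seed": seed,
            "true_params": truth.to_dict(orient="records"),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=1)
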