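"""Orchestration, recovery scoring, and reporting.

End-to-end runs go simulation -> preprocessing -> signal-detection indices ->
hierarchical DDM fit -> summary tables; the recovery harness simulates a
cohort with known parameters, fits it, and scores true-vs-estimated
agreement.  Every stage logs its seed, input hash, and row counts, and all
outputs are deterministic given the configured seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import pearsonr

from . import hier_model, preprocess as prep, reference, sdt, task_sim
from .hier_model import FAMILIES, ModelSpec, PriorSpec
from .task_sim import AgentSpec, BlockParams, TaskConfig

logger = logging.getLogger("prtddm")

__all__ = [
    "RunConfig",
    "RecoveryReport",
    "run_pipeline",
    "run_recovery",
    "summarize_groups",
    "simulate_reward_counts",
    "default_truth_generator",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Nested run configuration; JSON round-trippable, all seeds recorded."""

    seed: int = 0
    out_dir: str = "prt_run"
    groups: tuple = task_sim.GROUPS
    n_per_group: int = 4
    group_specs: dict = field(default_factory=dict)  # group -> {family: (mean, sd)}
    task: dict = field(default_factory=dict)  # TaskConfig overrides
    rt_lo: float = prep.RT_LO
    rt_hi: float = prep.RT_HI
    fit: bool = True
    chains: int = 2
    warmup: int = 500
    draws: int = 500

    def task_config(self) -> TaskConfig:
        return TaskConfig(**self.task)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(chains=self.chains, warmup=self.warmup, draws=self.draws)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["groups"] = tuple(d.get("groups", task_sim.GROUPS))
        return cls(**d)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_groups(indices: pd.DataFrame, estimates: pd.DataFrame | None = None,
                     trials: pd.DataFrame | None = None):
    """Descriptive group x block (x condition) means and SDs.

    Single-participant cells report SD = 0 with an ``n1_flag``.  Returns a
    dict of data frames: ``behaviour`` (RT and accuracy per group x block x
    stimulus, when ``trials`` given), ``indices`` (log b / log d per group x
    block), ``params`` (DDM estimates per group x block x condition, when
    ``estimates`` given).
    """
    if indices is None or len(indices) == 0:
        raise ValueError("empty indices table")
    out = {}

    def _agg(df, keys, cols):
        rows = []
        for key_vals, sub in df.groupby(keys, sort=True):
            if len(sub) == 0:
                raise ValueError(f"empty group cell {key_vals!r}")
            if not isinstance(key_vals, tuple):
                key_vals = (key_vals,)
            row = dict(zip(keys, key_vals))
            n = sub["participant_id"].nunique()
            row["n"] = n
            row["n1_flag"] = n == 1
            for c in cols:
                row[f"{c}_mean"] = float(sub[c].mean())
                row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if n > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows)

    out["indices"] = _agg(indices, ["group", "block"], ["log_b", "log_d"])

    if trials is not None:
        per_part = (
            trials.groupby(["group", "block", "stimulus", "participant_id"])
            .agg(rt=("rt", "mean"), acc=("correct", "mean"))
            .reset_index()
        )
        per_part["acc"] *= 100.0
        out["behaviour"] = _agg(per_part, ["group", "block", "stimulus"],
                                ["rt", "acc"])

    if estimates is not None:
        long = []
        for cond in ("rich", "lean"):
            sub = estimates[["participant_id", "group", "block",
                             f"v_{cond}", f"a_{cond}", f"t_{cond}", f"z_{cond}"]].copy()
            sub.columns = ["participant_id", "group", "block", "v", "a", "t", "z"]
            sub["condition"] = cond
            long.append(sub)
        long = pd.concat(long, ignore_index=True)
        out["params"] = _agg(long, ["group", "block", "condition"],
                             ["v", "a", "t", "z"])
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> preprocess -> indices -> (fit) -> summaries.

    Writes all artifacts into ``config.out_dir`` and returns a dict of output
    paths.  Deterministic given ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _stage(name):
        logger.info("stage %s: seed=%s", name, config.seed)

    try:
        _stage("simulate")
        task_cfg = config.task_config()
        specs = {g: config.group_specs.get(g, {}) for g in config.groups}
        trials, truth = task_sim.simulate_cohort(
            specs, config.n_per_group, task_cfg, seed=config.seed)
        paths["cohort"] = str(out / "cohort.csv")
        paths["truth"] = str(out / "cohort.truth.json")
        task_sim.write_cohort(trials, truth, task_cfg, paths["cohort"],
                              paths["truth"], seed=config.seed)
        logger.info("simulate: %d rows, hash=%s", len(trials),
                    _file_hash(paths["cohort"]))
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {e}") from e

    try:
        _stage("preprocess")
        filtered, excl, filt = prep.preprocess(trials, lo=config.rt_lo,
                                               hi=config.rt_hi)
        paths["filtered"] = str(out / "cohort.filtered.csv")
        ff = filtered.copy()
        ff["rt"] = ff["rt"].map(lambda x: f"{x:.6f}")
        ff.to_csv(paths["filtered"], index=False)
        paths["reports"] = str(out / "preprocess_report.json")
        with open(paths["reports"], "w") as fh:
            json.dump({"exclusion": excl.to_dict(), "filter": filt.to_dict(),
                       "seed": config.seed}, fh, indent=1)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'preprocess' failed: {e}") from e

    try:
        _stage("metrics")
        indices = sdt.indices_table(filtered)
        paths["indices"] = str(out / "indices.csv")
        indices.to_csv(paths["indices"], index=False, float_format="%.6f")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'metrics' failed: {e}") from e

    estimates = None
    if config.fit:
        try:
            _stage("fit")
            model = hier_model.build_model(filtered, PriorSpec(),
                                           config.model_spec())
            draws, diag = hier_model.fit(model, seed=config.seed)
            paths["draws"] = str(out / "posterior_draws.csv")
            draws.to_frame().to_csv(paths["draws"], index=False,
                                    float_format="%.8g")
            paths["diagnostics"] = str(out / "fit_diagnostics.json")
            with open(paths["diagnostics"], "w") as fh:
                json.dump(diag.to_dict(), fh, indent=1)
            estimates = hier_model.extract_subject_params(draws)
            gmap = trials.drop_duplicates("participant_id").set_index(
                "participant_id")["group"].to_dict()
            estimates.insert(1, "group", estimates["participant_id"].map(gmap))
            paths["estimates"] = str(out / "estimates.csv")
            estimates.to_csv(paths["estimates"], index=False,
                             float_format="%.6f")
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'fit' failed: {e}") from e

    try:
        _stage("report")
        summaries = summarize_groups(indices, estimates, trials=filtered)
        for key, df in summaries.items():
            paths[f"summary_{key}"] = str(out / f"summary_{key}.csv")
            df.to_csv(paths[f"summary_{key}"], index=False,
                      float_format="%.6f")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'report' failed: {e}") from e

    config.to_json(out / "run_config.json")
    paths["config"] = str(out / "run_config.json")
    return paths


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------


#: prior-plausible recovery region (v, a, t in native units; z on the mapped scale)
RECOVERY_REGION = {
    "v": (0.6, 1.6),
    "a": (1.0, 1.6),
    "t": (0.2, 0.35),
    "z": (0.45, 0.60),
}


def default_truth_generator(rng: np.random.Generator,
                            region: dict | None = None) -> BlockParams:
    """Draw one (participant, block) truth uniformly over the plausible
    region."""
    r = region or RECOVERY_REGION
    return BlockParams(
        v_rich=rng.uniform(*r["v"]),
        v_lean=rng.uniform(*r["v"]),
        a_rich=rng.uniform(*r["a"]),
        a_lean=rng.uniform(*r["a"]),
        t_rich=rng.uniform(*r["t"]),
        t_lean=rng.uniform(*r["t"]),
        z_raw=float(ndtri(rng.uniform(*r["z"]))),
    )


@dataclass
class RecoveryReport:
    """True-vs-estimated comparison over a simulated cohort."""

    per_param: dict  # family -> {"r": .., "bias": .., "rmse": ..}
    group_coverage: dict  # family -> fraction of (block) cells whose true
    #                       group mean falls in the 95% posterior interval
    metadata: dict

    def __post_init__(self) -> None:
        for fam, d in self.per_param.items():
            if not -1.0 <= d["r"] <= 1.0 or d["rmse"] < 0:
                raise ValueError(f"invalid recovery scores for {fam}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def summary(self) -> str:
        lines = ["parameter recovery:"]
        for fam, d in self.per_param.items():
            lines.append(
                f"  {fam:>2}: r={d['r']:+.3f}  bias={d['bias']:+.3f}  "
                f"rmse={d['rmse']:.3f}"
            )
        lines.append(f"  group-mean 95% coverage: "
                     + ", ".join(f"{k}={v:.2f}" for k, v in self.group_coverage.items()))
        return "\n".join(lines)


def simulate_recovery_cohort(n_agents: int, config: TaskConfig, seed: int,
                             truth_generator=None, group: str = "star"):
    """Simulate ``n_agents`` with truths drawn per (participant, block) from
    ``truth_generator`` (default: uniform over the plausible region)."""
    rng = np.random.default_rng(seed)
    gen = truth_generator or default_truth_generator
    frames, truth_rows = [], []
    for i in range(n_agents):
        pid = f"p{i + 1:03d}"
        params = {}
        for b in range(1, config.n_blocks + 1):
            bp = gen(rng)
            params[b] = bp
            truth_rows.append({
                "participant_id": pid, "group": group, "block": b,
                **dataclasses.asdict(bp), "z_rich": float(ndtr(bp.z_raw)),
            })
        spec = AgentSpec(participant_id=pid, group=group, params=params,
                         seed=int(rng.integers(0, 2**31 - 1)))
        frames.append(task_sim.trials_to_frame(task_sim.simulate_agent(spec, config)))
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)


def score_recovery(truth: pd.DataFrame, estimates: pd.DataFrame,
                   draws=None, metadata=None) -> RecoveryReport:
    """Pearson r, mean signed bias, and RMSE per parameter family, pooling
    rich/lean and blocks; plus group-level 95% interval coverage when draws
    are supplied."""
    merged = truth.merge(estimates, on=["participant_id", "block"],
                         suffixes=("_true", "_est"))
    if len(merged) == 0:
        raise ValueError("no overlap between truth and estimates")
    per_param = {}
    pools = {
        "v": [("v_rich", "v_rich"), ("v_lean", "v_lean")],
        "a": [("a_rich", "a_rich"), ("a_lean", "a_lean")],
        "t": [("t_rich", "t_rich"), ("t_lean", "t_lean")],
        "z": [("z_rich", "z_rich")],
    }
    for fam, pairs in pools.items():
        t_all, e_all = [], []
        for tcol, ecol in pairs:
            t_all.append(merged[f"{tcol}_true"].to_numpy(dtype=float))
            e_all.append(merged[f"{ecol}_est"].to_numpy(dtype=float))
        t_all = np.concatenate(t_all)
        e_all = np.concatenate(e_all)
        r = float(pearsonr(t_all, e_all).statistic) if len(t_all) > 2 else float("nan")
        per_param[fam] = {
            "r": r,
            "bias": float(np.mean(e_all - t_all)),
            "rmse": float(np.sqrt(np.mean((e_all - t_all) ** 2))),
        }

    coverage = {}
    if draws is not None:
        meta = draws.metadata
        group = meta["groups"][0]
        fam_cols = {"v": ("v_rich", "v_lean"), "a": ("a_rich", "a_lean"),
                    "t": ("t_rich", "t_lean"), "z": ("z_raw",)}
        for fam, cols in fam_cols.items():
            hits, cells = 0, 0
            for b in meta["blocks"]:
                for col in cols:
                    true_mean = truth.loc[truth["block"] == b, col].mean()
                    mu_draws = draws.get(f"mu_{col}[{group},b{b}]").reshape(-1)
                    lo, hi = np.quantile(mu_draws, [0.025, 0.975])
                    hits += int(lo <= true_mean <= hi)
                    cells += 1
            coverage[fam] = hits / cells
    return RecoveryReport(per_param=per_param, group_coverage=coverage,
                          metadata=metadata or {})


def run_recovery(n_agents: int = 12, seed: int = 0,
                 config: TaskConfig | None = None,
                 spec: ModelSpec | None = None,
                 truth_generator=None,
                 out_path=None,
                 max_bad_rhat_frac: float = 0.25) -> RecoveryReport:
    """Simulate, preprocess, fit, and score a recovery cohort.

    Raises with diagnostics when more than ``max_bad_rhat_frac`` of the
    parameters have R-hat > 1.2 (non-convergence).
    """
    config = config or TaskConfig()
    spec = spec or ModelSpec.reduced()
    trials, truth = simulate_recovery_cohort(n_agents, config, seed,
                                             truth_generator)
    filtered, excl, filt = prep.preprocess(trials)
    logger.info("recovery: %d agents, %d/%d trials kept, %d excluded",
                n_agents, filt.n_after, filt.n_before, excl.n_excluded)
    model = hier_model.build_model(filtered, PriorSpec(), spec)
    draws, diag = hier_model.fit(model, seed=seed)
    bad = np.mean([v > 1.2 for v in diag.rhat.values()])
    if bad > max_bad_rhat_frac:
        raise RuntimeError(
            f"recovery fit failed to converge: {bad:.0%} of parameters with "
            f"R-hat > 1.2 (max {diag.max_rhat:.3f})"
        )
    estimates = hier_model.extract_subject_params(draws, diag)
    meta = {
        "n_agents": n_agents,
        "trials_per_agent": config.n_blocks * config.trials_per_block,
        "chains": spec.chains, "warmup": spec.warmup, "draws": spec.draws,
        "seed": seed, "max_rhat": diag.max_rhat,
    }
    report = score_recovery(truth, estimates, draws=draws, metadata=meta)
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        with open(str(out_path) + ".txt", "w") as fh:
            fh.write(report.summary() + "\n")
    return report


# ---------------------------------------------------------------------------
# design-level session simulation (reward-count benchmark)
# ---------------------------------------------------------------------------


def simulate_reward_counts(n_sessions: int, seed: int,
                           config: TaskConfig | None = None,
                           accuracy=None) -> np.ndarray:
    """Total reward-feedback count per simulated session.

    Each trial is correct with the probability of its stimulus-by-block cell
    (default: the across-group benchmark accuracy profile); rewards then
    follow the skewed reward-on-correct rule.
    """
    config = config or TaskConfig()
    acc = accuracy or {
        (stim, b): reference.mean_accuracy(stim, b)
        for stim in ("rich", "lean") for b in range(1, config.n_blocks + 1)
    }
    rng = np.random.default_rng(seed)
    half = config.trials_per_block // 2
    totals = np.zeros(n_sessions, dtype=int)
    for s in range(n_sessions):
        n = 0
        for b in range(1, config.n_blocks + 1):
            for stim in ("rich", "lean"):
                p_corr = acc[(stim, b)]
                for _ in range(half):
                    correct = rng.random() < p_corr
                    if task_sim.assign_feedback(stim, correct, config, rng):
                        n += 1
        totals[s] = n
    return totals
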