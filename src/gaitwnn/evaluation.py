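"""Experimental protocol: shuffled 70/30 splits over three sequences,
cubic-spline reconstruction of full angle profiles from the 22 estimated
points, RMSE / NRMSE / Pearson-rho scoring, and In-/Out-Sample reporting
for the wavelet network and the MLP baseline.

Scoring convention: each sample's 22 estimated angle points per joint are
interpolated back to the 101-point phase grid with a natural cubic spline
through the sample's own event-schedule knots, compared against that
cycle's ground-truth channel; RMSE (degrees), NRMSE (% of the ground-truth
range) and rho are then averaged (mean +/- SD) over the samples in scope.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import pearsonr

from . import wnn_core
from .gi_features import EventSchedule, assemble_matrices, cycle_to_sample
from .preprocess import GaitCycleRecord, PHASE_GRID, trial_to_cycle
from .synthetic_gait import RawTrial

JOINT_SLICES = {"ankle": slice(0, 22), "knee": slice(22, 44), "hip": slice(44, 66)}
JOINT_CHANNELS = {"ankle": "theta_a", "knee": "theta_k", "hip": "theta_h"}


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """One shuffled 70/30 train/test partition."""

    sequence_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def make_splits(n: int, seeds: tuple[int, ...] = (11, 22, 33)) -> list[SplitPlan]:
    """Independent shuffled 70/30 partitions of ``n`` samples, one per seed
    (three sequences by default)."""
    if n < 10:
        raise ValueError("need at least 10 samples to split 70/30")
    if not seeds:
        raise ValueError("need at least one sequence seed")
    plans = []
    n_train = int(round(0.7 * n))
    for sid, seed in enumerate(seeds, start=1):
        order = np.random.default_rng(seed).permutation(n)
        plans.append(
            SplitPlan(
                sequence_id=sid,
                train_idx=np.sort(order[:n_train]),
                test_idx=np.sort(order[n_train:]),
                seed=seed,
            )
        )
    return plans


def reconstruct_profile(values: np.ndarray, schedule: EventSchedule) -> np.ndarray:
    """Cubic spline through the 22 (event index, angle) knots, evaluated on
    the 0-100 % grid.

    Not-a-knot boundary conditions: they reproduce polynomials up to cubic
    exactly and avoid the artificial end-flattening a natural spline would
    impose on the profile boundaries.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (22,):
        raise ValueError("expected 22 angle values")
    knots = schedule.indexes
    if np.unique(knots).size != knots.size:
        raise ValueError("duplicate knot abscissae")
    spline = CubicSpline(knots, values, bc_type="not-a-knot")
    return spline(PHASE_GRID)


@dataclasses.dataclass(frozen=True)
class ProfileScores:
    rmse: float   # degrees
    nrmse: float  # % of ground-truth range
    rho: float


def score_profiles(est: np.ndarray, truth: np.ndarray) -> ProfileScores:
    """RMSE (deg), range-normalized RMSE (%), and Pearson correlation."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("profile length mismatch")
    span = truth.max() - truth.min()
    if span == 0:
        raise ValueError("constant ground truth: NRMSE and rho undefined")
    rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
    rho = float(pearsonr(est, truth).statistic)
    return ProfileScores(rmse=rmse, nrmse=rmse / span * 100.0, rho=rho)


@dataclasses.dataclass
class ExperimentConfig:
    """End-to-end experiment settings."""

    training: wnn_core.TrainingConfig = dataclasses.field(
        default_factory=wnn_core.TrainingConfig
    )
    split_seeds: tuple[int, int, int] = (11, 22, 33)
    include_mlp: bool = True
    cycle_mode: str = "IC_to_NIC"
    filter_cutoff_hz: float | None = None
    predefined: dict[str, float] | None = None


@dataclasses.dataclass
class EvaluationReport:
    """mean +/- SD of RMSE/NRMSE/rho per model, sequence, joint and scope."""

    # results[model][sequence_id][joint][scope][metric] = {"mean":, "sd":}
    results: dict
    chosen_sequence: dict[str, int]
    n_samples: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "n_samples": self.n_samples,
                "chosen_sequence": self.chosen_sequence,
                "results": self.results,
            },
            indent=1,
        )

    def to_table(self) -> str:
        lines = []
        for model, seqs in self.results.items():
            lines.append(f"model: {model} (chosen sequence: {self.chosen_sequence[model]})")
            lines.append(
                f"  {'seq':>3} {'joint':>6} {'scope':>10} "
                f"{'RMSE(deg)':>14} {'NRMSE(%)':>14} {'rho':>14}"
            )
            for sid, joints in seqs.items():
                for joint, scopes in joints.items():
                    for scope, metrics in scopes.items():
                        cells = [
                            f"{metrics[m]['mean']:6.3f}±{metrics[m]['sd']:5.3f}"
                            for m in ("rmse", "nrmse", "rho")
                        ]
                        lines.append(
                            f"  {sid:>3} {joint:>6} {scope:>10} "
                            + " ".join(f"{c:>14}" for c in cells)
                        )
            lines.append("")
        return "\n".join(lines)

    def mean_rmse(self, model: str, sequence_id: int, scope: str = "all") -> float:
        joints = self.results[model][sequence_id]
        return float(
            np.mean([joints[j][scope]["rmse"]["mean"] for j in JOINT_SLICES])
        )


def _mean_sd(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0}


def prepare_samples(
    cohort: list[RawTrial], config: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray, list[GaitCycleRecord], list[EventSchedule]]:
    """Cohort -> normalized cycles, per-cycle schedules, x (22 x n), y (66 x n)."""
    cycles, schedules, pairs = [], [], []
    for trial in cohort:
        cyc = trial_to_cycle(trial, mode=config.cycle_mode,
                             cutoff_hz=config.filter_cutoff_hz)
        feats, targs, sched = cycle_to_sample(cyc, config.predefined)
        cycles.append(cyc)
        schedules.append(sched)
        pairs.append((feats, targs))
    x, y = assemble_matrices(pairs)
    return x, y, cycles, schedules


def _score_all_samples(params, x, cycles, schedules) -> dict[str, list[ProfileScores]]:
    yhat = wnn_core.forward(params, x)
    per_joint: dict[str, list[ProfileScores]] = {j: [] for j in JOINT_SLICES}
    for p in range(x.shape[1]):
        for joint, sl in JOINT_SLICES.items():
            est = reconstruct_profile(yhat[sl, p], schedules[p])
            truth = getattr(cycles[p], JOINT_CHANNELS[joint])
            per_joint[joint].append(score_profiles(est, truth))
    return per_joint


def run_experiment(cohort: list[RawTrial], config: ExperimentConfig) -> EvaluationReport:
    """Full protocol: per sequence, train on the 70% split, predict every
    sample, reconstruct profiles, score, and aggregate by scope; the
    sequence with the least mean RMSE (all samples, across joints) is
    chosen per model."""
    x, y, cycles, schedules = prepare_samples(cohort, config)
    n = x.shape[1]
    plans = make_splits(n, config.split_seeds)
    models = ["wnn"] + (["mlp"] if config.include_mlp else [])
    results: dict = {m: {} for m in models}

    for plan in plans:
        xtr, ytr = x[:, plan.train_idx], y[:, plan.train_idx]
        for model in models:
            cfg = config.training
            if model == "wnn":
                params0 = wnn_core.init_params(
                    xtr, ytr, cfg.n_hidden, seed=cfg.seed,
                    dilation_scale=cfg.dilation_scale,
                    init_weight_range=cfg.init_weight_range,
                )
                fitted, _ = wnn_core.train(params0, xtr, ytr, cfg)
            else:
                fitted, _ = wnn_core.mlp_baseline(xtr, ytr, cfg)
            try:
                per_joint = _score_all_samples(fitted, x, cycles, schedules)
            except Exception as err:  # surface with sequence context
                raise RuntimeError(
                    f"scoring failed in sequence {plan.sequence_id}: {err}"
                ) from err
            in_set = set(plan.train_idx.tolist())
            seq_res = {}
            for joint, scores in per_joint.items():
                scopes = {
                    "all": range(n),
                    "in_sample": [i for i in range(n) if i in in_set],
                    "out_sample": [i for i in range(n) if i not in in_set],
                }
                seq_res[joint] = {
                    scope: {
                        metric: _mean_sd([getattr(scores[i], metric) for i in idxs])
                        for metric in ("rmse", "nrmse", "rho")
                    }
                    for scope, idxs in scopes.items()
                }
            results[model][plan.sequence_id] = seq_res

    report = EvaluationReport(results=results, chosen_sequence={}, n_samples=n)
    for model in models:
        report.chosen_sequence[model] = min(
            results[model], key=lambda sid: report.mean_rmse(model, sid)
        )
    return report
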