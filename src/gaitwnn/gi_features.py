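"""Gait-Intervals (GI) feature selection.

Builds the 22-event schedule of one normalized gait cycle — 9 main gait
events (IC, OTO, HR, OIC, ITO, NTO, FA, TV, NIC) plus 13 intermediate
events spread over the seven sub-phases (LR, MST, TST, PSW, ISW, MSW, TSW)
— and extracts the 22 vGRF input features and 66 joint-angle targets
(ankle, knee, hip blocks) from each cycle.

Conventions:

* main events occupy feature numbers m in {1, 3, 6, 9, 11, 12, 15, 19, 22};
  intermediates fill the rest;
* the stance/swing transition (toe-off for a stance-initiated cycle,
  contact for a swing-initiated one) is a single physical instant serving
  two event roles; its index is split by +/-1 % into pre and post events;
* intermediate events inside a sub-phase bounded by main events at
  t_start < t_end with n intermediates use step b = (t_end - t_start)/(n+1)
  and land on the nearest integer grid index to t_start + k*b (round half
  up), which always lies inside the +/-1 % buffer at 1 % resolution;
* duplicate indexes are removed by shifting the later event +1 % until all
  22 indexes are unique;
* features at swing-leg events are taken from the opposite-leg signal and
  negated, so they cannot clash with stance-phase patterns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import GaitCycleRecord

#: Default predefined main-event indexes (% of an IC-initiated cycle).
#: Normative gait-phase boundaries; configurable.
DEFAULT_PREDEFINED = {"OTO": 10, "HR": 30, "OIC": 50, "FA": 73, "TV": 87}

#: Same landmarks expressed in a swing-initiated (ITO-start) cycle with the
#: contact instant near 40 %.
DEFAULT_PREDEFINED_SWING = {"FA": 13, "TV": 27, "OTO": 50, "HR": 70, "OIC": 90}

MAIN_FEATURE_NUMBERS = (1, 3, 6, 9, 11, 12, 15, 19, 22)
INTERMEDIATE_FEATURE_NUMBERS = (2, 4, 5, 7, 8, 10, 13, 14, 16, 17, 18, 20, 21)

#: Main-event feature numbers of a swing-initiated (ITO-start) cycle, where
#: the sub-phase order is rotated around the contact instant.
MAIN_FEATURE_NUMBERS_SWING = (1, 4, 8, 11, 12, 14, 17, 20, 22)

#: Sub-phase intermediate-event counts (sum = 13).
SUBPHASE_COUNTS = {"LR": 1, "MST": 2, "TST": 2, "PSW": 1, "ISW": 2, "MSW": 3, "TSW": 2}

# Cycle layouts: alternating main-event labels and (sub-phase, count) gaps.
# A None gap means the two mains are the split halves of a common instant.
_LAYOUTS = {
    "IC": [
        "IC", ("LR", 1), "OTO", ("MST", 2), "HR", ("TST", 2), "OIC",
        ("PSW", 1), "ITO", None, "NTO", ("ISW", 2), "FA", ("MSW", 3), "TV",
        ("TSW", 2), "NIC",
    ],
    "ITO": [
        "ITO", ("ISW", 2), "FA", ("MSW", 3), "TV", ("TSW", 2), "NIC",
        None, "IC", ("LR", 1), "OTO", ("MST", 2), "HR", ("TST", 2), "OIC",
        ("PSW", 1), "NTO",
    ],
}


@dataclasses.dataclass(frozen=True)
class SubPhaseSpec:
    """One sub-phase: its bounding main-event indexes and intermediate count."""

    i: int
    label: str
    t_start: float
    t_end: float
    n: int

    def __post_init__(self) -> None:
        if self.label not in SUBPHASE_COUNTS:
            raise ValueError(f"unknown sub-phase {self.label!r}")
        if not self.t_start < self.t_end:
            raise ValueError("sub-phase bounds must satisfy t_start < t_end")
        if self.n < 1:
            raise ValueError("a sub-phase hosts at least one intermediate event")


@dataclasses.dataclass(frozen=True)
class EventEntry:
    m: int          # feature number 1..22
    label: str
    t: int          # % index on the 0..100 grid
    kind: str       # "main" | "intermediate"
    leg: str        # "stance" | "swing" (state of the study leg)


@dataclasses.dataclass
class EventSchedule:
    """The 22 ordered, unique gait-event indexes of one cycle."""

    entries: list[EventEntry]

    def validate(self) -> None:
        if len(self.entries) != 22:
            raise ValueError("schedule must contain exactly 22 events")
        ts = [e.t for e in self.entries]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("event indexes must be strictly increasing")
        if any(not 0 <= t <= 100 for t in ts):
            raise ValueError("event indexes must lie on the 0-100 grid")
        ms = [e.m for e in self.entries]
        if ms != list(range(1, 23)):
            raise ValueError("feature numbers must run 1..22 in order")
        mains = {e.m for e in self.entries if e.kind == "main"}
        if mains not in (set(MAIN_FEATURE_NUMBERS), set(MAIN_FEATURE_NUMBERS_SWING)):
            raise ValueError("main events must sit at the canonical feature numbers")

    @property
    def indexes(self) -> np.ndarray:
        return np.array([e.t for e in self.entries], dtype=int)

    def to_json(self) -> str:
        return json.dumps(
            {"format_version": 1,
             "entries": [dataclasses.asdict(e) for e in self.entries]},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventSchedule":
        data = json.loads(text)
        sched = cls(entries=[EventEntry(**e) for e in data["entries"]])
        sched.validate()
        return sched


def split_common_event(t_common: int) -> tuple[int, int]:
    """Split a shared event instant into (pre, post) = (t-1, t+1)."""
    if not 1 <= t_common <= 99:
        raise ValueError("common event at the grid boundary cannot be split")
    return t_common - 1, t_common + 1


def intermediate_step_size(spec: SubPhaseSpec) -> float:
    """Step b_i = (t_end - t_start) / (n + 1) between intermediate events."""
    return (spec.t_end - spec.t_start) / (spec.n + 1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def resolve_intermediate_events(spec: SubPhaseSpec) -> list[int]:
    """Indexes of the n intermediate events of one sub-phase.

    Each lands on the nearest integer grid point (round half up) to
    t_start + k*b, k = 1..n, which at 1 % resolution is always inside the
    +/-1 % buffer around the exact position.
    """
    b = intermediate_step_size(spec)
    return [_round_half_up(spec.t_start + k * b) for k in range(1, spec.n + 1)]


def resolve_main_events(
    cycle: GaitCycleRecord, predefined: dict[str, float] | None = None
) -> dict[str, int]:
    """Resolve the nine main-event indexes of a cycle.

    IC/ITO/NTO/NIC come from the cycle's measured event indexes; OTO, HR,
    OIC, FA, TV come from the predefined map, snapped to the integer grid
    (within their +/-1 % buffer). The transition common event (toe-off for
    an IC-start cycle, contact for an ITO-start cycle) is split by +/-1 %
    when its two roles coincide or are adjacent on the grid.
    """
    if predefined is None:
        predefined = (
            DEFAULT_PREDEFINED if cycle.start_label == "IC" else DEFAULT_PREDEFINED_SWING
        )
    missing = set(DEFAULT_PREDEFINED) - set(predefined)
    if missing:
        raise ValueError(f"predefined map lacks events: {sorted(missing)}")

    events: dict[str, int] = {}
    if cycle.start_label == "IC":
        events["IC"] = int(round(cycle.t_ic))
        events["NIC"] = int(round(cycle.t_nic))
        pre, post = _resolve_transition(cycle.t_ito, cycle.t_nto)
        events["ITO"], events["NTO"] = pre, post
    else:
        events["ITO"] = int(round(cycle.t_ito))
        events["NTO"] = int(round(cycle.t_nto))
        pre, post = _resolve_transition(cycle.t_ic, cycle.t_nic)
        events["NIC"], events["IC"] = pre, post
    for label in ("OTO", "HR", "OIC", "FA", "TV"):
        events[label] = int(round(predefined[label]))
    return events


def _resolve_transition(t_first: float, t_second: float) -> tuple[int, int]:
    a, b = int(round(t_first)), int(round(t_second))
    if b - a < 2:  # shared instant: split into pre/post neighbours
        return split_common_event(_round_half_up((t_first + t_second) / 2.0))
    return a, b


def dedupe_indexes(schedule: EventSchedule) -> EventSchedule:
    """Shift any repeated index +1 % (repeatedly) until all 22 are unique.

    Scans in ascending feature number; errors if a shift escapes the grid
    or breaks the strictly-increasing order.
    """
    used: set[int] = set()
    entries = []
    for e in schedule.entries:
        t = e.t
        while t in used:
            t += 1
            if t > 100:
                raise ValueError("dedup shift escaped the 0-100 grid")
        used.add(t)
        entries.append(dataclasses.replace(e, t=t))
    out = EventSchedule(entries=entries)
    out.validate()
    return out


def build_event_schedule(
    cycle: GaitCycleRecord, predefined: dict[str, float] | None = None
) -> EventSchedule:
    """Build the full 22-event schedule for one normalized cycle."""
    mains = resolve_main_events(cycle, predefined)
    layout = _LAYOUTS[cycle.start_label]
    transition_m = 11  # study leg changes state after feature 11

    entries: list[EventEntry] = []
    m = 1
    sub_i = 0
    for pos, item in enumerate(layout):
        if isinstance(item, str):
            leg = _leg_for(m, cycle.start_label, transition_m)
            entries.append(EventEntry(m=m, label=item, t=mains[item], kind="main", leg=leg))
            m += 1
        elif item is not None:
            sub_i += 1
            label, n = item
            start_label = layout[pos - 1]
            end_label = layout[pos + 1]
            spec = SubPhaseSpec(
                i=sub_i,
                label=label,
                t_start=mains[start_label],
                t_end=mains[end_label],
                n=n,
            )
            for j, t in enumerate(resolve_intermediate_events(spec), start=1):
                leg = _leg_for(m, cycle.start_label, transition_m)
                entries.append(
                    EventEntry(m=m, label=f"{label}{j}", t=t, kind="intermediate", leg=leg)
                )
                m += 1
    schedule = dedupe_indexes(EventSchedule(entries=entries))
    return schedule


def _leg_for(m: int, start_label: str, transition_m: int) -> str:
    first = "stance" if start_label == "IC" else "swing"
    second = "swing" if first == "stance" else "stance"
    return first if m <= transition_m else second


def extract_features(cycle: GaitCycleRecord, schedule: EventSchedule) -> np.ndarray:
    """The 22 vGRF features of one cycle.

    Stance-leg events read the study-leg signal f(t); swing-leg events read
    the opposite-leg signal and are negated: -f'(t).
    """
    feats = np.empty(22, dtype=float)
    for i, e in enumerate(schedule.entries):
        if not 0 <= e.t <= 100:
            raise ValueError("schedule index outside the phase grid")
        feats[i] = cycle.f[e.t] if e.leg == "stance" else -cycle.f_prime[e.t]
    return feats


def extract_targets(cycle: GaitCycleRecord, schedule: EventSchedule) -> np.ndarray:
    """The 66 targets: ankle, knee, hip angles at the 22 schedule indexes."""
    ts = schedule.indexes
    return np.concatenate([cycle.theta_a[ts], cycle.theta_k[ts], cycle.theta_h[ts]])


def assemble_matrices(
    pairs: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-cycle (features, targets) pairs into x (22 x n), y (66 x n)."""
    if not pairs:
        raise ValueError("no samples to assemble")
    for f, t in pairs:
        if f.shape != (22,) or t.shape != (66,):
            raise ValueError("expected 22-feature / 66-target vectors")
    x = np.column_stack([f for f, _ in pairs])
    y = np.column_stack([t for _, t in pairs])
    return x, y


def cycle_to_sample(
    cycle: GaitCycleRecord, predefined: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray, EventSchedule]:
    """Schedule + features + targets for one cycle in a single call."""
    schedule = build_event_schedule(cycle, predefined)
    return extract_features(cycle, schedule), extract_targets(cycle, schedule), schedule


# ---------------------------------------------------------------------------
# disk round-trip

def write_matrices(x: np.ndarray, y: np.ndarray, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(x).to_csv(outdir / "features.csv", index=False, float_format="%.17g")
    pd.DataFrame(y).to_csv(outdir / "targets.csv", index=False, float_format="%.17g")


def read_matrices(indir: str | Path) -> tuple[np.ndarray, np.ndarray]:
    indir = Path(indir)
    x = pd.read_csv(indir / "features.csv", float_precision="round_trip").to_numpy(dtype=float)
    y = pd.read_csv(indir / "targets.csv", float_precision="round_trip").to_numpy(dtype=float)
    return x, y
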