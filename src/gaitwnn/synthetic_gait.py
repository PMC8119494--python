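"""Synthetic gait cohort generator.

Produces paired kinetic/kinematic walking trials — ipsilateral and
contralateral vertical ground reaction force (vGRF, in body-weight units)
plus ankle/knee/hip sagittal angles (degrees) sampled at 100 Hz — with the
statistical structure the downstream estimator assumes:

* a double-bump ("M"-shaped) stance-phase vGRF that is exactly zero while
  the foot is in swing;
* an opposite-foot signal offset by half a gait cycle;
* smooth, periodic normative angle curves confined to normal-gait envelopes
  (dorsiflexion/flexion positive);
* subject-level latent variation (amplitude "vigor" and timing) that drives
  both the forces and the angles, so a learnable vGRF -> angle mapping
  exists by construction;
* optional trial-level jitter and measurement noise.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

FS_HZ = 100.0
JOINTS = ("ankle", "knee", "hip")

#: Normal-gait sagittal envelopes (degrees) the templates must respect.
ANGLE_LIMITS = {
    "ankle": (-24.779, 16.126),
    "knee": (-4.865, 72.396),
    "hip": (-24.104, 33.245),
}

# Anchor points (phase %, degrees) for the normative curves. Chosen with
# comfortable margin inside ANGLE_LIMITS so that Fourier truncation and
# subject-level shrink-only amplitude scaling cannot escape the envelope.
_ANGLE_ANCHORS = {
    "ankle": [(0, 0.0), (7, -5.5), (20, 2.5), (45, 9.5), (55, 4.0),
              (65, -15.0), (75, -4.0), (85, 2.0), (100, 0.0)],
    "knee": [(0, 5.0), (12, 16.0), (25, 10.0), (40, 5.0), (60, 32.0),
             (72, 58.0), (85, 28.0), (100, 5.0)],
    "hip": [(0, 27.0), (20, 14.0), (35, 2.0), (50, -11.0), (60, -7.0),
            (75, 14.0), (88, 26.0), (100, 27.0)],
}
_N_HARMONICS = 8


@dataclasses.dataclass(frozen=True)
class VgrfParams:
    """Closed-form parameters of the stance-phase vGRF waveform.

    Heights are in body-weight (BW) units, centers/widths in % of the gait
    cycle. Defaults place the loading-response peak near 13% and the
    push-off peak near 48%, with toe-off at 60% — the standard M shape.
    """

    peak1_height: float = 1.10
    peak1_center: float = 13.0
    peak1_width: float = 9.0
    peak2_height: float = 1.15
    peak2_center: float = 48.0
    peak2_width: float = 8.0
    toe_off_pct: float = 60.0
    ramp_pct: float = 6.0


@dataclasses.dataclass(frozen=True)
class SubjectProfile:
    """Latent per-subject gait parameters shared by forces and angles."""

    subject_id: str
    cadence_scale: float
    amplitude_scales: dict[str, float]
    event_offsets: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.amplitude_scales.values()):
            raise ValueError("amplitude_scales must be strictly positive")
        if any(abs(v) > 3.0 for v in self.event_offsets.values()):
            raise ValueError("event offsets limited to ±3% of the cycle")


@dataclasses.dataclass
class RawTrial:
    """One walking trial at 100 Hz: two force channels, three angles, events.

    ``vgrf_left`` is the instrumented (study) leg; events refer to it.
    Event times are sample indexes and strictly increasing in the order
    t_IC < t_ITO < t_NTO < t_NIC.
    """

    trial_id: str
    subject_id: str
    time: np.ndarray
    vgrf_left: np.ndarray
    vgrf_right: np.ndarray
    theta_a: np.ndarray
    theta_k: np.ndarray
    theta_h: np.ndarray
    t_ic: int
    t_ito: int
    t_nto: int
    t_nic: int

    def validate(self) -> None:
        n = self.time.size
        for name in ("vgrf_left", "vgrf_right", "theta_a", "theta_k", "theta_h"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length mismatch")
        events = (self.t_ic, self.t_ito, self.t_nto, self.t_nic)
        if not all(0 <= t < n for t in events):
            raise ValueError("event indexes outside the trial")
        if not (self.t_ic < self.t_ito < self.t_nto < self.t_nic):
            raise ValueError("event times must be strictly increasing")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _bump(phase: np.ndarray, height: float, center: float, width: float) -> np.ndarray:
    """Compact-support Gaussian bump: exact ``height`` at its center, zero
    beyond 3 widths (the tail is subtracted so support is genuinely compact)."""
    u = (phase - center) / width
    tail = np.exp(-4.5)
    core = (np.exp(-0.5 * u * u) - tail) / (1.0 - tail)
    return np.where(np.abs(u) < 3.0, height * core, 0.0)


def vgrf_waveform(phase, params: VgrfParams | None = None) -> np.ndarray | float:
    """Stance-phase vGRF (BW units) at ``phase`` % of the gait cycle.

    Two compact bumps windowed by smoothstep ramps: exactly 0 at contact
    onset (phase 0) and for any phase at or beyond toe-off; continuous
    everywhere.
    """
    params = params or VgrfParams()
    p = np.asarray(phase, dtype=float)
    if np.any((p < 0.0) | (p > 100.0)):
        raise ValueError("phase must lie in [0, 100] % of the gait cycle")
    window = _smoothstep(p / params.ramp_pct) * _smoothstep(
        (params.toe_off_pct - p) / params.ramp_pct
    )
    shape = (
        _bump(p, params.peak1_height, params.peak1_center, params.peak1_width)
        + _bump(p, params.peak2_height, params.peak2_center, params.peak2_width)
    )
    out = window * shape
    return out if out.ndim else float(out)


def _fourier_coeffs(joint: str) -> np.ndarray:
    anchors = _ANGLE_ANCHORS[joint]
    px = np.array([a[0] for a in anchors], dtype=float)
    py = np.array([a[1] for a in anchors], dtype=float)
    spline = CubicSpline(px, py, bc_type="periodic")
    grid = np.arange(0.0, 100.0, 0.5)
    coeffs = np.fft.rfft(spline(grid)) / grid.size
    return coeffs[: _N_HARMONICS + 1]


_COEFF_CACHE: dict[str, np.ndarray] = {}


def normative_angle_template(joint: str, phase) -> np.ndarray | float:
    """Normative sagittal angle (degrees) for ``joint`` at ``phase`` %.

    A low-order Fourier series (8 harmonics) fitted to a periodic spline
    through normative anchor points; smooth, periodic, and confined to the
    joint's normal-gait envelope.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    p = np.asarray(phase, dtype=float)
    if np.any((p < 0.0) | (p > 100.0)):
        raise ValueError("phase must lie in [0, 100] % of the gait cycle")
    if joint not in _COEFF_CACHE:
        _COEFF_CACHE[joint] = _fourier_coeffs(joint)
    c = _COEFF_CACHE[joint]
    k = np.arange(c.size)
    basis = np.exp(2j * np.pi * np.outer(p, k) / 100.0)
    # one-sided spectrum: double every harmonic except DC
    weights = np.where(k == 0, 1.0, 2.0)
    out = (basis @ (weights * c)).real
    return out if out.ndim else float(out)


def _template_mean(joint: str) -> float:
    if joint not in _COEFF_CACHE:
        _COEFF_CACHE[joint] = _fourier_coeffs(joint)
    return float(_COEFF_CACHE[joint][0].real)


def _draw_subject(idx: int, rng: np.random.Generator) -> SubjectProfile:
    amp = float(np.clip(rng.normal(1.0, 0.04), 0.88, 1.12))
    timing = float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0))
    cadence = float(np.clip(rng.normal(1.0, 0.03), 0.92, 1.08))
    # Angle amplitude shrink factors are monotone in the force "vigor"
    # latent, so the vGRF -> angle mapping is invertible within the cohort.
    rel = (amp - 0.88) / 0.24  # 0..1
    amp_scales = {
        "vgrf": amp,
        "ankle": 0.90 + 0.10 * rel,
        "knee": 0.88 + 0.12 * rel,
        "hip": 0.92 + 0.08 * rel,
    }
    offsets = {"toe_off": float(np.clip(0.75 * timing, -3.0, 3.0)),
               "angle_shift": float(np.clip(0.8 * timing, -3.0, 3.0))}
    return SubjectProfile(
        subject_id=f"S{idx:03d}",
        cadence_scale=cadence,
        amplitude_scales=amp_scales,
        event_offsets=offsets,
    )


def _synthesize_trial(
    profile: SubjectProfile,
    trial_idx: int,
    rng: np.random.Generator,
    noise_sd: float,
    trial_jitter: bool,
    params: VgrfParams,
    angle_noise_ratio: float,
) -> RawTrial:
    if trial_jitter:
        amp_t = profile.amplitude_scales["vgrf"] * (1.0 + rng.normal(0.0, 0.01))
        toe_jit = float(np.clip(rng.normal(0.0, 0.3), -1.0, 1.0))
        cad_t = profile.cadence_scale * (1.0 + rng.normal(0.0, 0.01))
    else:
        amp_t = profile.amplitude_scales["vgrf"]
        toe_jit = 0.0
        cad_t = profile.cadence_scale

    toe_off = params.toe_off_pct + profile.event_offsets["toe_off"] + toe_jit
    trial_params = dataclasses.replace(
        params,
        peak1_height=params.peak1_height * amp_t,
        peak2_height=params.peak2_height * amp_t,
        toe_off_pct=toe_off,
    )

    cycle_samples = int(round(105 * cad_t))
    margin = 10
    n = margin + cycle_samples + margin + 1
    idx = np.arange(n)
    t_ic = margin
    t_nic = margin + cycle_samples
    phase = ((idx - t_ic) / cycle_samples * 100.0) % 100.0

    vgrf_left = vgrf_waveform(phase, trial_params)
    vgrf_right = vgrf_waveform((phase + 50.0) % 100.0, trial_params)

    shift = profile.event_offsets["angle_shift"]
    angles = {}
    for joint in JOINTS:
        base = normative_angle_template(joint, (phase - shift) % 100.0)
        mean = _template_mean(joint)
        s = profile.amplitude_scales[joint]
        angles[joint] = mean + s * (base - mean)

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        for key, arr in (("left", vgrf_left), ("right", vgrf_right)):
            stance = arr > 0
            noisy = arr + np.where(stance, rng.normal(0.0, noise_sd, n), 0.0)
            noisy[stance] = np.maximum(noisy[stance], 1e-6)
            if key == "left":
                vgrf_left = noisy
            else:
                vgrf_right = noisy
        for joint in JOINTS:
            angles[joint] = angles[joint] + rng.normal(
                0.0, noise_sd * angle_noise_ratio, n
            )

    toe_sample = t_ic + int(round(toe_off / 100.0 * cycle_samples))
    trial = RawTrial(
        trial_id=f"{profile.subject_id}_T{trial_idx:02d}",
        subject_id=profile.subject_id,
        time=idx / FS_HZ,
        vgrf_left=vgrf_left,
        vgrf_right=vgrf_right,
        theta_a=angles["ankle"],
        theta_k=angles["knee"],
        theta_h=angles["hip"],
        t_ic=t_ic,
        t_ito=toe_sample,
        t_nto=toe_sample + 1,
        t_nic=t_nic,
    )
    trial.validate()
    return trial


def generate_cohort(
    n_subjects: int = 30,
    trials_per_subject: int = 10,
    seed: int = 0,
    noise_sd: float = 0.02,
    trial_jitter: bool = True,
    params: VgrfParams | None = None,
    angle_noise_ratio: float = 25.0,
) -> list[RawTrial]:
    """Generate ``n_subjects x trials_per_subject`` walking trials.

    ``noise_sd`` is the vGRF measurement-noise SD in BW units, applied to
    stance samples only (swing stays exactly zero); angle noise is
    ``noise_sd * angle_noise_ratio`` degrees. ``trial_jitter=False`` makes
    all trials of a subject identical when ``noise_sd == 0``.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ValueError("need at least one subject and one trial")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    params = params or VgrfParams()
    rng = np.random.default_rng(seed)
    trials: list[RawTrial] = []
    for s in range(n_subjects):
        profile = _draw_subject(s, rng)
        for t in range(trials_per_subject):
            trials.append(
                _synthesize_trial(
                    profile, t, rng, noise_sd, trial_jitter, params,
                    angle_noise_ratio,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# cohort disk format: one CSV per trial + a JSON sidecar

_CSV_COLUMNS = ["time", "vgrf_left", "vgrf_right", "theta_a", "theta_k", "theta_h"]


def write_cohort(trials: list[RawTrial], outdir: str | Path, meta: dict | None = None) -> None:
    """Write a cohort as per-trial CSVs plus ``cohort.json`` (events, meta)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar = {"format_version": 1, "meta": meta or {}, "trials": []}
    for trial in trials:
        fname = f"{trial.trial_id}.csv"
        df = pd.DataFrame(
            {c: getattr(trial, c if c != "time" else "time") for c in _CSV_COLUMNS}
        )
        df.to_csv(outdir / fname, index=False, float_format="%.10g")
        sidecar["trials"].append(
            {
                "trial_id": trial.trial_id,
                "subject_id": trial.subject_id,
                "file": fname,
                "events": {
                    "t_IC": trial.t_ic,
                    "t_ITO": trial.t_ito,
                    "t_NTO": trial.t_nto,
                    "t_NIC": trial.t_nic,
                },
            }
        )
    (outdir / "cohort.json").write_text(json.dumps(sidecar, indent=1))


def read_cohort(indir: str | Path) -> list[RawTrial]:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    sidecar = json.loads((indir / "cohort.json").read_text())
    trials = []
    for entry in sidecar["trials"]:
        df = pd.read_csv(indir / entry["file"])
        ev = entry["events"]
        trial = RawTrial(
            trial_id=entry["trial_id"],
            subject_id=entry["subject_id"],
            time=df["time"].to_numpy(),
            vgrf_left=df["vgrf_left"].to_numpy(),
            vgrf_right=df["vgrf_right"].to_numpy(),
            theta_a=df["theta_a"].to_numpy(),
            theta_k=df["theta_k"].to_numpy(),
            theta_h=df["theta_h"].to_numpy(),
            t_ic=int(ev["t_IC"]),
            t_ito=int(ev["t_ITO"]),
            t_nto=int(ev["t_NTO"]),
            t_nic=int(ev["t_NIC"]),
        )
        trial.validate()
        trials.append(trial)
    return trials
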