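"""Raw-trial preprocessing: low-pass filtering, single-cycle partitioning,
and normalization of each cycle onto the 0-100 % phase grid.

The phase grid is fixed at 1 % resolution (101 points, 0..100 inclusive) so
that gait-event indexes can be quoted as integer percentages.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .synthetic_gait import FS_HZ, RawTrial

PHASE_GRID = np.arange(101, dtype=float)

#: Partitioning modes: cycle boundaries (start event, end event).
CYCLE_MODES = {
    "IC_to_NIC": ("t_ic", "t_nic"),
    "ITO_to_NTO": ("t_ito", "t_nto"),
}


@dataclasses.dataclass
class GaitCycleRecord:
    """One gait cycle normalized to the 101-point phase grid.

    ``f`` is the study-leg vGRF, ``f_prime`` the opposite leg, both in
    body-weight units; angles in degrees. Event indexes are in % of the
    cycle. ``start_label`` records which event opens the cycle ("IC" for a
    stance-initiated cycle, "ITO" for a swing-initiated one).
    """

    f: np.ndarray
    f_prime: np.ndarray
    theta_a: np.ndarray
    theta_k: np.ndarray
    theta_h: np.ndarray
    t_ic: float
    t_ito: float
    t_nto: float
    t_nic: float
    start_label: str = "IC"
    trial_id: str = ""

    phase_grid: np.ndarray = dataclasses.field(
        default_factory=lambda: PHASE_GRID.copy()
    )

    def validate(self) -> None:
        for name in ("f", "f_prime", "theta_a", "theta_k", "theta_h"):
            if getattr(self, name).size != 101:
                raise ValueError(f"channel {name} must have 101 points")
        events = (self.t_ic, self.t_ito, self.t_nto, self.t_nic)
        if not all(0.0 <= t <= 100.0 for t in events):
            raise ValueError("event indexes must lie in [0, 100] %")
        if self.start_label == "IC":
            if not (self.t_ic < self.t_ito <= self.t_nto < self.t_nic):
                raise ValueError("expected t_IC < t_ITO <= t_NTO < t_NIC")
        elif self.start_label == "ITO":
            if not (self.t_ito < self.t_ic <= self.t_nic < self.t_nto):
                raise ValueError("expected t_ITO < t_IC <= t_NIC < t_NTO")
        else:
            raise ValueError(f"unknown start_label {self.start_label!r}")


def butterworth_lowpass(
    x: np.ndarray,
    cutoff_hz: float,
    fs_hz: float = FS_HZ,
    zero_phase: bool = True,
) -> np.ndarray:
    """First-order Butterworth low-pass filter.

    ``zero_phase=True`` (default) applies the filter forward and backward
    (``filtfilt``) so event timings are not shifted; note the magnitude
    response is then squared, so attenuation at the cutoff is -6 dB instead
    of the single-pass -3 dB.
    """
    nyquist = fs_hz / 2.0
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    b, a = sps.butter(1, cutoff_hz, btype="low", fs=fs_hz)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return sps.filtfilt(b, a, x)
    return sps.lfilter(b, a, x)


def estimate_cutoff_fft(
    x: np.ndarray, fraction: float = 0.99, fs_hz: float = FS_HZ
) -> float:
    """Cutoff frequency from the FFT power spectrum: the lowest frequency
    whose cumulative power (DC excluded) reaches ``fraction`` of the total.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for a usable spectrum")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    power = spectrum[1:]  # cutoff concerns signal dynamics, not the mean
    total = power.sum()
    if total == 0.0:
        raise ValueError("signal has no spectral content above DC")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs_hz)[1:]
    cumulative = np.cumsum(power)
    idx = int(np.searchsorted(cumulative, fraction * total))
    idx = min(idx, freqs.size - 1)
    return float(freqs[idx])


def filter_trial(trial: RawTrial, cutoff_hz: float) -> RawTrial:
    """Zero-phase low-pass every channel of a trial at ``cutoff_hz``."""
    filtered = {
        name: butterworth_lowpass(getattr(trial, name), cutoff_hz)
        for name in ("vgrf_left", "vgrf_right", "theta_a", "theta_k", "theta_h")
    }
    return dataclasses.replace(trial, **filtered)


@dataclasses.dataclass
class CycleSlice:
    """Raw single-cycle slice between two boundary events (inclusive)."""

    time: np.ndarray
    vgrf_left: np.ndarray
    vgrf_right: np.ndarray
    theta_a: np.ndarray
    theta_k: np.ndarray
    theta_h: np.ndarray
    events: dict[str, int]  # sample offsets within the slice
    start_label: str
    trial_id: str = ""


def partition_cycle(trial: RawTrial, mode: str = "IC_to_NIC") -> CycleSlice:
    """Extract one gait cycle spanning the two boundary events of ``mode``."""
    if mode not in CYCLE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {list(CYCLE_MODES)}")
    start_attr, end_attr = CYCLE_MODES[mode]
    a = getattr(trial, start_attr)
    b = getattr(trial, end_attr)
    if a is None or b is None:
        raise ValueError(f"trial lacks events for mode {mode}")
    if a >= b:
        raise ValueError("degenerate cycle: boundary events must be distinct and ordered")
    sl = slice(a, b + 1)
    events = {}
    for label, attr in (("IC", "t_ic"), ("ITO", "t_ito"), ("NTO", "t_nto"), ("NIC", "t_nic")):
        t = getattr(trial, attr)
        if a <= t <= b:
            events[label] = t - a
    return CycleSlice(
        time=trial.time[sl],
        vgrf_left=trial.vgrf_left[sl],
        vgrf_right=trial.vgrf_right[sl],
        theta_a=trial.theta_a[sl],
        theta_k=trial.theta_k[sl],
        theta_h=trial.theta_h[sl],
        events=events,
        start_label="IC" if mode == "IC_to_NIC" else "ITO",
        trial_id=trial.trial_id,
    )


def normalize_cycle(cycle: CycleSlice) -> GaitCycleRecord:
    """Linearly resample every channel of a raw slice onto the 101-point
    phase grid and map event times to % indexes (boundaries -> 0 and 100)."""
    n = cycle.time.size
    if n < 2:
        raise ValueError("cycle slice needs at least 2 samples")
    if np.any(np.diff(cycle.time) <= 0):
        raise ValueError("time vector must be strictly increasing")
    pos = np.linspace(0.0, n - 1.0, 101)
    sample_idx = np.arange(n, dtype=float)

    def resample(ch: np.ndarray) -> np.ndarray:
        return np.interp(pos, sample_idx, ch)

    pct = {k: v / (n - 1) * 100.0 for k, v in cycle.events.items()}
    if cycle.start_label == "IC":
        # swing-initiated events absent from a stance cycle: toe-off plays
        # both ITO and NTO roles at the transition (split downstream)
        pct.setdefault("ITO", pct.get("NTO", 60.0))
        pct.setdefault("NTO", pct["ITO"])
    else:
        pct.setdefault("IC", pct.get("NIC", 40.0))
        pct.setdefault("NIC", pct["IC"])
    rec = GaitCycleRecord(
        f=resample(cycle.vgrf_left),
        f_prime=resample(cycle.vgrf_right),
        theta_a=resample(cycle.theta_a),
        theta_k=resample(cycle.theta_k),
        theta_h=resample(cycle.theta_h),
        t_ic=pct.get("IC", 0.0),
        t_ito=pct["ITO"],
        t_nto=pct["NTO"],
        t_nic=pct.get("NIC", 100.0),
        start_label=cycle.start_label,
        trial_id=cycle.trial_id,
    )
    rec.validate()
    return rec


def trial_to_cycle(
    trial: RawTrial,
    mode: str = "IC_to_NIC",
    cutoff_hz: float | None = None,
) -> GaitCycleRecord:
    """Convenience pipeline: (optional filter) -> partition -> normalize."""
    if cutoff_hz is not None:
        trial = filter_trial(trial, cutoff_hz)
    return normalize_cycle(partition_cycle(trial, mode))
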