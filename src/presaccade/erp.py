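"""Epoching, averaging and windowed ERP component measures.

Trials are stored as fixed-length epochs at 250 Hz in one of two alignments:

* **target-locked**, [-1100, +800] ms around target onset, baseline
  [-1100, -1000] ms (the 100 ms preceding the extracted pretarget second);
* **saccade-locked**, [-300, +100] ms around saccade onset, no baseline.

Three windowed component measures quantify the presaccadic ERP morphology:

* ``pretarget_neg_sw`` — mean level in the last 50 ms of the pretarget
  interval minus the mean in its first 50 ms (target-locked);
* ``presaccadic_pos_sw`` — mean level in [-50, -20] ms before the saccade;
* ``spike`` — mean in [-8, +8] ms minus mean in [-24, -16] ms.

Window means are computed as the time-average of the linearly interpolated
waveform over the closed window (trapezoidal rule).  For the piecewise-linear
signal the samples represent, this integral is exact, and it is well defined
whether or not a window endpoint coincides with a sample time.  A plain
sample-mean mode is available via ``mode="samples"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidSignalError, RereferenceError
from .montage import Montage

log = logging.getLogger(__name__)

DT_MS = 4.0
TARGET_WINDOW_MS = (-1100.0, 800.0)
SACCADE_WINDOW_MS = (-300.0, 100.0)
TARGET_BASELINE_MS = (-1100.0, -1000.0)

COMPONENT_WINDOWS = {
    "pretarget_neg_sw": {
        "alignment": "target",
        "main": (-50.0, 0.0),
        "baseline": (-1000.0, -950.0),
    },
    "presaccadic_pos_sw": {"alignment": "saccade", "main": (-50.0, -20.0), "baseline": None},
    "spike": {"alignment": "saccade", "main": (-8.0, 8.0), "baseline": (-24.0, -16.0)},
}


@dataclass
class EpochSet:
    """Trials x channels x samples (uV) with per-trial metadata."""

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    trials: pd.DataFrame
    alignment: str  # "raw" | "target" | "saccade"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != (len(self.trials), len(self.channels), self.times.size):
            raise ValueError("epoch data shape mismatch")
        steps = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(steps, DT_MS):
            raise ValueError("sample spacing must be exactly 4 ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, keep: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[keep],
            times=self.times,
            channels=list(self.channels),
            trials=self.trials.iloc[keep].reset_index(drop=True),
            alignment=self.alignment,
        )


@dataclass
class ERPWave:
    """Condition-averaged waveform, channels x samples (uV)."""

    condition: dict
    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    alignment: str
    n_trials: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.n_trials < 1:
            raise ValueError("an ERP must average at least one trial")


@dataclass
class ComponentMeasure:
    component: str
    scope: str
    condition: dict
    value_uv: float


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_saccade_onset(
    trace: np.ndarray,
    times: np.ndarray,
    threshold_uv: float,
    min_duration_ms: float = 12.0,
    baseline_ms: float = 100.0,
) -> float | None:
    """Earliest time at which |trace - baseline| reaches ``threshold_uv`` and
    stays there for at least ``min_duration_ms``.

    The baseline is the mean of the first ``baseline_ms`` of the trace.
    Returns None when the threshold is never sustained.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape:
        raise ValueError("trace and times must have matching shapes")
    if not np.all(np.isfinite(trace)):
        raise InvalidSignalError("EOG trace contains non-finite samples")
    base_mask = times <= times[0] + baseline_ms
    baseline = trace[base_mask].mean()
    above = np.abs(trace - baseline) >= threshold_uv
    need = max(1, int(np.ceil(min_duration_ms / DT_MS)))
    run = 0
    for i in range(above.size - 1, -1, -1):
        run = run + 1 if above[i] else 0
        above[i] = run >= need
    idx = np.flatnonzero(above)
    return float(times[idx[0]]) if idx.size else None


# ---------------------------------------------------------------------------
# Epoch extraction and conditioning
# ---------------------------------------------------------------------------

def _window_axis(window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return np.arange(lo, hi + DT_MS / 2, DT_MS)


def segment_epochs(raw: EpochSet, alignment: str, saccade_col: str = "rt_ms") -> EpochSet:
    """Cut fixed windows from target-locked raw records.

    Target-locked: [-1100, +800] ms.  Saccade-locked: [-300, +100] ms around
    the per-trial saccade onset; catch trials and trials whose window falls
    outside the record are dropped with a logged warning.
    """
    if raw.alignment != "raw":
        raise AlignmentError("segment_epochs expects raw target-locked records")
    if alignment == "target":
        out_times = _window_axis(TARGET_WINDOW_MS)
        i0 = int(round((out_times[0] - raw.times[0]) / DT_MS))
        if i0 < 0 or i0 + out_times.size > raw.times.size:
            raise AlignmentError("raw records do not cover the target-locked window")
        return EpochSet(
            data=raw.data[:, :, i0 : i0 + out_times.size].copy(),
            times=out_times,
            channels=list(raw.channels),
            trials=raw.trials.copy().reset_index(drop=True),
            alignment="target",
        )
    if alignment != "saccade":
        raise AlignmentError(f"unknown alignment {alignment!r}")
    out_times = _window_axis(SACCADE_WINDOW_MS)
    keep, slabs = [], []
    n_dropped = 0
    for i, row in raw.trials.iterrows():
        onset = row.get(saccade_col, np.nan)
        if row.get("movement") == "catch" or not np.isfinite(onset):
            continue
        onset = round(float(onset) / DT_MS) * DT_MS
        i0 = int(round((onset + SACCADE_WINDOW_MS[0] - raw.times[0]) / DT_MS))
        if i0 < 0 or i0 + out_times.size > raw.times.size:
            n_dropped += 1
            continue
        keep.append(i)
        slabs.append(raw.data[i, :, i0 : i0 + out_times.size])
    if n_dropped:
        log.warning("segment_epochs: dropped %d trials outside the record", n_dropped)
    return EpochSet(
        data=np.asarray(slabs) if slabs else np.empty((0, len(raw.channels), out_times.size)),
        times=out_times,
        channels=list(raw.channels),
        trials=raw.trials.iloc[keep].reset_index(drop=True),
        alignment="saccade",
    )


def reject_trials(epochs: EpochSet) -> EpochSet:
    """Drop error- and blink-flagged trials; log removal counts."""
    t = epochs.trials
    err = t["error"].to_numpy(bool) if "error" in t else np.zeros(len(t), bool)
    blink = t["blink"].to_numpy(bool) if "blink" in t else np.zeros(len(t), bool)
    bad = err | blink
    if bad.any():
        counts = t.loc[bad].groupby(["cue", "movement"], observed=True).size()
        log.info("reject_trials: removed %d trials\n%s", int(bad.sum()), counts)
    kept = epochs.subset(~bad)
    if kept.n_trials == 0:
        warnings.warn("reject_trials: no trials remain after rejection", stacklevel=2)
    return kept


def rereference_average(obj: EpochSet | ERPWave):
    """Algebraic average reference: subtract the channel mean at each sample."""
    if len(obj.channels) < 2:
        raise RereferenceError("average reference needs at least two channels")
    data = obj.data - obj.data.mean(axis=-2, keepdims=True)
    if isinstance(obj, EpochSet):
        return EpochSet(data, obj.times, list(obj.channels), obj.trials.copy(), obj.alignment)
    return ERPWave(dict(obj.condition), data, obj.times, list(obj.channels), obj.alignment, obj.n_trials)


def compute_erp(
    epochs: EpochSet,
    group_by: list[str] | None = None,
    baseline_window: tuple[float, float] | None | str = "auto",
) -> dict[tuple, ERPWave]:
    """Condition-averaged ERPs with per-trial baseline-mean subtraction.

    ``baseline_window="auto"`` uses [-1100, -1000] ms for target-locked
    epochs and no baseline for saccade-locked ones.  Empty condition cells
    are omitted with a warning.
    """
    if baseline_window == "auto":
        baseline_window = TARGET_BASELINE_MS if epochs.alignment == "target" else None
    data = epochs.data
    if baseline_window is not None:
        lo, hi = baseline_window
        if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
            raise ValueError("baseline window outside the epoch")
        sel = (epochs.times >= lo - 1e-9) & (epochs.times <= hi + 1e-9)
        data = data - data[:, :, sel].mean(axis=2, keepdims=True)

    out: dict[tuple, ERPWave] = {}
    if group_by:
        grouped = epochs.trials.groupby(group_by, observed=True).indices
        items = sorted(grouped.items(), key=lambda kv: str(kv[0]))
    else:
        items = [((), np.arange(epochs.n_trials))]
    for key, idx in items:
        key = key if isinstance(key, tuple) else (key,)
        if len(idx) == 0:
            warnings.warn(f"compute_erp: empty condition cell {key}", stacklevel=2)
            continue
        cond = dict(zip(group_by or [], key))
        out[key] = ERPWave(
            condition=cond,
            data=data[idx].mean(axis=0),
            times=epochs.times,
            channels=list(epochs.channels),
            alignment=epochs.alignment,
            n_trials=len(idx),
        )
    if not out:
        warnings.warn("compute_erp: no condition produced an ERP", stacklevel=2)
    return out


def flip_lateral(obj: EpochSet | ERPWave, montage: Montage, side: str | None = None):
    """Swap left/right mirror-paired channels for left-directed trials.

    After flipping, the eye movement is "toward the right" on every trial,
    so e.g. Parietal3 is contralateral and Parietal4 ipsilateral.  Midline
    channels are fixed points; flipping twice is the identity.
    """
    perm = np.array([obj.channels.index(montage.mirror_partner(ch)) for ch in obj.channels])
    if isinstance(obj, ERPWave):
        flip_this = (side or obj.condition.get("side")) == "left"
        data = obj.data[perm] if flip_this else obj.data.copy()
        return ERPWave(dict(obj.condition), data, obj.times, list(obj.channels), obj.alignment, obj.n_trials)
    sides = obj.trials["side"].to_numpy() if side is None else np.full(obj.n_trials, side)
    data = obj.data.copy()
    left = np.asarray(sides == "left")
    data[left] = data[left][:, perm, :]
    return EpochSet(data, obj.times, list(obj.channels), obj.trials.copy(), obj.alignment)


# ---------------------------------------------------------------------------
# Windowed measures
# ---------------------------------------------------------------------------

def window_mean(
    data: np.ndarray, times: np.ndarray, window: tuple[float, float], mode: str = "integral"
) -> np.ndarray:
    """Mean of ``data`` (..., n_samples) over a closed time window.

    ``integral`` (default): time-average of the linear interpolant
    (trapezoidal rule) — exact for piecewise-linear signals and well defined
    for off-grid endpoints.  ``samples``: plain mean of in-window samples.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must have positive length")
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] outside epoch [{times[0]}, {times[-1]}]")
    if mode == "samples":
        sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
        return data[..., sel].mean(axis=-1)
    if mode != "integral":
        raise ValueError(f"unknown window mode {mode!r}")
    inner = np.flatnonzero((times > lo + 1e-9) & (times < hi - 1e-9))
    grid = np.concatenate(([lo], times[inner], [hi]))
    vals = np.concatenate(
        (
            _interp_at(data, times, lo)[..., None],
            data[..., inner],
            _interp_at(data, times, hi)[..., None],
        ),
        axis=-1,
    )
    return np.trapezoid(vals, grid, axis=-1) / (hi - lo)


def _interp_at(data: np.ndarray, times: np.ndarray, t: float) -> np.ndarray:
    i = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0, times.size - 2))
    w = (t - times[i]) / (times[i + 1] - times[i])
    return (1.0 - w) * data[..., i] + w * data[..., i + 1]


def component_values(erp: ERPWave, component: str, mode: str = "integral") -> np.ndarray:
    """Per-channel component measure (uV) for one ERP."""
    if component not in COMPONENT_WINDOWS:
        raise KeyError(f"unknown component {component!r}")
    spec = COMPONENT_WINDOWS[component]
    if erp.alignment != spec["alignment"]:
        raise AlignmentError(
            f"{component} requires {spec['alignment']}-locked data, got {erp.alignment}"
        )
    val = window_mean(erp.data, erp.times, spec["main"], mode=mode)
    if spec["baseline"] is not None:
        val = val - window_mean(erp.data, erp.times, spec["baseline"], mode=mode)
    return val


def measure_component(
    erp: ERPWave,
    component: str,
    scope: str,
    montage: Montage | None = None,
    mode: str = "integral",
) -> ComponentMeasure:
    """Component measure over a virtual-electrode group or single channel."""
    vals = component_values(erp, component, mode=mode)
    if scope in erp.channels:
        value = float(vals[erp.channels.index(scope)])
    else:
        if montage is None:
            raise ValueError("a montage is required for group scopes")
        members = montage.group_channels(scope)
        idx = [erp.channels.index(ch) for ch in members]
        value = float(vals[idx].mean())
    return ComponentMeasure(component, scope, dict(erp.condition), value)


def virtual_group_values(erp: ERPWave, montage: Montage, group: str):
    """Member-channel waveforms of a virtual group, plus their mean.

    Returns ``(channel_names, member_data, mean_waveform)``; member data is
    (n_members, n_samples).
    """
    members = montage.group_channels(group)
    idx = [erp.channels.index(ch) for ch in members]
    member_data = erp.data[idx]
    return members, member_data, member_data.mean(axis=0)


def component_table(
    erps: dict[tuple, ERPWave],
    montage: Montage,
    groups: dict[str, list[str]] | None = None,
    mode: str = "integral",
) -> pd.DataFrame:
    """Tidy table of component measures per condition, group and channel."""
    rows = []
    for erp in erps.values():
        for component, spec in COMPONENT_WINDOWS.items():
            if erp.alignment != spec["alignment"]:
                continue
            vals = component_values(erp, component, mode=mode)
            use_groups = groups or montage.virtual_groups
            for group, members in use_groups.items():
                idx = [erp.channels.index(ch) for ch in members]
                base = {**erp.condition, "component": component, "n_trials": erp.n_trials}
                rows.append({**base, "scope": group, "value_uv": float(vals[idx].mean())})
                rows.extend(
                    {**base, "scope": ch, "value_uv": float(vals[j])}
                    for ch, j in zip(members, idx)
                )
    return pd.DataFrame(rows)
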