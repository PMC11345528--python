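"""Kinematic event detection and EMG feature extraction.

Position traces are wrist-handle positions in quadrature-encoder units;
movement onset is the first sample exceeding a 2-unit excursion from the
start position and offset the first sample after the peak excursion back
within 2 units.  EMG traces are full-wave rectified, smoothed with a short
moving average, and summarised by the mean of the ten largest samples in a
padded movement window minus the mean of a 1000-ms pre-stimulus baseline
taken from the instruction phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientSamplesError,
    NoMovementError,
    NoReturnError,
    ResampleRequiredError,
    WindowError,
)
from .simulate import BASELINE_WINDOW_MS


@dataclass
class Trace:
    """A time-indexed 1-D signal with named event markers.

    ``t`` is in ms (strictly increasing), ``v`` in encoder units (position)
    or a.u. (EMG).  Events typically include ``instruction_onset``, ``go``
    and ``stim``.
    """

    t: np.ndarray
    v: np.ndarray
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing with >= 2 samples")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.t)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9))


@dataclass(frozen=True)
class EMGFeature:
    participant_id: str
    movement: str
    cue: str
    peak_value: float
    baseline_value: float

    @property
    def difference(self) -> float:
        return self.peak_value - self.baseline_value


def _start_position(trace: Trace) -> float:
    go = trace.events.get("go", trace.t[0])
    return float(np.interp(go, trace.t, trace.v))


def detect_onset(trace: Trace, threshold_units: float = 2.0) -> float:
    """Time (ms) of the first sample exceeding the excursion threshold.

    The start position is the handle position at the go event; samples
    before go are ignored.  The crossing is strict (> threshold).
    """
    start = _start_position(trace)
    go = trace.events.get("go", trace.t[0])
    mask = trace.t >= go
    exc = np.abs(trace.v[mask] - start)
    idx = np.nonzero(exc > threshold_units)[0]
    if idx.size == 0:
        raise NoMovementError("position never exceeds the movement threshold")
    return float(trace.t[mask][idx[0]])


def detect_offset(
    trace: Trace, threshold_units: float = 2.0, onset: float | None = None
) -> float:
    """Time (ms) of the first post-peak sample back within the threshold.

    The peak is the maximum absolute excursion after onset; the return
    test is non-strict (<= threshold).
    """
    if onset is None:
        onset = detect_onset(trace, threshold_units)
    start = _start_position(trace)
    sel = trace.t >= onset
    t = trace.t[sel]
    exc = np.abs(trace.v[sel] - start)
    peak = int(np.argmax(exc))
    back = np.nonzero(exc[peak:] <= threshold_units)[0]
    if back.size == 0:
        raise NoReturnError("position never returns within the threshold")
    return float(t[peak + back[0]])


def movement_duration(trace: Trace, threshold_units: float = 2.0) -> float:
    onset = detect_onset(trace, threshold_units)
    return detect_offset(trace, threshold_units, onset=onset) - onset


def preprocess_emg(trace: Trace, smooth_window_ms: float = 50.0) -> Trace:
    """Full-wave rectification followed by a centred moving average.

    Edge samples use truncated windows so the output has the same length
    as the input.  Requires uniform sampling.
    """
    if not trace.is_uniform():
        raise ResampleRequiredError("EMG preprocessing requires uniform sampling")
    w = max(1, int(round(smooth_window_ms / trace.dt)))
    rect = pd.Series(np.abs(trace.v))
    smooth = rect.rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    return Trace(t=trace.t.copy(), v=smooth, events=dict(trace.events))


def emg_feature(
    trace: Trace,
    onset: float,
    offset: float,
    k_largest: int = 10,
    pad_ms: float = 500.0,
    baseline_ms: float = 1000.0,
    participant_id: str = "",
    movement: str = "",
    cue: str = "",
) -> EMGFeature:
    """Peak-minus-baseline EMG feature for one (already preprocessed) trial.

    Peak = mean of the ``k_largest`` largest samples between ``onset -
    pad_ms`` and ``offset + pad_ms``; baseline = mean of the last
    ``baseline_ms`` of the instruction phase.  Adding a constant to the
    whole trace leaves the difference unchanged.
    """
    t, v = trace.t, trace.v
    lo, hi = onset - pad_ms, offset + pad_ms
    if lo < t[0] or hi > t[-1]:
        raise WindowError(
            f"movement window [{lo}, {hi}] ms exceeds trace extent [{t[0]}, {t[-1]}]"
        )
    instr = trace.events.get("instruction_onset", t[0])
    b_lo, b_hi = instr, instr + baseline_ms
    if b_lo < t[0] or b_hi > t[-1]:
        raise WindowError("baseline window exceeds trace extent")
    win = v[(t >= lo) & (t <= hi)]
    if win.size < k_largest:
        raise InsufficientSamplesError(
            f"movement window holds {win.size} samples, need >= {k_largest}"
        )
    peak = float(np.sort(win)[-k_largest:].mean())
    base = float(v[(t >= b_lo) & (t <= b_hi)].mean())
    return EMGFeature(
        participant_id=participant_id,
        movement=movement,
        cue=cue,
        peak_value=peak,
        baseline_value=base,
    )


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------


def traces_from_long(
    long_df: pd.DataFrame, kind: str, events: dict | None = None
) -> dict[int, Trace]:
    """Split a long-format trace table (trial_id, t_ms, value) into Traces."""
    ev = {"instruction_onset": -2500.0, "go": 0.0} if events is None else events
    sub = long_df[long_df["kind"] == kind] if "kind" in long_df.columns else long_df
    out = {}
    for tid, grp in sub.groupby("trial_id"):
        grp = grp.sort_values("t_ms")
        out[int(tid)] = Trace(grp["t_ms"].to_numpy(), grp["value"].to_numpy(), dict(ev))
    return out


def kinematic_summary(
    traces: dict[int, Trace], threshold_units: float = 2.0
) -> pd.DataFrame:
    """Per-trial onset/offset/duration from position traces.

    Trials with no detectable movement or return are reported with NaNs and
    a reason, mirroring the behaviour of the trial-exclusion step.
    """
    rows = []
    for tid, tr in traces.items():
        row = {"trial_id": tid, "onset_ms": np.nan, "offset_ms": np.nan,
               "duration_ms": np.nan, "reason": ""}
        try:
            onset = detect_onset(tr, threshold_units)
            offset = detect_offset(tr, threshold_units, onset=onset)
            row.update(onset_ms=onset, offset_ms=offset, duration_ms=offset - onset)
        except NoMovementError:
            row["reason"] = "no_movement"
        except NoReturnError:
            row["reason"] = "no_return"
        rows.append(row)
    return pd.DataFrame(rows)


def emg_feature_table(
    emg_traces: dict[int, Trace],
    trials: pd.DataFrame,
    smooth_window_ms: float = 50.0,
    **feature_kwargs,
) -> pd.DataFrame:
    """EMG features for every trial with a trace, joined with condition labels.

    Baseline (no-movement) trials use the nominal movement window; movement
    trials use their recorded kinematic onset/offset.
    """
    meta = trials.set_index("trial_id")
    rows = []
    for tid, raw in emg_traces.items():
        tr = preprocess_emg(raw, smooth_window_ms)
        m = meta.loc[tid]
        onset, offset = m["movement_onset_rel_go"], m["movement_offset_rel_go"]
        if m["movement"] == "baseline" or not np.isfinite(onset):
            onset, offset = BASELINE_WINDOW_MS
        feat = emg_feature(
            tr, float(onset), float(offset),
            participant_id=str(m["participant_id"]),
            movement=str(m["movement"]), cue=str(m["session_cue"]),
            **feature_kwargs,
        )
        rows.append(
            {
                "trial_id": tid,
                "participant_id": feat.participant_id,
                "movement": feat.movement,
                "session_cue": feat.cue,
                "peak_value": feat.peak_value,
                "baseline_value": feat.baseline_value,
                "emg_difference": feat.difference,
            }
        )
    return pd.DataFrame(rows)


def mean_emg_differences(features: pd.DataFrame) -> pd.DataFrame:
    """Participant x movement x cue mean EMG difference (the LMM response)."""
    return (
        features.groupby(
            ["participant_id", "movement", "session_cue"],
            as_index=False,
            observed=True,
        )["emg_difference"]
        .mean()
    )
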