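"""Generative model of a movement-locked tactile detection experiment.

The simulator reproduces the structure of a wrist-movement tactile
suppression study: three movement conditions (resting baseline, active
wrist movement, device-driven passive movement) crossed with two cue
sessions (upcoming condition announced, ``cue+``, or not, ``cue-``).  On
half of the trials a brief vibrotactile probe of one of 11 amplitudes is
delivered shortly before movement onset; the other half are catch (noise)
trials.  Probe timing uses the online adaptive rule of the experiment: the
planned stimulation time is the mean of the previous five movement onsets
minus a fixed lead, and passive-trial probes are drawn from the empirical
distribution of the participant's active movement onsets.

Detection behaviour follows an equal-variance Gaussian signal-detection
observer with a linear transducer: on a signal trial with amplitude ``a``
the probability of a "yes" is

    p = guess + (1 - guess - lapse) * Phi(gain * a - criterion)

so the generating sensitivity at amplitude ``a`` is exactly ``d' = gain*a``
and the generating criterion is ``c = criterion - gain*a/2``, which makes
the estimands of the downstream signal-detection pipeline analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import InsufficientHistoryError, InvalidDesignError

MOVEMENTS = ("baseline", "active", "passive")
CUES = ("cue-", "cue+")

# Trial timeline (ms relative to the go signal = end of the countdown).
INSTRUCTION_MS = 1000.0
COUNTDOWN_MS = 1500.0  # 3 x 500 ms
MOVEMENT_WINDOW_MS = 2500.0
RESPONSE_WINDOW_MS = 2000.0
ITI_MS = 750.0
DEFAULT_LEAD_MS = 75.0
# Nominal "movement" window used for EMG extraction on baseline (no-movement)
# trials, where no kinematic onset/offset exists.
BASELINE_WINDOW_MS = (500.0, 1500.0)

TRIAL_COLUMNS = [
    "trial_id",
    "participant_id",
    "session_cue",
    "block",
    "movement",
    "stimulus_present",
    "amplitude_mm",
    "stim_time_rel_go",
    "movement_onset_rel_go",
    "movement_offset_rel_go",
    "stim_time_rel_onset",
    "response",
    "valid",
    "exclusion_reason",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmplitudeGrid:
    """Ordered set of peak-to-peak probe displacements (mm).

    The default grid has 11 equally spaced levels with step 0.139/11 mm
    (~0.0126 mm, top level 0.139 mm).  The step is calibrated so that the
    canonical 5-bin grouping (2, 2, 3, 2, 2 consecutive levels) has bin
    mean amplitudes of 0.019, 0.044, 0.076, 0.107 and 0.133 mm at three
    decimals; no equally spaced grid ending exactly at 0.140 mm achieves
    all five of those means.  A literal 0.013-mm-step grid and a grid with
    top level exactly 0.140 mm are available as alternative constructors.
    """

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.ndim != 1 or lv.size == 0:
            raise InvalidDesignError("amplitude grid must be a non-empty 1-D sequence")
        if np.any(lv <= 0):
            raise InvalidDesignError("amplitudes must all be positive")
        if np.any(np.diff(lv) <= 0):
            raise InvalidDesignError("amplitudes must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def default(cls) -> "AmplitudeGrid":
        step = 0.139 / 11.0
        return cls(tuple(step * k for k in range(1, 12)))

    @classmethod
    def literal_step(cls, step: float = 0.013, n_levels: int = 11) -> "AmplitudeGrid":
        return cls(tuple(step * k for k in range(1, n_levels + 1)))

    @classmethod
    def max_140(cls) -> "AmplitudeGrid":
        step = 0.140 / 11.0
        return cls(tuple(step * k for k in range(1, 12)))


@dataclass(frozen=True)
class DesignSpec:
    """Counts and factor levels of the experimental design.

    With the defaults every movement x cue cell holds
    ``n_levels * reps_per_amplitude = 66`` signal trials plus an equal
    number of catch trials, i.e. 132 trials per condition.
    """

    grid: AmplitudeGrid = field(default_factory=AmplitudeGrid.default)
    movements: tuple[str, ...] = MOVEMENTS
    cues: tuple[str, ...] = CUES
    reps_per_amplitude: int = 6
    catch_ratio: float = 0.5
    n_blocks: int = 2

    def __post_init__(self) -> None:
        if self.reps_per_amplitude < 1 or self.n_blocks < 1:
            raise InvalidDesignError("counts must be positive")
        if not 0.0 < self.catch_ratio < 1.0:
            raise InvalidDesignError("catch_ratio must lie in (0, 1)")
        if not set(self.movements) <= set(MOVEMENTS):
            raise InvalidDesignError(f"movements must be a subset of {MOVEMENTS}")
        if not set(self.cues) <= set(CUES):
            raise InvalidDesignError(f"cues must be a subset of {CUES}")

    @property
    def n_signal_per_condition(self) -> int:
        return self.grid.n_levels * self.reps_per_amplitude

    @property
    def n_catch_per_condition(self) -> int:
        n = self.n_signal_per_condition * self.catch_ratio / (1.0 - self.catch_ratio)
        if abs(n - round(n)) > 1e-9:
            raise InvalidDesignError(
                "catch_ratio does not yield an integer number of catch trials"
            )
        return int(round(n))

    @property
    def trials_per_condition(self) -> int:
        return self.n_signal_per_condition + self.n_catch_per_condition


def build_design(spec: DesignSpec, n_participants: int, seed: int) -> pd.DataFrame:
    """Build the full randomized trial schedule for a cohort.

    Per participant and cue session, each movement condition contributes
    ``n_signal + n_catch`` trials; signal repetitions and catch trials are
    balanced across blocks and the order is shuffled within block.  The
    same seed always yields the same schedule.
    """
    if n_participants < 1:
        raise InvalidDesignError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.asarray(spec.grid.levels)
    nl, reps, nb = spec.grid.n_levels, spec.reps_per_amplitude, spec.n_blocks
    n_catch = spec.n_catch_per_condition

    # session template: identical trial multiset for every participant/cue
    mov_t, stim_t, amp_t, blk_t = [], [], [], []
    for movement in spec.movements:
        mov_t.append(np.repeat(movement, nl * reps + n_catch))
        stim_t.append(np.concatenate([np.ones(nl * reps, bool), np.zeros(n_catch, bool)]))
        amp_t.append(np.concatenate([np.tile(levels, reps), np.full(n_catch, np.nan)]))
        blk_t.append(
            np.concatenate([np.repeat(np.arange(reps) % nb, nl), np.arange(n_catch) % nb])
        )
    mov_t = np.concatenate(mov_t)
    stim_t = np.concatenate(stim_t)
    amp_t = np.concatenate(amp_t)
    blk_t = np.concatenate(blk_t)
    n_session = len(mov_t)
    block_members = [np.nonzero(blk_t == b)[0] for b in range(nb)]

    pid_col, cue_col, order_col = [], [], []
    for p in range(n_participants):
        pid = f"p{p + 1:03d}"
        for cue in spec.cues:
            order = np.concatenate([idx[rng.permutation(len(idx))] for idx in block_members])
            order_col.append(order)
            pid_col.append(np.repeat(pid, n_session))
            cue_col.append(np.repeat(cue, n_session))
    order = np.concatenate(order_col)
    out = pd.DataFrame(
        {
            "participant_id": np.concatenate(pid_col),
            "session_cue": np.concatenate(cue_col),
            "block": blk_t[order],
            "movement": mov_t[order],
            "stimulus_present": stim_t[order],
            "amplitude_mm": amp_t[order],
        }
    )
    out["trial_in_block"] = out.groupby(
        ["participant_id", "session_cue", "block"]
    ).cumcount()
    return out[
        [
            "participant_id",
            "session_cue",
            "block",
            "trial_in_block",
            "movement",
            "stimulus_present",
            "amplitude_mm",
        ]
    ]


# ---------------------------------------------------------------------------
# observer
# ---------------------------------------------------------------------------


def _cond_lookup(mapping: Mapping, movement: str, cue: str) -> float:
    """Look up a per-condition parameter keyed by (movement, cue) or movement."""
    if (movement, cue) in mapping:
        return float(mapping[(movement, cue)])
    return float(mapping[movement])


@dataclass
class ObserverModel:
    """Ground-truth generative observer for one participant.

    ``gain`` (1/mm) and ``criterion`` (z units) may be keyed either by
    movement or by ``(movement, cue)``.  ``lapse_rate`` is the probability
    of a stimulus-independent "no", ``guess_rate`` of a stimulus-independent
    "yes".  Onset/duration parameters are in ms relative to the go signal;
    ``emg_level`` is the expected extensor EMG burst scale per movement
    type (a.u.).
    """

    gain: Mapping
    criterion: Mapping
    lapse_rate: float = 0.0
    guess_rate: float = 0.0
    onset_mean: Mapping = field(
        default_factory=lambda: {"active": 1000.0, "passive": 1000.0}
    )
    onset_sd: Mapping = field(default_factory=lambda: {"active": 139.0, "passive": 20.0})
    duration_mean: Mapping = field(
        default_factory=lambda: {"active": 1025.0, "passive": 996.0}
    )
    duration_sd: Mapping = field(default_factory=lambda: {"active": 80.0, "passive": 20.0})
    emg_level: Mapping = field(
        default_factory=lambda: {"baseline": 8.0, "active": 49.0, "passive": 24.0}
    )
    baseline_stim_mean: float = 698.0
    baseline_stim_sd: float = 90.0
    missing_rate: float = 0.0
    gain_timecourse: Callable[[str, float], float] | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        if self.lapse_rate < 0 or self.guess_rate < 0:
            raise InvalidDesignError("lapse and guess rates must be non-negative")
        if self.lapse_rate + self.guess_rate >= 1.0:
            raise InvalidDesignError("lapse_rate + guess_rate must be < 1")
        for m in MOVEMENTS:
            for c in CUES:
                if _cond_lookup(self.gain, m, c) <= 0:
                    raise InvalidDesignError("gains must be positive")
        for d in (self.onset_sd, self.duration_sd):
            if any(v < 0 for v in d.values()):
                raise InvalidDesignError("standard deviations must be non-negative")

    def gain_for(self, movement: str, cue: str) -> float:
        return _cond_lookup(self.gain, movement, cue)

    def criterion_for(self, movement: str, cue: str) -> float:
        return _cond_lookup(self.criterion, movement, cue)


# Condition-specific sensitivity gains (1/mm) and decision criteria (z units)
# for the "paper_like" preset.  The values preserve the suppression
# ordering (baseline > passive > active sensitivity), criterion ordering
# (active > passive > baseline) and the sign/magnitude of the active-passive
# sensitivity contrast, while keeping every generating d' inside the range
# that finite-trial signal-detection cells can estimate without ceiling
# bias — the regime in which the pipeline's estimands are analytic and
# recoverable, which is this observer's purpose.
PAPER_LIKE_GAIN = {"baseline": 16.0, "active": 10.0, "passive": 13.0}
PAPER_LIKE_CRITERION = {"baseline": 1.0, "active": 1.5, "passive": 1.25}


def paper_like_observer(
    lapse_rate: float = 0.02,
    guess_rate: float = 0.02,
    **overrides,
) -> ObserverModel:
    """Observer preset emulating the experimental conditions being modelled."""
    model = ObserverModel(
        gain=dict(PAPER_LIKE_GAIN),
        criterion=dict(PAPER_LIKE_CRITERION),
        lapse_rate=lapse_rate,
        guess_rate=guess_rate,
    )
    if not (
        model.gain["baseline"] >= model.gain["passive"] >= model.gain["active"]
    ):
        raise InvalidDesignError("paper-like preset requires baseline >= passive >= active gains")
    return replace(model, **overrides) if overrides else model


def null_effect_observer(
    gain: float = 13.0, criterion: float = 1.25, **overrides
) -> ObserverModel:
    """Observer with identical sensitivity and criterion in every condition."""
    model = ObserverModel(
        gain={m: gain for m in MOVEMENTS},
        criterion={m: criterion for m in MOVEMENTS},
    )
    return replace(model, **overrides) if overrides else model


PRESETS = {"paper_like": paper_like_observer, "null_effect": null_effect_observer}


def make_cohort(
    n_participants: int,
    preset: str = "paper_like",
    seed: int = 0,
    sensitivity_jitter: float = 0.15,
    gain_jitter: float = 0.05,
    criterion_offset_sd: float = 0.15,
    criterion_jitter: float = 0.05,
    **preset_kwargs,
) -> list[ObserverModel]:
    """Draw a cohort of observers around a preset.

    Heterogeneity has a shared participant component (an overall
    sensitivity multiplier and a criterion offset applied to every
    condition, producing random-intercept variance at the group level)
    plus independent per-condition jitter.  Normal deviates are truncated
    symmetrically at two standard deviations, so multipliers keep mean 1
    and offsets mean 0 exactly and the population-mean condition
    differences equal the preset differences.
    """
    if preset not in PRESETS:
        raise InvalidDesignError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    base = PRESETS[preset](**preset_kwargs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 901517]))

    def trunc(sd: float) -> float:
        return float(np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd))

    models = []
    for p in range(n_participants):
        s = 1.0 + trunc(sensitivity_jitter)
        c0 = trunc(criterion_offset_sd)
        gmul = {m: 1.0 + trunc(gain_jitter) for m in MOVEMENTS}
        coff = {m: trunc(criterion_jitter) for m in MOVEMENTS}
        gain = {m: _cond_lookup(base.gain, m, CUES[0]) * s * gmul[m] for m in MOVEMENTS}
        crit = {
            m: _cond_lookup(base.criterion, m, CUES[0]) + c0 + coff[m] for m in MOVEMENTS
        }
        models.append(
            replace(base, gain=gain, criterion=crit, participant_id=f"p{p + 1:03d}")
        )
    return models


# ---------------------------------------------------------------------------
# stimulus scheduling
# ---------------------------------------------------------------------------


def schedule_stimulation(
    onset_history: Sequence[float],
    phase: str = "adaptive",
    lead_ms: float = DEFAULT_LEAD_MS,
) -> float:
    """Planned stimulation time (ms relative to go) for the next trial.

    During the first practice trials (``phase='practice_early'``) the probe
    is presented a fixed 75 ms after the countdown regardless of movement
    onsets.  In the adaptive phase the probe is scheduled at the mean of
    the five most recent movement onsets minus ``lead_ms``.
    """
    if phase == "practice_early":
        return DEFAULT_LEAD_MS
    if phase != "adaptive":
        raise ValueError(f"unknown phase {phase!r}")
    if len(onset_history) < 5:
        raise InsufficientHistoryError(
            f"adaptive scheduling needs >= 5 prior onsets, got {len(onset_history)}"
        )
    recent = np.asarray(onset_history[-5:], dtype=float)
    return float(recent.mean() - lead_ms)


def sample_passive_stim_time(
    active_onsets: Sequence[float],
    lead_ms: float = DEFAULT_LEAD_MS,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw a passive-trial stimulation time from the active onset distribution.

    A normal distribution is fitted to the participant's active movement
    onsets (sample mean and SD); one draw from it, minus ``lead_ms``, gives
    the planned stimulation time.
    """
    onsets = np.asarray(active_onsets, dtype=float)
    if onsets.size < 2:
        raise InsufficientHistoryError(
            "passive stimulus sampling needs >= 2 active onsets"
        )
    rng = np.random.default_rng() if rng is None else rng
    mu = onsets.mean()
    sd = onsets.std(ddof=1)
    return float(rng.normal(mu, sd) - lead_ms)


# ---------------------------------------------------------------------------
# detection model
# ---------------------------------------------------------------------------


def detection_probability(
    model: ObserverModel,
    movement: str,
    cue: str,
    amplitude_mm: float | None = None,
    stim_time_rel_onset: float | None = None,
) -> float:
    """Probability of a "yes" response under the generative observer.

    ``amplitude_mm=None`` denotes a catch trial.  If the observer carries a
    ``gain_timecourse`` and the probe time relative to movement onset is
    known, the gain is modulated accordingly (used to emulate time-resolved
    suppression).
    """
    lam = model.criterion_for(movement, cue)
    if amplitude_mm is None:
        x = -lam
    else:
        if amplitude_mm < 0:
            raise ValueError("amplitude must be non-negative")
        g = model.gain_for(movement, cue)
        if model.gain_timecourse is not None and stim_time_rel_onset is not None:
            g = g * float(model.gain_timecourse(movement, stim_time_rel_onset))
        x = g * amplitude_mm - lam
    p = model.guess_rate + (1.0 - model.guess_rate - model.lapse_rate) * norm.cdf(x)
    return float(p)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    trials: pd.DataFrame
    ground_truth: pd.DataFrame


def _respond(
    model: ObserverModel, out: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw yes/no/missing responses for a trial table (vectorized)."""
    movement = out["movement"].to_numpy()
    cue = out["session_cue"].to_numpy()
    stim_present = out["stimulus_present"].to_numpy()
    amplitude = out["amplitude_mm"].to_numpy()
    n = len(out)
    lam = np.empty(n)
    g = np.empty(n)
    for m in np.unique(movement):
        for c in np.unique(cue):
            sel = (movement == m) & (cue == c)
            if sel.any():
                lam[sel] = model.criterion_for(m, c)
                g[sel] = model.gain_for(m, c)
    if model.gain_timecourse is not None:
        tmod = np.array(
            [
                model.gain_timecourse(m, t)
                if (sp and m != "baseline" and np.isfinite(t))
                else 1.0
                for m, sp, t in zip(
                    movement, stim_present, out["stim_time_rel_onset"]
                )
            ]
        )
        g = g * tmod
    x = np.where(stim_present, g * np.nan_to_num(amplitude) - lam, -lam)
    p_yes = model.guess_rate + (1.0 - model.guess_rate - model.lapse_rate) * norm.cdf(x)
    u = rng.random(n)
    response = np.where(u < p_yes, "yes", "no")
    if model.missing_rate > 0:
        response = np.where(rng.random(n) < model.missing_rate, "missing", response)
    out["response"] = response
    out["valid"] = response != "missing"
    out["exclusion_reason"] = np.where(out["valid"], "", "missing_response")
    return out


def _simulate_cohort_iid(
    models: Sequence[ObserverModel],
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    lead_ms: float,
) -> pd.DataFrame:
    """Vectorized whole-cohort trial generation with stationary scheduling.

    Probe times are drawn from the stationary distribution of the adaptive
    rule: active probes at ``mean onset - lead`` plus the sampling noise of
    a five-trial rolling mean, passive probes from the active onset
    distribution minus the lead.
    """
    out = schedule
    n = len(out)
    codes, uniques = pd.factorize(out["participant_id"])
    by_pid = {m.participant_id or f"p{k + 1:03d}": m for k, m in enumerate(models)}
    mods = [by_pid[u] for u in uniques]
    movement = out["movement"].to_numpy()
    cue = out["session_cue"].to_numpy()
    stim_present = out["stimulus_present"].to_numpy()
    amplitude = out["amplitude_mm"].to_numpy()

    def pvec(fn) -> np.ndarray:
        return np.array([fn(m) for m in mods], dtype=float)[codes]

    onset = np.full(n, np.nan)
    offset = np.full(n, np.nan)
    stim_go = np.full(n, np.nan)
    z1, z2, z3 = rng.normal(size=(3, n))
    for m in ("active", "passive"):
        sel = movement == m
        mu = pvec(lambda o: o.onset_mean[m])
        sd = pvec(lambda o: o.onset_sd[m])
        onset[sel] = mu[sel] + sd[sel] * z1[sel]
        dur = np.maximum(
            100.0,
            pvec(lambda o: o.duration_mean[m])[sel]
            + pvec(lambda o: o.duration_sd[m])[sel] * z2[sel],
        )
        offset[sel] = onset[sel] + dur
    mu_a = pvec(lambda o: o.onset_mean["active"])
    sd_a = pvec(lambda o: o.onset_sd["active"])
    sel = (movement == "active") & stim_present
    stim_go[sel] = mu_a[sel] - lead_ms + (sd_a[sel] / np.sqrt(5.0)) * z3[sel]
    sel = (movement == "passive") & stim_present
    stim_go[sel] = mu_a[sel] - lead_ms + sd_a[sel] * z3[sel]
    sel = (movement == "baseline") & stim_present
    stim_go[sel] = (
        pvec(lambda o: o.baseline_stim_mean)[sel]
        + pvec(lambda o: o.baseline_stim_sd)[sel] * z3[sel]
    )

    out["movement_onset_rel_go"] = onset
    out["movement_offset_rel_go"] = offset
    out["stim_time_rel_go"] = stim_go
    out["stim_time_rel_onset"] = stim_go - onset

    # responses: per-row gain/criterion via (participant, movement, cue) lookup
    lam = np.empty(n)
    g = np.empty(n)
    for m in MOVEMENTS:
        for c in CUES:
            sel = (movement == m) & (cue == c)
            if sel.any():
                lam[sel] = pvec(lambda o: o.criterion_for(m, c))[sel]
                g[sel] = pvec(lambda o: o.gain_for(m, c))[sel]
    tc_models = [m for m in mods if m.gain_timecourse is not None]
    if tc_models:
        by_code = {i: m for i, m in enumerate(mods)}
        tmod = np.array(
            [
                by_code[k].gain_timecourse(mv, t)
                if (by_code[k].gain_timecourse and sp and mv != "baseline" and np.isfinite(t))
                else 1.0
                for k, mv, sp, t in zip(
                    codes, movement, stim_present, stim_go - onset
                )
            ]
        )
        g = g * tmod
    x = np.where(stim_present, g * np.nan_to_num(amplitude) - lam, -lam)
    guess = pvec(lambda o: o.guess_rate)
    lapse = pvec(lambda o: o.lapse_rate)
    p_yes = guess + (1.0 - guess - lapse) * norm.cdf(x)
    response = np.where(rng.random(n) < p_yes, "yes", "no")
    missing = pvec(lambda o: o.missing_rate)
    if np.any(missing > 0):
        response = np.where(rng.random(n) < missing, "missing", response)
    out["response"] = response
    out["valid"] = response != "missing"
    out["exclusion_reason"] = np.where(out["valid"], "", "missing_response")
    return out


def _simulate_participant(
    model: ObserverModel,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
    lead_ms: float,
    n_practice: int = 12,
) -> pd.DataFrame:
    """Run one participant through their schedule with adaptive scheduling."""
    mu_a = float(model.onset_mean["active"])
    sd_a = float(model.onset_sd["active"])

    # Practice block: active movements; the first five probes are fixed at
    # 75 ms after the countdown, later ones already use the adaptive rule.
    history: list[float] = []
    active_onsets: list[float] = []
    for i in range(n_practice):
        onset = rng.normal(mu_a, sd_a)
        if i >= 5:
            schedule_stimulation(history, "adaptive", lead_ms)  # planned, unused
        history.append(onset)
        active_onsets.append(onset)

    n = len(schedule)
    movement = schedule["movement"].to_numpy()
    stim_present = schedule["stimulus_present"].to_numpy()

    onset_out = np.full(n, np.nan)
    offset_out = np.full(n, np.nan)
    stim_go = np.full(n, np.nan)

    # Pre-draw the per-trial noise streams (deterministic order).
    z_onset = rng.normal(size=n)
    z_dur = rng.normal(size=n)
    z_passive = rng.normal(size=n)

    for i in range(n):
        m = movement[i]
        if m == "baseline":
            if stim_present[i]:
                stim_go[i] = model.baseline_stim_mean + model.baseline_stim_sd * z_onset[i]
            continue
        mu = float(model.onset_mean[m])
        sd = float(model.onset_sd[m])
        onset = mu + sd * z_onset[i]
        dur = max(100.0, float(model.duration_mean[m]) + float(model.duration_sd[m]) * z_dur[i])
        onset_out[i] = onset
        offset_out[i] = onset + dur
        if stim_present[i]:
            if m == "active":
                stim_go[i] = schedule_stimulation(history, "adaptive", lead_ms)
            else:  # passive: draw from the active onset distribution so far
                arr = np.asarray(active_onsets)
                stim_go[i] = arr.mean() + arr.std(ddof=1) * z_passive[i] - lead_ms
        if m == "active":
            history.append(onset)
            active_onsets.append(onset)

    out = schedule.copy()
    out["movement_onset_rel_go"] = onset_out
    out["movement_offset_rel_go"] = offset_out
    out["stim_time_rel_go"] = stim_go
    out["stim_time_rel_onset"] = stim_go - onset_out
    return _respond(model, out, rng)


def simulate_cohort(
    models: Sequence[ObserverModel],
    spec: DesignSpec | None = None,
    seed: int = 0,
    lead_ms: float = DEFAULT_LEAD_MS,
    scheduling: str = "adaptive",
) -> SimulationResult:
    """Simulate a full cohort: trial table plus ground-truth parameter table.

    ``scheduling='adaptive'`` runs the online rule trial by trial (mean of
    the last five onsets minus the lead, passive probes drawn from the
    active onset distribution).  ``scheduling='iid'`` draws probe times
    independently from the stationary distribution of that rule; it is
    statistically equivalent for timing-independent observers and much
    faster for large parameter-recovery cohorts.
    """
    if scheduling not in ("adaptive", "iid"):
        raise ValueError("scheduling must be 'adaptive' or 'iid'")
    spec = DesignSpec() if spec is None else spec
    root = np.random.SeedSequence(seed)
    design_seed = int(root.generate_state(1)[0] % (2**31))
    schedule = build_design(spec, len(models), design_seed)

    children = root.spawn(len(models))
    models = [
        replace(m, participant_id=f"p{k + 1:03d}") if m.participant_id is None else m
        for k, m in enumerate(models)
    ]
    frames = []
    gt_rows = []
    if scheduling == "iid":
        rng = np.random.default_rng(root.spawn(1)[0])
        frames.append(_simulate_cohort_iid(models, schedule, rng, lead_ms))
    for k, (model, ss) in enumerate(zip(models, children)):
        pid = f"p{k + 1:03d}"
        if scheduling == "adaptive":
            sub = schedule[schedule["participant_id"] == pid].reset_index(drop=True)
            rng = np.random.default_rng(ss)
            frames.append(_simulate_participant(model, sub, rng, lead_ms))
        for m in MOVEMENTS:
            for c in CUES:
                gt_rows.append(
                    {
                        "participant_id": pid,
                        "movement": m,
                        "session_cue": c,
                        "gain": model.gain_for(m, c),
                        "criterion": model.criterion_for(m, c),
                        "lapse_rate": model.lapse_rate,
                        "guess_rate": model.guess_rate,
                        "onset_mean": model.onset_mean.get(m, np.nan),
                        "onset_sd": model.onset_sd.get(m, np.nan),
                        "duration_mean": model.duration_mean.get(m, np.nan),
                        "duration_sd": model.duration_sd.get(m, np.nan),
                        "emg_level": model.emg_level.get(m, np.nan),
                    }
                )
    trials = pd.concat(frames, ignore_index=True)
    trials.insert(0, "trial_id", np.arange(len(trials)))
    trials = trials[TRIAL_COLUMNS]
    return SimulationResult(trials=trials, ground_truth=pd.DataFrame(gt_rows))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def position_trace_values(
    t: np.ndarray,
    onset: float,
    duration: float,
    peak_units: float = 100.0,
    threshold_units: float = 2.0,
) -> np.ndarray:
    """Triangular out-and-back wrist excursion in encoder units.

    The motion is anchored so that the position crosses ``threshold_units``
    exactly at ``onset`` on the way out and returns to the threshold exactly
    at ``onset + duration``; the detected duration is therefore unbiased up
    to sampling resolution.
    """
    # span solves span - 2*delta = duration with delta = threshold*span/(2*peak)
    span = duration / (1.0 - threshold_units / peak_units)
    slope = 2.0 * peak_units / span
    delta = threshold_units / slope
    t0 = onset - delta
    mid = t0 + span / 2.0
    v = peak_units - slope * np.abs(np.asarray(t, dtype=float) - mid)
    return np.clip(v, 0.0, None)


def emg_trace_values(
    t: np.ndarray,
    rng: np.random.Generator,
    onset: float | None,
    offset: float | None,
    burst_scale: float,
    baseline_scale: float = 5.0,
) -> np.ndarray:
    """Raw (unrectified) surface-EMG-like signal in arbitrary units.

    Zero-mean Gaussian noise whose scale rises from ``baseline_scale`` to
    ``baseline_scale + burst_scale`` during the movement (from 100 ms
    before onset until offset).  Baseline trials (``onset=None``) carry
    only the resting scale.
    """
    t = np.asarray(t, dtype=float)
    scale = np.full(t.shape, baseline_scale)
    if onset is not None and offset is not None and np.isfinite(onset):
        in_burst = (t >= onset - 100.0) & (t <= offset)
        scale = np.where(in_burst, baseline_scale + burst_scale, scale)
    return rng.normal(0.0, 1.0, t.shape) * scale


def simulate_traces(
    trials: pd.DataFrame,
    models: Sequence[ObserverModel],
    seed: int = 0,
    dt_ms: float = 5.0,
    t_start: float = -(INSTRUCTION_MS + COUNTDOWN_MS),
    t_end: float = 3600.0,
) -> pd.DataFrame:
    """Generate long-format position and EMG traces for the given trials.

    Returns a DataFrame with columns ``trial_id, kind, t_ms, value`` where
    ``kind`` is ``position`` or ``emg``.  Event markers shared by all
    trials: instruction onset at -2500 ms, go at 0 ms.
    """
    by_pid = {}
    for k, m in enumerate(models):
        pid = m.participant_id or f"p{k + 1:03d}"
        by_pid[pid] = m
    t = np.arange(t_start, t_end + dt_ms / 2, dt_ms)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AACE5 % (2**31)]))
    chunks = []
    for row in trials.itertuples():
        model = by_pid[row.participant_id]
        onset = row.movement_onset_rel_go
        offset = row.movement_offset_rel_go
        if row.movement == "baseline" or not np.isfinite(onset):
            # residual extensor tone in the nominal movement window; the
            # feature pipeline uses the same nominal window for baseline
            pos = np.zeros_like(t)
            emg = emg_trace_values(
                t, rng, BASELINE_WINDOW_MS[0], BASELINE_WINDOW_MS[1],
                float(model.emg_level.get("baseline", 0.0)),
            )
        else:
            pos = position_trace_values(t, onset, offset - onset)
            emg = emg_trace_values(
                t, rng, onset, offset, float(model.emg_level.get(row.movement, 0.0))
            )
        for kind, v in (("position", pos), ("emg", emg)):
            chunks.append(
                pd.DataFrame(
                    {
                        "trial_id": row.trial_id,
                        "kind": kind,
                        "t_ms": t,
                        "value": v,
                    }
                )
            )
    return pd.concat(chunks, ignore_index=True)
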