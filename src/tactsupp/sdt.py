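"""Signal-detection pipeline: trial exclusion, amplitude binning,
loglinear-corrected rates, d'/c/relative c, detection thresholds and
detection-rate time courses.

Conventions (equal-variance Gaussian SDT):

    d' = z(H) - z(F)
    c  = -(z(H) + z(F)) / 2
    relative c = c / d'

where ``z`` is the standard-normal quantile.  When a hit rate of 1 or a
false-alarm rate of 0 (or the symmetric boundary) would send ``z`` to
infinity, the loglinear correction adds 0.5 to both counts and 1 to both
trial totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.proportion import proportion_confint

from .exceptions import (
    EmptyCellError,
    InsufficientNoiseError,
    MustCorrectError,
    NoThresholdError,
    UnsupportedGridError,
)
from .simulate import AmplitudeGrid

DEFAULT_WINDOW_MS = (-300.0, 0.0)
DEFAULT_BIN_SIZES = (2, 2, 3, 2, 2)


# ---------------------------------------------------------------------------
# trial exclusion
# ---------------------------------------------------------------------------


def filter_trials(
    trials: pd.DataFrame, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step trial exclusion.

    Step 1 removes behavioural/technical failures: missing responses,
    trials already flagged invalid, and movement trials without a detected
    movement onset.  Step 2 removes movement-trial probes outside the
    suppression window: kept iff ``window_ms[0] <= stim_time_rel_onset <
    window_ms[1]`` (the lower boundary is inclusive, probes at or after
    movement onset are excluded).  Baseline trials and catch trials are
    untouched by step 2.

    Returns ``(kept, summary)`` where ``summary`` reports per-condition
    counts and fractions; kept + excluded always equals the input count.
    """
    df = trials.copy(deep=False)
    mov = df["movement"].to_numpy()
    is_movement = (mov == "active") | (mov == "passive")

    resp = df["response"].to_numpy(dtype=object)
    valid_in = (
        df["valid"].to_numpy(dtype=bool)
        if "valid" in df.columns
        else np.ones(len(df), dtype=bool)
    )
    step1 = (
        pd.isna(resp)
        | (resp == "missing")
        | ~valid_in
        | (is_movement & df["movement_onset_rel_go"].isna().to_numpy())
    )

    t = df["stim_time_rel_onset"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        step2 = (
            ~step1
            & is_movement
            & df["stimulus_present"].to_numpy(dtype=bool)
            & ((t < window_ms[0]) | (t >= window_ms[1]) | np.isnan(t))
        )
    step1 = pd.Series(step1, index=df.index)
    step2 = pd.Series(step2, index=df.index)

    reason = np.where(step1, "behavior_or_technical", np.where(step2, "outside_window", ""))
    df["valid"] = ~(step1 | step2)
    df["exclusion_reason"] = reason

    summary = (
        df.assign(_s1=step1.to_numpy(), _s2=step2.to_numpy())
        .groupby(["participant_id", "movement", "session_cue"], observed=True)
        .agg(
            n_total=("valid", "size"),
            n_step1=("_s1", "sum"),
            n_step2=("_s2", "sum"),
            n_kept=("valid", "sum"),
        )
        .reset_index()
    )
    summary["frac_excluded"] = 1.0 - summary["n_kept"] / summary["n_total"]

    keep_mask = df["valid"].to_numpy(dtype=bool)
    kept = df[keep_mask]
    assert len(kept) + int((~keep_mask).sum()) == len(trials)
    return kept, summary


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinScheme:
    """Partition of the amplitude grid into contiguous ordered bins."""

    sizes: tuple[int, ...]
    level_bin: tuple[int, ...]  # bin index of each grid level
    bin_mean_amplitude: tuple[float, ...]  # mm

    @property
    def n_bins(self) -> int:
        return len(self.sizes)


def bin_amplitudes(
    grid: AmplitudeGrid, sizes: tuple[int, ...] = DEFAULT_BIN_SIZES
) -> BinScheme:
    """Group grid levels into contiguous bins (default 2, 2, 3, 2, 2).

    Raises :class:`UnsupportedGridError` when the grid size does not match
    the requested partition; pass custom ``sizes`` for generic k-binning.
    """
    if sum(sizes) != grid.n_levels:
        raise UnsupportedGridError(
            f"bin sizes {sizes} do not partition a {grid.n_levels}-level grid"
        )
    level_bin = []
    for b, s in enumerate(sizes):
        level_bin.extend([b] * s)
    levels = np.asarray(grid.levels)
    means = tuple(
        float(levels[[i for i, lb in enumerate(level_bin) if lb == b]].mean())
        for b in range(len(sizes))
    )
    return BinScheme(sizes=tuple(sizes), level_bin=tuple(level_bin), bin_mean_amplitude=means)


def assign_noise_bins(
    n_trials: int, n_bins: int = 5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random partition of noise trials into bins with near-equal sizes.

    66 trials over 5 bins gives sizes {14, 13, 13, 13, 13}; which bin gets
    the extra trial and which trial lands in which bin are randomized by
    ``rng``.
    """
    if n_trials < n_bins:
        raise InsufficientNoiseError(
            f"{n_trials} noise trials cannot fill {n_bins} bins"
        )
    rng = np.random.default_rng() if rng is None else rng
    base, extra = divmod(n_trials, n_bins)
    lucky = rng.permutation(n_bins)[:extra]
    sizes = np.full(n_bins, base)
    sizes[lucky] += 1
    labels = np.repeat(np.arange(n_bins), sizes)
    return rng.permutation(labels)


# ---------------------------------------------------------------------------
# rates and measures
# ---------------------------------------------------------------------------


def corrected_rates(
    hits: int, n_signal: int, fas: int, n_noise: int
) -> tuple[float, float, bool]:
    """Hit/false-alarm rates with the conditional loglinear correction.

    If either rate sits on the 0/1 boundary, 0.5 is added to both counts
    and 1 to both trial totals (both rates move together); otherwise the
    raw rates are returned.  Output rates always lie strictly in (0, 1).
    """
    if n_signal <= 0 or n_noise <= 0:
        raise EmptyCellError("cell has no signal or no noise trials")
    if not (0 <= hits <= n_signal and 0 <= fas <= n_noise):
        raise ValueError("counts out of range")
    H_raw = hits / n_signal
    F_raw = fas / n_noise
    if H_raw in (0.0, 1.0) or F_raw in (0.0, 1.0):
        return (hits + 0.5) / (n_signal + 1), (fas + 0.5) / (n_noise + 1), True
    return H_raw, F_raw, False


def loglinear_rates(
    hits: int, n_signal: int, fas: int, n_noise: int
) -> tuple[float, float, bool]:
    """Unconditional loglinear rates (always-correct mode)."""
    if n_signal <= 0 or n_noise <= 0:
        raise EmptyCellError("cell has no signal or no noise trials")
    return (hits + 0.5) / (n_signal + 1), (fas + 0.5) / (n_noise + 1), True


def sdt_measures(H: float, F: float) -> tuple[float, float, float]:
    """(d', c, relative c) from corrected hit and false-alarm rates."""
    if not (0.0 < H < 1.0 and 0.0 < F < 1.0):
        raise MustCorrectError("rates on the 0/1 boundary must be corrected first")
    zH, zF = norm.ppf(H), norm.ppf(F)
    d = zH - zF
    c = -(zH + zF) / 2.0
    rel = c / d if abs(d) > 1e-12 else float("nan")
    return float(d), float(c), float(rel)


# ---------------------------------------------------------------------------
# cell table
# ---------------------------------------------------------------------------


def _amplitude_to_level(amps: np.ndarray, levels: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(levels, amps)
    idx = np.clip(idx, 0, len(levels) - 1)
    left = np.clip(idx - 1, 0, len(levels) - 1)
    idx = np.where(
        np.abs(levels[left] - amps) < np.abs(levels[idx] - amps), left, idx
    )
    if np.any(np.abs(levels[idx] - amps) > 1e-6 + 1e-4 * np.abs(amps)):
        raise UnsupportedGridError("some trial amplitudes do not match the grid")
    return idx


def compute_sdt_cells(
    trials: pd.DataFrame,
    grid: AmplitudeGrid | None = None,
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    loglinear: str = "conditional",
    d_eps: float = 0.1,
    relc_max: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-cell SDT table from a raw trial table.

    Pipeline: exclusion -> amplitude binning (signal) and random equal
    split (noise) -> hit/FA rates with loglinear handling -> d', c,
    relative c -> condition-level exclusion flags.  Returns ``(cells,
    exclusion_summary)``; one cell per participant x movement x cue x bin.
    """
    if loglinear not in ("conditional", "always"):
        raise ValueError("loglinear must be 'conditional' or 'always'")
    kept, summary = filter_trials(trials, window_ms)

    sig = kept[kept["stimulus_present"].astype(bool)].copy()
    noi = kept[~kept["stimulus_present"].astype(bool)].copy()
    if grid is None:
        grid = AmplitudeGrid(tuple(sorted(sig["amplitude_mm"].dropna().unique())))
    scheme = bin_amplitudes(grid, bin_sizes)
    levels = np.asarray(grid.levels)
    level_bin = np.asarray(scheme.level_bin)

    sig["bin_index"] = level_bin[_amplitude_to_level(sig["amplitude_mm"].to_numpy(), levels)]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 425611]))
    noi = noi.sort_values("trial_id")
    bins = np.empty(len(noi), dtype=int)
    noi = noi.reset_index(drop=True)
    for _, idx in noi.groupby(
        ["participant_id", "movement", "session_cue"], observed=True, sort=True
    ).indices.items():
        bins[idx] = assign_noise_bins(len(idx), scheme.n_bins, rng)
    noi["bin_index"] = bins

    s_counts = (
        sig.assign(yes=sig["response"] == "yes")
        .groupby(["participant_id", "movement", "session_cue", "bin_index"], observed=True)
        .agg(n_signal=("yes", "size"), hits=("yes", "sum"))
    )
    n_counts = (
        noi.assign(yes=noi["response"] == "yes")
        .groupby(["participant_id", "movement", "session_cue", "bin_index"], observed=True)
        .agg(n_noise=("yes", "size"), false_alarms=("yes", "sum"))
    )
    cells = s_counts.join(n_counts, how="outer").reset_index()
    cells = cells.dropna(subset=["n_signal", "n_noise"])
    for c in ("n_signal", "hits", "n_noise", "false_alarms"):
        cells[c] = cells[c].astype(int)

    # vectorized form of corrected_rates / loglinear_rates over all cells
    hits = cells["hits"].to_numpy(float)
    n_sig = cells["n_signal"].to_numpy(float)
    fas = cells["false_alarms"].to_numpy(float)
    n_noi = cells["n_noise"].to_numpy(float)
    H_raw, F_raw = hits / n_sig, fas / n_noi
    boundary = (H_raw == 0) | (H_raw == 1) | (F_raw == 0) | (F_raw == 1)
    corr = np.ones_like(boundary) if loglinear == "always" else boundary
    H = np.where(corr, (hits + 0.5) / (n_sig + 1), H_raw)
    F = np.where(corr, (fas + 0.5) / (n_noi + 1), F_raw)
    zH, zF = norm.ppf(H), norm.ppf(F)
    cells["H"], cells["F"], cells["corrected"] = H, F, corr
    cells["d_prime"] = zH - zF
    cells["c"] = -(zH + zF) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["relative_c"] = np.where(
            np.abs(cells["d_prime"]) > 1e-12, cells["c"] / cells["d_prime"], np.nan
        )
    cells["amplitude_mm"] = np.asarray(scheme.bin_mean_amplitude)[cells["bin_index"]]
    cells = exclude_cells(cells, d_eps=d_eps, relc_max=relc_max)
    return cells, summary


def exclude_cells(
    cells: pd.DataFrame,
    d_eps: float = 0.1,
    relc_max: float = 30.0,
    level: str = "condition",
) -> pd.DataFrame:
    """Flag cells from unreliable conditions.

    A participant x movement x cue condition is excluded when its mean
    |d'| is nearly zero (< ``d_eps``) or its mean |relative c| exceeds
    ``relc_max``; all bins of that condition are flagged.  With
    ``level='cell'`` the rule is applied per bin instead.
    """
    out = cells.copy()
    if level == "cell":
        bad_d = out["d_prime"].abs() < d_eps
        bad_r = out["relative_c"].abs() > relc_max
    elif level == "condition":
        grp = out.groupby(["participant_id", "movement", "session_cue"], observed=True)
        mean_d = grp["d_prime"].transform("mean")
        mean_r = grp["relative_c"].transform("mean")
        bad_d = mean_d.abs() < d_eps
        bad_r = mean_r.abs() > relc_max
    else:
        raise ValueError("level must be 'condition' or 'cell'")
    out["excluded"] = (bad_d | bad_r.fillna(False)).to_numpy()
    out["cell_exclusion_reason"] = np.where(
        bad_d, "d_prime_near_zero", np.where(bad_r.fillna(False), "relative_c_large", "")
    )
    return out


# ---------------------------------------------------------------------------
# psychometric threshold
# ---------------------------------------------------------------------------


class PsychometricThreshold(BaseEstimator):
    """Cumulative-Gaussian psychometric function fitted by maximum likelihood.

    Model: P(yes | a) = guess + (1 - guess - lapse) * Phi((a - mu) / sigma).
    The detection threshold is the amplitude at 50% "yes" (equal to ``mu``
    when guess and lapse are zero).  If the likelihood fit fails, the
    threshold falls back to linear interpolation of per-amplitude detection
    rates across 0.5.

    Attributes (after ``fit``): ``mu_``, ``sigma_``, ``threshold_``,
    ``slope_`` (= 1/sigma_), ``method_`` ('mle' or 'interpolation'),
    ``converged_``.
    """

    def __init__(self, guess: float = 0.0, lapse: float = 0.0):
        self.guess = guess
        self.lapse = lapse

    def _target_phi(self) -> float:
        span = 1.0 - self.guess - self.lapse
        q = (0.5 - self.guess) / span
        if not 0.0 < q < 1.0:
            raise NoThresholdError("50% point unreachable for these guess/lapse rates")
        return q

    def fit(self, X, y):
        a = np.asarray(X, dtype=float).reshape(-1)
        r = np.asarray(y)
        if r.dtype.kind in "OUS":
            r = (r == "yes").astype(float)
        r = np.asarray(r, dtype=float).reshape(-1)
        if a.shape != r.shape or a.size < 2:
            raise ValueError("need matching amplitude/response vectors with >= 2 trials")
        if np.unique(a).size < 2:
            raise NoThresholdError("need >= 2 distinct amplitude levels")
        if r.min() == r.max():
            raise NoThresholdError("all-yes or all-no data carry no threshold information")

        span = 1.0 - self.guess - self.lapse
        mu0 = float(np.interp(0.5, *self._rate_curve(a, r)))
        s0 = max((a.max() - a.min()) / 4.0, 1e-6)

        def nll(theta):
            mu, log_s = theta
            p = self.guess + span * norm.cdf((a - mu) / np.exp(log_s))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(r * np.log(p) + (1 - r) * np.log1p(-p))

        res = optimize.minimize(nll, x0=[mu0, np.log(s0)], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        amax = a.max()
        if res.success and -amax <= res.x[0] <= 3 * amax:
            self.mu_ = float(res.x[0])
            self.sigma_ = float(np.exp(res.x[1]))
            self.threshold_ = self.mu_ + self.sigma_ * float(norm.ppf(self._target_phi()))
            self.method_ = "mle"
            self.converged_ = True
        else:
            self.mu_ = mu0
            self.sigma_ = s0
            self.threshold_ = mu0
            self.method_ = "interpolation"
            self.converged_ = False
        self.slope_ = 1.0 / self.sigma_
        return self

    @staticmethod
    def _rate_curve(a: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        df = pd.DataFrame({"a": a, "r": r}).groupby("a")["r"].mean()
        return df.to_numpy(), df.index.to_numpy()

    def predict(self, X):
        a = np.asarray(X, dtype=float).reshape(-1)
        span = 1.0 - self.guess - self.lapse
        return self.guess + span * norm.cdf((a - self.mu_) / self.sigma_)


def detection_threshold(
    trials: pd.DataFrame, guess: float = 0.0, lapse: float = 0.0
) -> float:
    """50%-detection amplitude (mm) from one participant-condition's signal trials."""
    sig = trials[trials["stimulus_present"].astype(bool)]
    est = PsychometricThreshold(guess=guess, lapse=lapse)
    est.fit(sig["amplitude_mm"].to_numpy(), sig["response"].to_numpy())
    return float(est.threshold_)


# ---------------------------------------------------------------------------
# detection time course
# ---------------------------------------------------------------------------


def detection_timecourse(
    trials: pd.DataFrame,
    bin_edges_ms: np.ndarray | None = None,
    by: tuple[str, ...] = ("movement", "session_cue"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detection rate of movement-locked probes per stimulation-time bin.

    Bins are over stimulation time relative to movement onset (default
    50-ms bins spanning [-300, 0) ms).  Each condition x bin row carries
    the detected/total counts and a binomial (Clopper-Pearson) confidence
    interval; bins without trials are simply absent.
    """
    edges = np.arange(-300.0, 0.1, 50.0) if bin_edges_ms is None else np.asarray(bin_edges_ms, float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D array")
    sig = trials[
        trials["stimulus_present"].astype(bool)
        & trials["movement"].isin(["active", "passive"])
        & trials["stim_time_rel_onset"].notna()
    ].copy()
    sig["time_bin"] = pd.cut(sig["stim_time_rel_onset"], edges, right=False)
    sig = sig[sig["time_bin"].notna()]
    rows = []
    for key, grp in sig.groupby([*by, "time_bin"], observed=True):
        n = len(grp)
        k = int((grp["response"] == "yes").sum())
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        interval = key[-1]
        rows.append(
            {
                **dict(zip(by, key[:-1])),
                "bin_left_ms": float(interval.left),
                "bin_right_ms": float(interval.right),
                "n": n,
                "detected": k,
                "rate": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------


class TrialFilter(BaseEstimator, TransformerMixin):
    """Transformer applying the two-step trial exclusion to a trial table."""

    def __init__(self, window_ms: tuple[float, float] = DEFAULT_WINDOW_MS):
        self.window_ms = window_ms

    def fit(self, X: pd.DataFrame, y=None):
        if "movement" not in X.columns:
            raise ValueError("expected a trial table with a 'movement' column")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept, summary = filter_trials(X, tuple(self.window_ms))
        self.summary_ = summary
        return kept


class SDTAnalysis(BaseEstimator, TransformerMixin):
    """Transformer mapping a raw trial table to the per-cell SDT table.

    Composes with :class:`sklearn.pipeline.Pipeline`; the transform output
    is the participant x movement x cue x amplitude-bin table of hits,
    false alarms, corrected rates, d', c and relative c, ready for the
    mixed-model stage.
    """

    def __init__(
        self,
        window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
        bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES,
        loglinear: str = "conditional",
        d_eps: float = 0.1,
        relc_max: float = 30.0,
        seed: int = 0,
    ):
        self.window_ms = window_ms
        self.bin_sizes = bin_sizes
        self.loglinear = loglinear
        self.d_eps = d_eps
        self.relc_max = relc_max
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        missing = {"movement", "stimulus_present", "response"} - set(X.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cells, summary = compute_sdt_cells(
            X,
            bin_sizes=tuple(self.bin_sizes),
            window_ms=tuple(self.window_ms),
            loglinear=self.loglinear,
            d_eps=self.d_eps,
            relc_max=self.relc_max,
            seed=self.seed,
        )
        self.exclusion_summary_ = summary
        return cells
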