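"""Monte-Carlo validation studies: parameter recovery, CI coverage,
and null calibration of the full pipeline.

These drive the package's self-contained validation: simulated cohorts
with known ground truth are pushed through the complete exclusion ->
binning -> rates -> measures -> mixed-model chain, and the recovered
quantities are compared with the generating parameters.  Sizes follow the
package's validation design (see docs/methods.md): zero-lapse cohorts of
34 observers with 48 repetitions per amplitude give 96-144 signal and
~105 noise trials per bin, enough that the signal-detection estimates are
effectively unbiased while a 200-seed study still runs in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import fit_lmm, pairwise_contrasts
from .sdt import bin_amplitudes, compute_sdt_cells
from .simulate import (
    PAPER_LIKE_GAIN,
    AmplitudeGrid,
    DesignSpec,
    make_cohort,
    simulate_cohort,
)


def _child_seeds(seed: int, n: int, stream: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return ss.generate_state(n) % (2**31)


def recovery_study(
    n_seeds: int = 200,
    n_participants: int = 34,
    reps_per_amplitude: int = 48,
    seed: int = 0,
) -> dict:
    """Parameter recovery and contrast CI coverage on zero-lapse cohorts.

    Per seed: simulate a paper-like cohort with known per-participant
    gains, run the full SDT pipeline, compare per-bin d' with the
    generating ``gain * bin-mean amplitude``, fit the condition LMM and
    record whether each pairwise movement-contrast CI covers the
    population generating difference.

    Returns per-bin mean biases, the maximum absolute bias, and pooled CI
    coverage.
    """
    seeds = _child_seeds(seed, 3 * n_seeds, stream=101).reshape(3, n_seeds)
    scheme = bin_amplitudes(AmplitudeGrid.default())
    abar = float(np.mean(scheme.bin_mean_amplitude))
    true_diff = {
        "active - baseline": (PAPER_LIKE_GAIN["active"] - PAPER_LIKE_GAIN["baseline"]) * abar,
        "active - passive": (PAPER_LIKE_GAIN["active"] - PAPER_LIKE_GAIN["passive"]) * abar,
        "baseline - passive": (PAPER_LIKE_GAIN["baseline"] - PAPER_LIKE_GAIN["passive"]) * abar,
    }
    bias_rows = []
    covered = []
    for k in range(n_seeds):
        models = make_cohort(
            n_participants, "paper_like", seed=int(seeds[0, k]),
            lapse_rate=0.0, guess_rate=0.0,
        )
        sim = simulate_cohort(
            models, DesignSpec(reps_per_amplitude=reps_per_amplitude),
            seed=int(seeds[1, k]), scheduling="iid",
        )
        cells, _ = compute_sdt_cells(sim.trials, seed=int(seeds[2, k]))
        merged = cells.merge(
            sim.ground_truth, on=["participant_id", "movement", "session_cue"]
        )
        merged["bias"] = merged["d_prime"] - merged["gain"] * merged["amplitude_mm"]
        per_bin = merged.groupby(["movement", "bin_index"], observed=True)["bias"].mean()
        bias_rows.append(per_bin)

        fit = fit_lmm(cells, response="d_prime")
        contrasts, _ = pairwise_contrasts(fit, "movement")
        for row in contrasts.itertuples():
            t = true_diff[row.pair]
            covered.append(row.ci_low <= t <= row.ci_high)

    bias = pd.concat(bias_rows, axis=1).mean(axis=1)
    return {
        "per_bin_bias": bias,
        "max_abs_bias": float(bias.abs().max()),
        "coverage": float(np.mean(covered)),
        "n_seeds": n_seeds,
        "n_intervals": len(covered),
    }


def null_calibration_study(
    n_seeds: int = 300,
    n_participants: int = 34,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the movement F test under a no-effect generator.

    The null cohort has identical gains and criteria in every condition
    (participant-level overall sensitivity and criterion offsets remain,
    and are absorbed by the random intercept); condition-specific jitter
    is off so the movement null is exactly true.
    """
    seeds = _child_seeds(seed, 3 * n_seeds, stream=202).reshape(3, n_seeds)
    pvals = []
    for k in range(n_seeds):
        models = make_cohort(
            n_participants, "null_effect", seed=int(seeds[0, k]),
            gain_jitter=0.0, criterion_jitter=0.0,
        )
        sim = simulate_cohort(
            models, DesignSpec(), seed=int(seeds[1, k]), scheduling="iid"
        )
        cells, _ = compute_sdt_cells(sim.trials, seed=int(seeds[2, k]))
        fit = fit_lmm(cells, response="d_prime")
        pvals.append(fit.anova.set_index("term").loc["movement", "p"])
    pvals = np.asarray(pvals)
    return {
        "type1_rate": float(np.mean(pvals < alpha)),
        "n_seeds": n_seeds,
        "p_values": pvals,
    }


def spearman_null_study(
    n_reps: int = 10_000,
    n: int = 35,
    alpha: float = 0.05,
    n_tests: int = 8,
    seed: int = 0,
) -> dict:
    """Rejection rate of the Bonferroni-thresholded Spearman test under
    independence (vectorized over replicates)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    x = rng.random((n_reps, n))
    y = rng.random((n_reps, n))
    rx = np.argsort(np.argsort(x, axis=1), axis=1).astype(float)
    ry = np.argsort(np.argsort(y, axis=1), axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    rho = (rx * ry).sum(axis=1) / np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    thr = alpha / n_tests
    return {
        "rejection_rate": float(np.mean(p < thr)),
        "threshold": thr,
        "n_reps": n_reps,
    }


def exclusion_study(n_seeds: int = 10, n_participants: int = 34, seed: int = 0) -> dict:
    """Fraction of condition cells excluded by the d'/relative-c rules and
    per-condition trial-exclusion fractions on default paper-like cohorts."""
    seeds = _child_seeds(seed, 3 * n_seeds, stream=404).reshape(3, n_seeds)
    cond_fracs = []
    step2 = {"active": [], "passive": []}
    lead_means = []
    for k in range(n_seeds):
        models = make_cohort(n_participants, "paper_like", seed=int(seeds[0, k]))
        sim = simulate_cohort(models, DesignSpec(), seed=int(seeds[1, k]))
        cells, summary = compute_sdt_cells(sim.trials, seed=int(seeds[2, k]))
        per_cond = cells.groupby(
            ["participant_id", "movement", "session_cue"], observed=True
        )["excluded"].first()
        cond_fracs.append(per_cond.mean())
        t = sim.trials
        for mv in ("active", "passive"):
            sub = summary[summary["movement"] == mv]
            n_probe = (
                t[(t["movement"] == mv) & t["stimulus_present"]].shape[0]
            )
            step2[mv].append(sub["n_step2"].sum() / n_probe)
        probes = t[(t["movement"] == "active") & t["stimulus_present"]]
        lead_means.append(probes["stim_time_rel_onset"].mean())
    return {
        "excluded_condition_fraction": float(np.mean(cond_fracs)),
        "active_step2_fraction": float(np.mean(step2["active"])),
        "passive_step2_fraction": float(np.mean(step2["passive"])),
        "active_probe_lead_mean_ms": float(np.mean(lead_means)),
        "n_seeds": n_seeds,
    }
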