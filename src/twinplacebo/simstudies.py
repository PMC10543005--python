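"""Validation experiments: parameter recovery, error calibration, BF nulls.

These are the package's own operating-characteristic studies, run on scaled
synthetic cohorts with known ground truth:

* :func:`recovery_study` — repeated cohorts with the thermal placebo effect
  planted at -0.359 on the z scale; reports the mean REML estimate, its
  Monte Carlo standard error, and empirical 95% CI coverage using
  Satterthwaite degrees of freedom.
* :func:`type1_study` — repeated cohorts with a zero placebo effect;
  reports the rejection rate of the Wald t test at alpha = .05.  Generation
  and fit both use zygosity-split random intercepts, the structure under
  which the 1,000-replicate loop is affordable.
* :func:`bf_null_study` — repeated null cohorts; reports the median Bayes
  factor per (prior width, interaction) grid cell, which should fall below
  1/3 (moderate-or-better evidence for the null) everywhere.

Cohort compositions are scaled-down versions of the study composition
(71 MZ / 80 DZ / 93 singleton families), preserving the MZ:DZ:singleton mix.
"""

from __future__ import annotations

import numpy as np

from . import bayes, synth, twinlmm

__all__ = ["recovery_study", "type1_study", "bf_null_study"]

#: ~100 families preserving the study's MZ / DZ / singleton mix
RECOVERY_COHORT = (58, 66, 38)
#: ~40 families for the high-replicate loops
SMALL_COHORT = (24, 26, 15)

PLANTED_PLACEBO = -0.359  # thermal placebo effect, z scale


def _child_seed(seed: int, rep: int, salt: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=(salt, rep)).generate_state(1)[0]
        % (2**31 - 1)
    )


def recovery_study(
    n_reps: int = 200, seed: int = 0, cohort_counts: tuple[int, int, int] = RECOVERY_COHORT
) -> dict:
    """Planted-effect recovery and CI coverage for the thermal placebo slope."""
    estimates, covered = [], []
    for rep in range(n_reps):
        s = _child_seed(seed, rep, 1)
        cohort = synth.generate_cohort(synth.CohortSpec(*cohort_counts, seed=s))
        trials, _ = synth.simulate_trial_table(cohort, seed=s, rt_violation_fraction=0.0)
        thermal = trials[trials.modality == "thermal"]
        fit = twinlmm.fit_reml(
            twinlmm.encode_design(thermal, twinlmm.ModelSpec(outcome="intensity_latent")),
            seed=s,
        )
        est = twinlmm.test_fixed_effect(fit, "placebo_condition")
        estimates.append(est.beta)
        covered.append(est.ci95[0] <= PLANTED_PLACEBO <= est.ci95[1])
    estimates = np.asarray(estimates)
    return {
        "n_reps": n_reps,
        "planted": PLANTED_PLACEBO,
        "mean_estimate": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        "bias": float(estimates.mean() - PLANTED_PLACEBO),
        "coverage": float(np.mean(covered)),
    }


_NULL_EFFECTS = synth.EffectSpec(
    thermal=(0.0, 0.409, 0.0, 0.0), mechanical=(0.0, 0.202, 0.0, 0.0)
)
#: intercept-only random structure (slope SDs zero) for the fast null loops
_INTERCEPT_VC = synth.VarianceComponents(
    family_cov=np.diag([0.5**2, 0.0, 0.0]),
    sd_individual_mz=(0.30, 0.0, 0.0),
    sd_individual_dz=(0.45, 0.0, 0.0),
)


def type1_study(
    n_reps: int = 1000,
    seed: int = 0,
    cohort_counts: tuple[int, int, int] = SMALL_COHORT,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the placebo Wald t test under a planted null."""
    rejections = 0
    spec = twinlmm.ModelSpec(outcome="intensity_latent", random=("intercept",))
    for rep in range(n_reps):
        s = _child_seed(seed, rep, 2)
        cohort = synth.generate_cohort(synth.CohortSpec(*cohort_counts, seed=s))
        trials, _ = synth.simulate_trial_table(
            cohort, _NULL_EFFECTS, _INTERCEPT_VC, seed=s, rt_violation_fraction=0.0
        )
        thermal = trials[trials.modality == "thermal"]
        fit = twinlmm.fit_reml(twinlmm.encode_design(thermal, spec), seed=s)
        est = twinlmm.test_fixed_effect(fit, "placebo_condition")
        rejections += est.p < alpha
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "rejection_rate": rejections / n_reps,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }


def bf_null_study(
    n_reps: int = 11,
    seed: int = 0,
    cohort_counts: tuple[int, int, int] = SMALL_COHORT,
    n_mc: int = 1500,
) -> dict:
    """Median Bayes factor per robustness-grid cell under a strong null."""
    cells: dict[tuple[float, bool], list[float]] = {}
    for rep in range(n_reps):
        s = _child_seed(seed, rep, 3)
        cohort = synth.generate_cohort(synth.CohortSpec(*cohort_counts, seed=s))
        trials, _ = synth.simulate_trial_table(
            cohort, _NULL_EFFECTS, _INTERCEPT_VC, seed=s, rt_violation_fraction=0.0
        )
        thermal = trials[trials.modality == "thermal"]
        results, _robust = bayes.bf_robustness(
            thermal, "intensity_latent", "placebo_condition", n_mc=n_mc, seed=s
        )
        for res in results:
            cells.setdefault((res.rscale, res.include_interaction), []).append(res.bf10)
    medians = {key: float(np.median(vals)) for key, vals in cells.items()}
    return {
        "n_reps": n_reps,
        "medians": medians,
        "max_median_bf10": max(medians.values()),
    }
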