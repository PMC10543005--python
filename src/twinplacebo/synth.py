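"""Synthetic twin cohorts, trial tables, signature volumes and contrast maps.

Everything downstream of this module (scoring, QC, the twin mixed model, the
Bayes-factor machinery, the individual-difference models) is exercised on data
generated here, with known ground truth.  The generator mirrors the structure
of the study being emulated:

* a cohort of monozygotic (MZ) twin pairs, dizygotic (DZ) twin pairs and
  singletons (defaults 142 / 160 / 93 individuals);
* a 3 (stimulus level) x 2 (modality) x 2 (placebo vs. control) within-
  participant factorial, 32 trials over 4 runs in control-placebo-placebo-
  control order, 4 thermal + 4 mechanical trials per run;
* outcomes built from a linear predictor on centred codes (level -0.5/0/+0.5,
  condition -0.5 control / +0.5 placebo) plus a family random draw shared
  within family, an individual draw whose SD depends on zygosity (DZ more
  variable than MZ), and iid residual noise;
* gLMS-style intensity and unpleasantness ratings in [0, 1];
* voxel volumes whose masked dot product with a planted signature recovers a
  requested score in expectation.

The generative scale of all outcomes is the z scale; ratings are an affine
map of the latent outcome into [0, 1] with clipping (the clipped fraction is
recorded).  Latent outcomes are kept in the table so parameter-recovery
simulations can fit the model on the exact generative scale.

Reproducibility: one root seed; child streams are spawned with
``numpy.random.SeedSequence(seed, spawn_key=...)`` where the spawn key encodes
the purpose (cohort, participant x run, volume), so adding participants or
runs never perturbs other streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "VarianceComponents",
    "EffectSpec",
    "SimulationLog",
    "generate_cohort",
    "simulate_trial_table",
    "simulate_cell_scores",
    "make_synthetic_signature",
    "simulate_contrast_maps",
    "LEVEL_CODES",
    "CONDITION_CODES",
    "RT_LOW",
    "RT_HIGH",
]

#: centred factorial codes used both for generation and for model fitting
LEVEL_CODES = {"low": -0.5, "medium": 0.0, "high": 0.5}
CONDITION_CODES = {"control": -0.5, "placebo": 0.5}

#: reaction-time validity window (seconds); ratings outside it are QC-dropped
RT_LOW = 0.02
RT_HIGH = 5.01

_RUN_CONDITION = {1: "control", 2: "placebo", 3: "placebo", 4: "control"}

# affine map from the latent z scale onto the gLMS [0, 1] scale
_GLMS_LOC = 0.22
_GLMS_SCALE = 0.10


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition in *individuals* (twins come in pairs)."""

    n_mz_individuals: int = 142
    n_dz_individuals: int = 160
    n_singletons: int = 93
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_individuals", "n_dz_individuals", "n_singletons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_mz_individuals % 2:
            raise ValueError("n_mz_individuals must be even: MZ twins come in pairs")
        if self.n_dz_individuals % 2:
            raise ValueError("n_dz_individuals must be even: DZ twins come in pairs")


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect structure over (intercept, level slope, placebo slope).

    ``family_cov`` is the covariance of the family-level draw, shared by both
    members of a twin pair.  Individual draws are diagonal with per-term SDs
    that differ by zygosity; DZ twins are more variable within family than MZ
    twins, which is the heteroskedasticity the fitted model targets.
    Singletons receive the family draw only: with one member per family an
    individual draw is not identifiable, so it is fixed at zero.
    """

    family_cov: np.ndarray = field(
        default_factory=lambda: np.diag([0.50**2, 0.15**2, 0.20**2])
    )
    sd_individual_mz: tuple[float, float, float] = (0.30, 0.10, 0.10)
    sd_individual_dz: tuple[float, float, float] = (0.45, 0.15, 0.15)
    sd_residual: float = 0.75

    def __post_init__(self) -> None:
        fam = np.asarray(self.family_cov, dtype=float)
        if fam.shape != (3, 3):
            raise ValueError("family_cov must be 3x3 over (intercept, level, placebo)")
        if not np.allclose(fam, fam.T):
            raise ValueError("family_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(fam)
        if eigvals.min() < -1e-10:
            raise ValueError("family_cov must be positive semidefinite")
        if any(s < 0 for s in self.sd_individual_mz + self.sd_individual_dz):
            raise ValueError("individual SDs must be nonnegative")
        if self.sd_residual < 0:
            raise ValueError("sd_residual must be nonnegative")


@dataclass(frozen=True)
class EffectSpec:
    """Fixed effects on the z-scored outcome scale, one tuple per modality.

    Order: (intercept, stimulus intensity, placebo, intensity x placebo).
    Defaults are the behavioural rating effects used as planted truth:
    thermal intensity 0.409 and placebo -0.359, mechanical 0.202 and -0.244,
    zero interaction.
    """

    thermal: tuple[float, float, float, float] = (0.0, 0.409, -0.359, 0.0)
    mechanical: tuple[float, float, float, float] = (0.0, 0.202, -0.244, 0.0)

    def __post_init__(self) -> None:
        for betas in (self.thermal, self.mechanical):
            if len(betas) != 4 or not np.all(np.isfinite(betas)):
                raise ValueError("each modality needs 4 finite betas")

    def betas(self, modality: str) -> np.ndarray:
        return np.asarray(getattr(self, modality), dtype=float)


@dataclass
class SimulationLog:
    """Bookkeeping emitted by :func:`simulate_trial_table`."""

    n_trials: int = 0
    clipped_fraction_intensity: float = 0.0
    clipped_fraction_unpleasantness: float = 0.0
    n_rt_violations_planted: int = 0


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator for ``key`` under the documented splitting rule."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Build the participant table: MZ/DZ pairs and singleton families.

    Returns a DataFrame with ``participant_id``, ``family_id`` and
    ``zygosity`` (MZ / DZ / singleton); ids are deterministic given the spec.
    """
    rows: list[tuple[str, str, str]] = []
    fam = 0
    pid = 0

    def _family(zygosity: str, size: int) -> None:
        nonlocal fam, pid
        fam += 1
        for _ in range(size):
            pid += 1
            rows.append((f"P{pid:04d}", f"F{fam:04d}", zygosity))

    for _ in range(spec.n_mz_individuals // 2):
        _family("MZ", 2)
    for _ in range(spec.n_dz_individuals // 2):
        _family("DZ", 2)
    for _ in range(spec.n_singletons):
        _family("singleton", 1)

    return pd.DataFrame(rows, columns=["participant_id", "family_id", "zygosity"])


def _level_schedule(participant_index: int, rng: np.random.Generator) -> dict[tuple[str, str], list[str]]:
    """Stimulus levels for the 8 trials of each modality x condition cell.

    8 trials cover 3 levels as 3+3+2; the short level rotates across
    participants so the cohort is balanced in aggregate.  Order within the
    cell is shuffled (split 4+4 over the cell's two runs downstream).
    """
    levels = ["low", "medium", "high"]
    schedule: dict[tuple[str, str], list[str]] = {}
    for m_i, modality in enumerate(("thermal", "mechanical")):
        for c_i, condition in enumerate(("control", "placebo")):
            short = levels[(participant_index + m_i + 2 * c_i) % 3]
            cell: list[str] = []
            for lv in levels:
                cell.extend([lv] * (2 if lv == short else 3))
            rng.shuffle(cell)
            schedule[(modality, condition)] = cell
    return schedule


def simulate_trial_table(
    cohort: pd.DataFrame,
    effects: EffectSpec | None = None,
    vc: VarianceComponents | None = None,
    seed: int = 0,
    *,
    rt_violation_fraction: float = 0.0047,
    sigma_unpleasantness: float = 0.35,
) -> tuple[pd.DataFrame, SimulationLog]:
    """Simulate the 32-trial factorial table for every participant.

    outcome = x'(beta + b_family + b_individual) + residual, where
    x = (1, level code, condition code) and the interaction enters through
    the fixed part only.  Latent outcomes are returned in
    ``intensity_latent`` / ``unpleasantness_latent``; the rating columns are
    the affine gLMS mapping clipped to [0, 1].

    A fraction ``rt_violation_fraction`` of trials (rounded to a count,
    chosen with a dedicated child stream) gets a reaction time planted
    outside the [0.02, 5.01] s validity window for QC testing.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    effects = effects or EffectSpec()
    vc = vc or VarianceComponents()
    log = SimulationLog()

    # PSD factor via eigendecomposition: exact for singular (or zero) matrices
    evals, evecs = np.linalg.eigh(np.asarray(vc.family_cov, float))
    fam_chol = evecs * np.sqrt(np.clip(evals, 0.0, None))
    ind_sd = {
        "MZ": np.asarray(vc.sd_individual_mz, float),
        "DZ": np.asarray(vc.sd_individual_dz, float),
        "singleton": np.zeros(3),
    }

    fam_draws: dict[str, np.ndarray] = {}
    for f_i, fid in enumerate(cohort["family_id"].unique()):
        rng = _child_rng(seed, 1, f_i)
        fam_draws[fid] = fam_chol @ rng.standard_normal(3)

    records: list[dict] = []
    for p_i, row in enumerate(cohort.itertuples(index=False)):
        rng_p = _child_rng(seed, 2, p_i)
        b_ind = ind_sd[row.zygosity] * rng_p.standard_normal(3)
        b_fam = fam_draws[row.family_id]
        schedule = _level_schedule(p_i, rng_p)
        cell_pos = {k: 0 for k in schedule}

        trial_index = 0
        for run in (1, 2, 3, 4):
            rng_run = _child_rng(seed, 3, p_i, run)
            condition = _RUN_CONDITION[run]
            modalities = ["thermal"] * 4 + ["mechanical"] * 4
            rng_run.shuffle(modalities)
            for modality in modalities:
                trial_index += 1
                key = (modality, condition)
                level = schedule[key][cell_pos[key]]
                cell_pos[key] += 1

                x = np.array([1.0, LEVEL_CODES[level], CONDITION_CODES[condition]])
                beta = effects.betas(modality)
                eta = (
                    x @ (beta[:3] + b_fam + b_ind)
                    + beta[3] * x[1] * x[2]
                    + vc.sd_residual * rng_run.standard_normal()
                )
                unp = eta + sigma_unpleasantness * rng_run.standard_normal()
                rt = float(np.clip(rng_run.lognormal(0.3, 0.35), 0.25, 4.8))
                records.append(
                    {
                        "participant_id": row.participant_id,
                        "family_id": row.family_id,
                        "zygosity": row.zygosity,
                        "run": run,
                        "trial_index": trial_index,
                        "modality": modality,
                        "condition": condition,
                        "stimulus_level": level,
                        "intensity_latent": eta,
                        "unpleasantness_latent": unp,
                        "rt_intensity": rt,
                    }
                )

    table = pd.DataFrame.from_records(records)

    for col in ("intensity", "unpleasantness"):
        raw = _GLMS_LOC + _GLMS_SCALE * table[f"{col}_latent"]
        clipped = raw.clip(0.0, 1.0)
        setattr(
            log,
            f"clipped_fraction_{col}",
            float((raw != clipped).mean()),
        )
        table[f"{col}_rating"] = clipped

    # plant RT violations for QC testing
    n_out = int(round(rt_violation_fraction * len(table)))
    if n_out:
        rng_v = _child_rng(seed, 4)
        idx = rng_v.choice(len(table), size=n_out, replace=False)
        half = n_out // 2
        table.loc[table.index[idx[:half]], "rt_intensity"] = RT_LOW / 2.0
        table.loc[table.index[idx[half:]], "rt_intensity"] = RT_HIGH + 0.5
    log.n_rt_violations_planted = n_out
    log.n_trials = len(table)
    return table, log


def simulate_cell_scores(
    cohort: pd.DataFrame,
    effects: EffectSpec,
    vc: VarianceComponents,
    seed: int,
    marker: str = "marker",
) -> pd.DataFrame:
    """Per participant x modality x condition x level latent marker scores.

    The cell-level analogue of :func:`simulate_trial_table`: one score per
    condition cell (12 per participant), built from the same fixed + family +
    zygosity-specific individual + residual structure.  These serve as the
    target scores planted into voxel maps by :func:`simulate_contrast_maps`.
    """
    trials, _ = simulate_trial_table(
        cohort, effects, vc, seed=seed, rt_violation_fraction=0.0
    )
    cells = (
        trials.groupby(
            ["participant_id", "family_id", "zygosity", "modality", "condition", "stimulus_level"],
            as_index=False, sort=False,
        )["intensity_latent"]
        .mean()
        .rename(columns={"intensity_latent": "score"})
    )
    cells["marker"] = marker
    return cells


def simulate_expectations(
    cohort: pd.DataFrame, seed: int = 0, mean: float = 65.0, sd: float = 18.0
) -> pd.DataFrame:
    """Pre-scan expected-efficacy ratings on the 0-100 scale, one per person."""
    rng = _child_rng(seed, 5)
    vals = np.clip(mean + sd * rng.standard_normal(len(cohort)), 0.0, 100.0)
    return pd.DataFrame(
        {"participant_id": cohort["participant_id"], "expected_efficacy": vals}
    )


# ---------------------------------------------------------------------------
# volumes


def make_synthetic_signature(
    grid_dims: tuple[int, int, int] = (16, 16, 16),
    n_pos_subregions: int = 2,
    n_neg_subregions: int = 6,
    seed: int = 0,
    *,
    affine: np.ndarray | None = None,
):
    """Synthetic signature weight volume with signed, disjoint subregions.

    Stand-in for an external neuromarker weight map (e.g. an NPS- or
    SIIPS-like pattern): cubic subregions are placed on a coarse lattice so
    they cannot overlap, positive-labelled regions carry all-positive
    weights, negative-labelled regions all-negative weights.  Returns a
    :class:`twinplacebo.scoring.SignatureMap`.
    """
    from .scoring import SignatureMap

    dims = tuple(int(d) for d in grid_dims)
    if any(d < 8 for d in dims):
        raise ValueError("grid_dims must be at least (8, 8, 8)")
    n_regions = n_pos_subregions + n_neg_subregions
    block = 4  # subregion bounding cube, voxels
    lattice = [d // block for d in dims]
    capacity = int(np.prod(lattice))
    if n_regions > capacity:
        raise ValueError(
            f"{n_regions} subregions do not fit disjointly in grid {dims} "
            f"(capacity {capacity})"
        )

    rng = _child_rng(seed, 10)
    slots = rng.choice(capacity, size=n_regions, replace=False)
    weights = np.zeros(dims, dtype=np.float32)
    labels = np.zeros(dims, dtype=np.int16)
    signs: dict[int, int] = {}
    for label, slot in enumerate(slots, start=1):
        sign = 1 if label <= n_pos_subregions else -1
        i, j, k = np.unravel_index(slot, lattice)
        sl = (
            slice(i * block, i * block + 3),
            slice(j * block, j * block + 3),
            slice(k * block, k * block + 3),
        )
        w = rng.uniform(0.2, 1.0, size=(3, 3, 3)).astype(np.float32)
        weights[sl] = sign * w
        labels[sl] = label
        signs[label] = sign

    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return SignatureMap(
        values=weights,
        affine=np.asarray(affine, float),
        mask=labels > 0,
        subregions=labels,
        subregion_signs=signs,
    )


def simulate_contrast_maps(
    cell_scores: pd.DataFrame,
    signature,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[tuple, "np.ndarray"]:
    """One volume per condition cell, with the signature score planted.

    Each map is ``signature.weights * (target / ||w||^2)`` plus iid voxel
    noise, so the masked dot product with the signature recovers the target
    score in expectation (exactly when ``noise_sd`` is 0).

    Returns a dict keyed by (participant_id, modality, condition, level)
    mapping to :class:`twinplacebo.scoring.VolumeMap`.
    """
    from .scoring import VolumeMap

    w = np.asarray(signature.weights, dtype=float)
    wnorm2 = float(np.sum(w[signature.mask] ** 2))
    if wnorm2 <= 0:
        raise ValueError("signature has zero weight norm inside its mask")

    maps: dict[tuple, VolumeMap] = {}
    for m_i, row in enumerate(cell_scores.itertuples(index=False)):
        rng = _child_rng(seed, 11, m_i)
        values = w * (row.score / wnorm2)
        if noise_sd > 0:
            values = values + noise_sd * rng.standard_normal(w.shape)
        key = (row.participant_id, row.modality, row.condition, row.stimulus_level)
        maps[key] = VolumeMap(
            values=values.astype(np.float32),
            affine=signature.affine.copy(),
            mask=signature.mask.copy(),
        )
    return maps


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_signature(signature, directory: str | Path, name: str = "signature") -> None:
    """Persist a signature as NIfTI weights + integer atlas + JSON legend."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(np.asarray(signature.weights, np.float32), signature.affine),
        directory / f"{name}_weights.nii",
    )
    nib.save(
        nib.Nifti1Image(np.asarray(signature.subregions, np.int16), signature.affine),
        directory / f"{name}_atlas.nii",
    )
    legend = {str(k): int(v) for k, v in signature.subregion_signs.items()}
    (directory / f"{name}_legend.json").write_text(json.dumps(legend, indent=2))
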