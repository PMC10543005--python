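"""Individual-difference analyses: placebo contrasts and twin-LMM correlations.

For each participant, modality and stimulus level, *behavioral analgesia* is
the control-minus-placebo difference in mean rating and *neural reduction*
is the same difference in a marker score; both are z-scored across
participants within modality.  A nonparametric variant replaces the raw
differences with their rank (ties averaged) within each modality x level
cell.  Brain-behavior, expectation and cross-modality transfer correlations
are then slopes in the same heteroskedastic twin mixed model (family and
zygosity-split participant random effects) rather than plain correlations,
so the familial structure is respected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import twinlmm
from .scoring import zscore_within

__all__ = [
    "participant_contrasts",
    "brain_behavior_model",
    "expectation_model",
    "transfer_model",
]

_ID_COLS = ["participant_id", "family_id", "zygosity"]


def _cell_means(
    trials: pd.DataFrame, value_col: str, out_name: str
) -> pd.DataFrame:
    keys = _ID_COLS + ["modality", "stimulus_level", "condition"]
    cells = trials.groupby(keys, as_index=False, sort=False)[value_col].mean()
    wide = cells.pivot_table(
        index=_ID_COLS + ["modality", "stimulus_level"],
        columns="condition",
        values=value_col,
        aggfunc="first",
    ).reset_index()
    # a participant missing one condition in a cell contributes no contrast
    wide = wide.dropna(subset=["control", "placebo"])
    wide[out_name] = wide["control"] - wide["placebo"]
    return wide.drop(columns=["control", "placebo"])


def participant_contrasts(
    trials: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    rating_col: str = "intensity_rating",
) -> pd.DataFrame:
    """Per-participant control-minus-placebo contrasts, z-scored and ranked.

    ``trials`` is a QC-passed trial table; ``scores`` (optional) is a tidy
    score table (participant_id, modality, condition, stimulus_level,
    marker, score) as produced by the scoring stage.  Output has one row per
    participant x modality x level with ``behavioral_analgesia`` plus one
    ``neural_reduction_<marker>`` column per marker, each z-scored across
    participants within modality, and rank variants (``*_rank``) ranked
    within modality x level with ties averaged.
    """
    out = _cell_means(trials, rating_col, "behavioral_analgesia")
    value_cols = ["behavioral_analgesia"]

    if scores is not None:
        for marker, sub in scores.groupby("marker", sort=False):
            sub = sub.merge(
                trials[_ID_COLS].drop_duplicates(), on="participant_id", how="inner"
            )
            col = f"neural_reduction_{marker}"
            wide = _cell_means(
                sub.rename(columns={"score": "value"}), "value", col
            )
            out = out.merge(
                wide, on=_ID_COLS + ["modality", "stimulus_level"], how="inner"
            )
            value_cols.append(col)

    for col in value_cols:
        out[f"{col}_rank"] = out.groupby(["modality", "stimulus_level"], sort=False)[
            col
        ].transform(lambda s: rankdata(s, method="average"))
        out = zscore_within(out, ["modality"], value_col=col)
    return out


def _contrast_model(
    contrasts: pd.DataFrame,
    outcome: str,
    predictor: str,
    modality: str,
    seed: int = 0,
) -> twinlmm.FixedEffectEstimate:
    sub = contrasts[contrasts["modality"] == modality].dropna(
        subset=[outcome, predictor]
    )
    if sub["family_id"].nunique() < 2:
        raise ValueError("need contrasts from at least 2 families")
    spec = twinlmm.ModelSpec(
        outcome=outcome,
        fixed=("stimulus_level", predictor),
    )
    fit = twinlmm.fit_reml(twinlmm.encode_design(sub, spec), seed=seed)
    return twinlmm.test_fixed_effect(fit, predictor)


def brain_behavior_model(
    contrasts: pd.DataFrame,
    marker: str,
    modality: str = "thermal",
    use_ranks: bool = False,
    seed: int = 0,
) -> twinlmm.FixedEffectEstimate:
    """Slope of neural reduction on behavioral analgesia, twin LMM.

    Model: neural reduction ~ 1 + stimulus level + behavioral analgesia,
    with the family and zygosity-split participant random structure over the
    same terms.  ``use_ranks`` switches both sides to the within-cell ranks
    (the Spearman-flavoured robustness variant).
    """
    suffix = "_rank" if use_ranks else ""
    return _contrast_model(
        contrasts,
        outcome=f"neural_reduction_{marker}{suffix}",
        predictor=f"behavioral_analgesia{suffix}",
        modality=modality,
        seed=seed,
    )


def expectation_model(
    contrasts: pd.DataFrame,
    expectations: pd.DataFrame,
    outcome: str = "behavioral_analgesia",
    modality: str = "thermal",
    seed: int = 0,
) -> twinlmm.FixedEffectEstimate:
    """Slope of the placebo contrast on pre-scan expected efficacy.

    ``expectations`` has one row per participant with ``expected_efficacy``
    on the 0-100 scale; it is z-scored within modality before entering the
    model as the individual-difference predictor.
    """
    exp = expectations[["participant_id", "expected_efficacy"]].copy()
    if (exp["expected_efficacy"] < 0).any() or (exp["expected_efficacy"] > 100).any():
        raise ValueError("expected_efficacy must lie in [0, 100]")
    if exp["participant_id"].duplicated().any():
        raise ValueError("one expectation rating per participant")
    merged = contrasts.merge(exp, on="participant_id", how="inner")
    if merged.loc[merged["modality"] == modality, "expected_efficacy"].nunique() < 2:
        raise ValueError("expectations are constant; cannot z-score")
    merged = zscore_within(
        merged, ["modality"], value_col="expected_efficacy", out_col="expectation_z"
    )
    return _contrast_model(
        merged, outcome=outcome, predictor="expectation_z", modality=modality, seed=seed
    )


def transfer_model(
    contrasts: pd.DataFrame,
    outcome: str = "behavioral_analgesia",
    seed: int = 0,
) -> twinlmm.FixedEffectEstimate:
    """Cross-modality transfer: mechanical contrast on the thermal contrast.

    The thermal placebo contrast (averaged over that participant's levels)
    predicts the mechanical contrast, with the full family + zygosity-split
    participant random structure.
    """
    thermal = (
        contrasts[contrasts["modality"] == "thermal"]
        .groupby("participant_id", as_index=False, sort=False)[outcome]
        .mean()
        .rename(columns={outcome: "thermal_contrast"})
    )
    mech = contrasts[contrasts["modality"] == "mechanical"].merge(
        thermal, on="participant_id", how="inner"
    )
    spec = twinlmm.ModelSpec(
        outcome=outcome,
        fixed=("stimulus_level", "thermal_contrast"),
    )
    sub = mech.dropna(subset=[outcome, "thermal_contrast"])
    fit = twinlmm.fit_reml(twinlmm.encode_design(sub, spec), seed=seed)
    return twinlmm.test_fixed_effect(fit, "thermal_contrast")
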