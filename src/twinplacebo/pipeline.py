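"""End-to-end orchestration: simulate -> score -> qc -> fit -> bf -> correlate -> report.

A :class:`RunConfig` (YAML-loadable, schema-checked) drives the whole run.
Every output file is stamped with the config hash and the seed, and the run
is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, correl, qc, report, scoring, synth, twinlmm

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("twinplacebo")


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    # simulation (scaled default cohort; the full study composition is
    # 142/160/93 and can be requested explicitly)
    n_mz_individuals: int = 48
    n_dz_individuals: int = 54
    n_singletons: int = 30
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_pos_subregions: int = 2
    n_neg_subregions: int = 6
    map_noise_sd: float = 0.002
    # optional externally supplied inputs (paths); simulated when absent
    trial_table_path: str | None = None
    signature_dir: str | None = None
    # modelling
    alpha: float = 0.05
    markers: tuple[str, ...] = ("nps_like", "siips_like")
    bf_rscales: tuple[float, ...] = bayes.RSCALE_GRID
    bf_n_mc: int = 2000
    comparison_sets: dict[str, int] = field(default_factory=lambda: dict(report.DEFAULT_SETS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_mz_individuals % 2 or self.n_dz_individuals % 2:
            raise ValueError("twin counts must be even")
        if self.bf_n_mc < 100:
            raise ValueError("bf_n_mc too small for a usable error estimate")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


#: marker-level fixed effects planted into the synthetic cell scores
_MARKER_EFFECTS = {
    # an intensity-tracking marker with no placebo response
    "nps_like": synth.EffectSpec(
        thermal=(0.8, 0.245, -0.030, 0.0), mechanical=(0.7, 0.164, 0.008, 0.0)
    ),
    # a higher-level marker that does respond to placebo
    "siips_like": synth.EffectSpec(
        thermal=(0.3, 0.181, -0.129, 0.0), mechanical=(0.3, 0.150, -0.100, 0.0)
    ),
}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage naming contract
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig):
    cohort = synth.generate_cohort(
        synth.CohortSpec(
            cfg.n_mz_individuals, cfg.n_dz_individuals, cfg.n_singletons, seed=cfg.seed
        )
    )
    if cfg.trial_table_path:
        trials = pd.read_csv(cfg.trial_table_path)
    else:
        trials, _ = synth.simulate_trial_table(cohort, seed=cfg.seed)
    cell_scores = {
        marker: synth.simulate_cell_scores(
            cohort, _MARKER_EFFECTS[marker], synth.VarianceComponents(),
            seed=cfg.seed + 1000 + i, marker=marker,
        )
        for i, marker in enumerate(cfg.markers)
    }
    expectations = synth.simulate_expectations(cohort, seed=cfg.seed)
    return cohort, trials, cell_scores, expectations


@_stage("score")
def _score(cfg: RunConfig, cell_scores) -> pd.DataFrame:
    if cfg.signature_dir:
        sig_dir = Path(cfg.signature_dir)
        if not sig_dir.exists():
            raise FileNotFoundError(f"signature path {sig_dir} does not exist")
        signature = scoring.load_signature(sig_dir)
    else:
        signature = synth.make_synthetic_signature(
            cfg.grid_dims, cfg.n_pos_subregions, cfg.n_neg_subregions, seed=cfg.seed
        )
    rows = []
    for marker, cells in cell_scores.items():
        maps = synth.simulate_contrast_maps(
            cells, signature, noise_sd=cfg.map_noise_sd, seed=cfg.seed + 77
        )
        for (pid, modality, condition, level), vmap in maps.items():
            rows.append(
                {
                    "participant_id": pid,
                    "modality": modality,
                    "condition": condition,
                    "stimulus_level": level,
                    "marker": marker,
                    "score": scoring.signature_score(vmap, signature),
                }
            )
    return pd.DataFrame(rows)


@_stage("qc")
def _qc(trials: pd.DataFrame):
    return qc.run_qc(trials)


@_stage("fit")
def _fit(cfg: RunConfig, trials: pd.DataFrame, scores: pd.DataFrame) -> list[dict]:
    rows: list[dict] = []

    def add(outcome_table, outcome, marker, modality, set_name):
        sub = outcome_table[outcome_table["modality"] == modality]
        sub = scoring.zscore_within(sub, ["modality"], value_col=outcome)
        rep = twinlmm.interaction_protocol(sub, outcome, alpha=cfg.alpha, seed=cfg.seed)
        for term, est in rep.estimates.items():
            if term == "intercept":
                continue
            rows.append(
                report.estimate_row(marker, modality, est, set_name, rep.source[term])
            )

    for modality in ("thermal", "mechanical"):
        add(trials.copy(), "intensity_rating", "ratings", modality, "single")
    for marker in cfg.markers:
        marker_scores = scores[scores["marker"] == marker].copy()
        merged = marker_scores.merge(
            trials[["participant_id", "family_id", "zygosity"]].drop_duplicates(),
            on="participant_id",
        )
        for modality in ("thermal", "mechanical"):
            add(merged, "score", marker, modality, "single")
    return rows


@_stage("bf")
def _bf(cfg: RunConfig, trials: pd.DataFrame, scores: pd.DataFrame) -> list[dict]:
    rows = []
    for marker in cfg.markers:
        sub = scores[scores["marker"] == marker].merge(
            trials[["participant_id", "family_id", "zygosity"]].drop_duplicates(),
            on="participant_id",
        )
        sub = sub[sub["modality"] == "thermal"]
        res = bayes.bf_fixed_effect(
            sub, "score", "placebo_condition",
            n_mc=cfg.bf_n_mc, seed=cfg.seed,
        )
        label, odds = bayes.interpret_bf(res.bf10)
        rows.append(
            {
                "marker": marker,
                "modality": "thermal",
                "effect": "placebo_condition",
                "bf10": res.bf10,
                "proportional_error_pct": 100.0 * res.proportional_error,
                "rscale": res.rscale,
                "n_mc": res.n_mc,
                "seed": res.seed,
                "label": label,
                "odds": odds,
            }
        )
    return rows


@_stage("correlate")
def _correlate(cfg: RunConfig, trials, scores, expectations) -> list[dict]:
    contrasts = correl.participant_contrasts(trials, scores)
    rows = []
    for marker in cfg.markers:
        for modality in ("thermal", "mechanical"):
            est = correl.brain_behavior_model(
                contrasts, marker, modality=modality, seed=cfg.seed
            )
            rows.append(report.estimate_row(f"{marker}~analgesia", modality, est))
    est = correl.expectation_model(contrasts, expectations, seed=cfg.seed)
    rows.append(report.estimate_row("analgesia~expectation", "thermal", est))
    est = correl.transfer_model(contrasts, seed=cfg.seed)
    rows.append(report.estimate_row("transfer", "mechanical", est))
    return rows


@_stage("report")
def _report(cfg: RunConfig, out: Path, stamp: str, fit_rows, bf_rows, corr_rows, qc_log):
    report.write_report(
        fit_rows, cfg.comparison_sets, cfg.alpha,
        csv_path=out / "fits.csv", md_path=out / "fits.md", header_comment=stamp,
    )
    report.write_report(
        corr_rows, cfg.comparison_sets, cfg.alpha,
        csv_path=out / "correlations.csv", header_comment=stamp,
    )
    bf_df = pd.DataFrame(bf_rows)
    with open(out / "bayes_factors.csv", "w") as fh:
        fh.write(f"# {stamp}\n")
        bf_df.to_csv(fh, index=False)
    qc_log.to_json(out / "exclusions.json")
    (out / "run.json").write_text(json.dumps({"stamp": stamp}, indent=2))


STAGES = ("simulate", "glm", "score", "qc", "fit", "bf", "correlate", "report")


@_stage("glm")
def _glm_demo(cfg: RunConfig, out: Path, stamp: str) -> None:
    """Tiny single-run first-level demonstration: design legend + betas."""
    from . import glm as glm_mod

    config = glm_mod.GLMConfig(n_volumes=240)
    events = pd.DataFrame(
        {
            "onset": [20.0, 50.0, 80.0],
            "duration": [10.0, 10.0, 10.0],
            "trial_type": [
                "stim_thermal_control_low",
                "stim_thermal_placebo_medium",
                "stim_thermal_control_high",
            ],
        }
    )
    design, names = glm_mod.build_design_matrix(events, config)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(55,)))
    beta_true = rng.standard_normal((8, design.shape[1]))
    data = beta_true @ design.T + 0.1 * rng.standard_normal((8, design.shape[0]))
    fit = glm_mod.fit_glm(data, design, names)
    with open(out / "glm_demo_betas.csv", "w") as fh:
        fh.write(f"# {stamp}\n")
        pd.DataFrame(fit.betas, columns=names).to_csv(fh, index=False)


def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig, stop_after: str = "report") -> Path:
    """Execute the stages in order; returns the output directory.

    ``stop_after`` names the last stage to run (one of ``STAGES``); earlier
    stages always run, so any stage command is reproducible in isolation.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={cfg.hash()} seed={cfg.seed}"
    log.info("run %s", stamp)
    rank = STAGES.index(stop_after)

    cohort, trials, cell_scores, expectations = _simulate(cfg)
    _write_csv(trials, out / "trials_raw.csv", stamp)
    if rank < STAGES.index("glm"):
        return out
    _glm_demo(cfg, out, stamp)
    if rank < STAGES.index("score"):
        return out

    scores = _score(cfg, cell_scores)
    _write_csv(scores, out / "scores.csv", stamp)
    if rank < STAGES.index("qc"):
        return out

    trials_qc, qc_log = _qc(trials)
    qc_log.to_json(out / "exclusions.json")
    _write_csv(trials_qc, out / "trials.csv", stamp)
    scores = scores[scores["participant_id"].isin(trials_qc["participant_id"].unique())]
    if rank < STAGES.index("fit"):
        return out

    fit_rows = _fit(cfg, trials_qc, scores)
    if rank < STAGES.index("bf"):
        report.write_report(
            fit_rows, cfg.comparison_sets, cfg.alpha,
            csv_path=out / "fits.csv", header_comment=stamp,
        )
        return out
    bf_rows = _bf(cfg, trials_qc, scores)
    if rank < STAGES.index("correlate"):
        _write_csv(pd.DataFrame(bf_rows), out / "bayes_factors.csv", stamp)
        return out
    corr_rows = _correlate(cfg, trials_qc, scores, expectations)
    _report(cfg, out, stamp, fit_rows, bf_rows, corr_rows, qc_log)
    return out
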