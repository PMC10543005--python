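"""Brain-behavior, expectation and cross-modality transfer correlations.

Builds per-participant control-minus-placebo contrasts (z-scored within
modality, plus within-cell rank variants), then fits the twin-LMM slope of:
neural reduction on behavioral analgesia (per marker and modality, linear
and rank-based), behavioral analgesia on pre-scan expected efficacy, and
the mechanical placebo contrast on the thermal one (transfer).  Exports the
per-participant scatter data alongside the model table.
"""

import importlib.util
import sys
import warnings
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "cfg", Path(__file__).parent / "00_config.py"
)
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from twinplacebo import correl, report


def main() -> None:
    warnings.filterwarnings("ignore", message="singular REML")
    trials = pd.read_csv(cfg.RESULTS / "trials.csv")
    scores = pd.read_csv(cfg.RESULTS / "scores.csv")
    expectations = pd.read_csv(cfg.RESULTS / "expectations.csv")

    contrasts = correl.participant_contrasts(trials, scores)
    contrasts.to_csv(cfg.RESULTS / "participant_contrasts.csv", index=False)

    rows = []
    for marker in scores["marker"].unique():
        for modality in ("thermal", "mechanical"):
            est = correl.brain_behavior_model(contrasts, marker, modality, seed=cfg.SEED)
            rows.append(report.estimate_row(f"{marker}~analgesia", modality, est))
            est_rank = correl.brain_behavior_model(
                contrasts, marker, modality, use_ranks=True, seed=cfg.SEED
            )
            rows.append(report.estimate_row(f"{marker}~analgesia(rank)", modality, est_rank))
            print(f"{marker:12s} {modality:10s} brain~behavior: "
                  f"beta={est.beta:+.3f} p={est.p:.4f} (rank beta={est_rank.beta:+.3f})")

    for modality in ("thermal", "mechanical"):
        est = correl.expectation_model(contrasts, expectations, modality=modality, seed=cfg.SEED)
        rows.append(report.estimate_row("analgesia~expectation", modality, est))
        print(f"expectation  {modality:10s} beta={est.beta:+.3f} p={est.p:.4f}")

    est = correl.transfer_model(contrasts, seed=cfg.SEED)
    rows.append(report.estimate_row("transfer(thermal->mechanical)", "mechanical", est))
    print(f"transfer: beta={est.beta:+.3f} p={est.p:.4f}")

    report.write_report(rows, csv_path=cfg.RESULTS / "correlations.csv",
                        header_comment=f"seed={cfg.SEED}")
    print("wrote results/correlations.csv and results/participant_contrasts.csv")


if __name__ == "__main__":
    sys.exit(main())
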