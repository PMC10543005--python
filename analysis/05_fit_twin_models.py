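"""Fit the heteroskedastic twin mixed models per outcome and modality.

For the behavioural ratings and each planted marker, z-scores the outcome
within modality, runs the interaction-then-mains protocol (report mains
from the reduced model when the level x placebo interaction is not
significant), and writes the report table with within-set Bonferroni flags.
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

from twinplacebo import report, twinlmm
from twinplacebo.scoring import zscore_within


def main() -> None:
    warnings.filterwarnings("ignore", message="singular REML")
    trials = pd.read_csv(cfg.RESULTS / "trials.csv")
    scores = pd.read_csv(cfg.RESULTS / "scores.csv")
    ids = trials[["participant_id", "family_id", "zygosity"]].drop_duplicates()
    scores = scores.merge(ids, on="participant_id")

    rows = []

    def fit_one(table, outcome, marker, modality):
        sub = table[table["modality"] == modality]
        sub = zscore_within(sub, ["modality"], value_col=outcome)
        rep = twinlmm.interaction_protocol(sub, outcome, seed=cfg.SEED)
        for term, est in rep.estimates.items():
            if term == "intercept":
                continue
            rows.append(report.estimate_row(marker, modality, est, "single", rep.source[term]))
        placebo = rep.estimates["placebo_condition"]
        print(f"{marker:12s} {modality:10s} placebo: beta={placebo.beta:+.3f} "
              f"SE={placebo.se:.3f} t({placebo.df:.1f})={placebo.t:+.2f} p={placebo.p:.4f}")

    for modality in ("thermal", "mechanical"):
        fit_one(trials, "intensity_rating", "ratings", modality)
    for marker in scores["marker"].unique():
        sub = scores[scores["marker"] == marker]
        for modality in ("thermal", "mechanical"):
            fit_one(sub, "score", marker, modality)

    df = report.write_report(rows, csv_path=cfg.RESULTS / "fits.csv",
                             md_path=cfg.RESULTS / "fits.md",
                             header_comment=f"seed={cfg.SEED}")
    print(f"wrote {len(df)} rows -> results/fits.csv")


if __name__ == "__main__":
    sys.exit(main())
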