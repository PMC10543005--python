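"""Report tables: estimate rows with within-set Bonferroni flags.

Every region or marker belongs to an a priori multiple-comparison set (the
nociceptive regions, the signature subregions, the higher-level regions);
each reported row carries the uncorrected two-sided p value plus a pass/fail
flag against the Bonferroni threshold alpha / (set size).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .twinlmm import FixedEffectEstimate

__all__ = ["REPORT_COLUMNS", "estimate_row", "write_report", "DEFAULT_SETS"]

REPORT_COLUMNS = [
    "marker",
    "modality",
    "effect",
    "estimate",
    "ci_lo",
    "ci_hi",
    "se",
    "t",
    "df",
    "p",
    "set",
    "uncorrected_significant",
    "bonferroni_threshold",
    "bonferroni_pass",
    "model_source",
]

#: a priori multiple-comparison set sizes
DEFAULT_SETS = {
    "nociceptive": 7,
    "siips_subregions": 8,
    "higher_level": 10,
    "single": 1,
}


def estimate_row(
    marker: str,
    modality: str,
    est: FixedEffectEstimate,
    set_name: str = "single",
    model_source: str = "reduced",
) -> dict:
    return {
        "marker": marker,
        "modality": modality,
        "effect": est.term,
        "estimate": est.beta,
        "ci_lo": est.ci95[0],
        "ci_hi": est.ci95[1],
        "se": est.se,
        "t": est.t,
        "df": est.df,
        "p": est.p,
        "set": set_name,
        "model_source": model_source,
    }


def write_report(
    rows: list[dict] | pd.DataFrame,
    sets: dict[str, int] | None = None,
    alpha: float = 0.05,
    csv_path: str | Path | None = None,
    md_path: str | Path | None = None,
    header_comment: str | None = None,
) -> pd.DataFrame:
    """Assemble the report table and optionally write CSV / Markdown.

    ``sets`` maps set names to set sizes; each row's Bonferroni threshold is
    alpha / size of its set.  An empty input yields an empty table with the
    full header.
    """
    sets = {**DEFAULT_SETS, **(sets or {})}
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    if df.empty:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    else:
        unknown = set(df["set"]) - set(sets)
        if unknown:
            raise KeyError(f"unknown comparison sets {sorted(unknown)}")
        df["uncorrected_significant"] = df["p"] < alpha
        df["bonferroni_threshold"] = df["set"].map(lambda s: alpha / sets[s])
        df["bonferroni_pass"] = df["p"] < df["bonferroni_threshold"]
        df = df.reindex(columns=REPORT_COLUMNS)

    if csv_path is not None:
        with open(csv_path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
    if md_path is not None:
        with open(md_path, "w") as fh:
            if header_comment:
                fh.write(f"<!-- {header_comment} -->\n\n")
            fh.write(df.to_markdown(index=False))
            fh.write("\n")
    return df
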