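"""Score synthetic contrast maps against the signature.

Plants per-cell marker scores with the twin generative structure into voxel
maps, recovers them by masked dot product, and writes the tidy score table.
Two markers are planted: an intensity-tracking one with no placebo response
(NPS-like) and a placebo-responsive one (SIIPS-like).
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

spec = importlib.util.spec_from_file_location(
    "cfg", Path(__file__).parent / "00_config.py"
)
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from twinplacebo import scoring, synth
from twinplacebo.pipeline import _MARKER_EFFECTS


def main() -> None:
    cohort = synth.generate_cohort(synth.CohortSpec(*cfg.COHORT, seed=cfg.SEED))
    signature = scoring.load_signature(cfg.RESULTS, "signature")

    rows = []
    for i, (marker, effects) in enumerate(_MARKER_EFFECTS.items()):
        cells = synth.simulate_cell_scores(
            cohort, effects, synth.VarianceComponents(), seed=cfg.SEED + 1000 + i,
            marker=marker,
        )
        maps = synth.simulate_contrast_maps(
            cells, signature, noise_sd=0.002, seed=cfg.SEED + 77
        )
        recovered = []
        for row in cells.itertuples(index=False):
            key = (row.participant_id, row.modality, row.condition, row.stimulus_level)
            score = scoring.signature_score(maps[key], signature)
            recovered.append(score)
            rows.append(
                dict(participant_id=row.participant_id, modality=row.modality,
                     condition=row.condition, stimulus_level=row.stimulus_level,
                     marker=marker, score=score)
            )
        err = np.abs(np.asarray(recovered) - cells["score"].to_numpy())
        print(f"{marker}: {len(cells)} cell maps scored; "
              f"mean |recovery error| = {err.mean():.4f} (voxel noise SD 0.002)")

    pd.DataFrame(rows).to_csv(cfg.RESULTS / "scores.csv", index=False)
    print(f"wrote {len(rows)} scores -> results/scores.csv")


if __name__ == "__main__":
    sys.exit(main())
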