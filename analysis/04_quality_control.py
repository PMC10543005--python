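"""Apply the trial- and participant-level exclusion rules.

Reads the raw trial table, drops trials with intensity-rating reaction
times outside (0.02, 5.01) s, then drops participants lacking two stimulus
levels in any modality x condition cell; writes the cleaned table and the
exclusion log.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "cfg", Path(__file__).parent / "00_config.py"
)
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from twinplacebo import qc


def main() -> None:
    trials = pd.read_csv(cfg.RESULTS / "trials_raw.csv")
    kept, log = qc.run_qc(trials)
    kept.to_csv(cfg.RESULTS / "trials.csv", index=False)
    log.to_json(cfg.RESULTS / "exclusions.json")
    for line in log.lines():
        print(line)


if __name__ == "__main__":
    sys.exit(main())
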