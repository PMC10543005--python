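"""Operating characteristics of the twin model and the Bayes factors.

Quick-look versions of the validation studies (full-size runs live in the
test suite and scripts/acceptance.py): planted-effect recovery with CI
coverage, type-I error under the null, and the null Bayes-factor grid.
"""

import importlib.util
import json
import sys
import warnings
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "cfg", Path(__file__).parent / "00_config.py"
)
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from twinplacebo import simstudies


def main() -> None:
    warnings.filterwarnings("ignore")
    rec = simstudies.recovery_study(n_reps=25, seed=cfg.SEED)
    print(f"recovery ({rec['n_reps']} cohorts): planted {rec['planted']}, "
          f"mean estimate {rec['mean_estimate']:.3f} (MC SE {rec['mc_se']:.3f}), "
          f"CI coverage {rec['coverage']:.0%}")
    t1 = simstudies.type1_study(n_reps=200, seed=cfg.SEED + 1)
    print(f"type-I ({t1['n_reps']} null cohorts): rejection rate "
          f"{t1['rejection_rate']:.3f} at alpha {t1['alpha']}")
    bf = simstudies.bf_null_study(n_reps=3, seed=cfg.SEED + 2)
    print(f"null BFs ({bf['n_reps']} cohorts): max median BF10 across grid "
          f"= {bf['max_median_bf10']:.3f} (want < 1/3)")

    out = {
        "recovery": rec,
        "type1": t1,
        "bf_null": {"max_median_bf10": bf["max_median_bf10"]},
    }
    (cfg.RESULTS / "operating_characteristics.json").write_text(
        json.dumps(out, indent=2, default=str) + "\n"
    )
    print("wrote results/operating_characteristics.json")


if __name__ == "__main__":
    sys.exit(main())
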