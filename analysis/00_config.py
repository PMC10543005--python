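"""Shared settings for the numbered analysis scripts.

A scaled cohort (48 MZ / 54 DZ / 30 singleton individuals, preserving the
study's MZ:DZ:singleton mix) keeps every script interactive-fast; the full
composition (142/160/93) can be swapped in by editing COHORT.
"""

from pathlib import Path

SEED = 7
COHORT = (48, 54, 30)  # individuals: MZ, DZ, singletons
RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)
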