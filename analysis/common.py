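"""Shared study configuration for the numbered analysis scripts.

All scripts operate on the same deterministic synthetic cohort (n=100,
seed 17, default generator conditions) and exchange intermediates as
CSV/JSON under results/.  Volumes are regenerated from the seed where a
script needs voxel data; everything else flows through the text artifacts.
"""

from pathlib import Path

from habitatvpi import phantom as ph
from habitatvpi import pipeline as pl
from habitatvpi import preprocess as pp

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 17
N_CASES = 100

COHORT_CONFIG = ph.CohortConfig(n_cases=N_CASES, vpi_prevalence=0.4, seed=SEED)
PREPROC_SPEC = pp.PreprocSpec()
VAL_FRAC = 0.3


def cohort():
    return ph.generate_cohort(COHORT_CONFIG)


def splits(cases):
    return pl.split_cohort([c.case_id for c in cases], VAL_FRAC, 0.0)
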