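import warnings

import numpy as np
import pandas as pd
import pytest

from habitatvpi import habitat as hb
from habitatvpi import phantom as ph
from habitatvpi import pipeline as pl
from habitatvpi import preprocess as pp
from habitatvpi import radiomics as rx


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-case default-condition phantom cohort shared across tests."""
    return ph.generate_cohort(
        ph.CohortConfig(n_cases=60, vpi_prevalence=0.4, seed=7)
    )


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    spec = pp.PreprocSpec()
    return {c.case_id: pl.preprocess_case(c, spec) for c in small_cohort}


@pytest.fixture(scope="session")
def whole_feature_table(small_cohort, preprocessed_cohort):
    """Whole-lesion 106-feature table with batch and outcome columns attached."""
    rows = {}
    for case in small_cohort:
        vol, lesion, *_ = preprocessed_cohort[case.case_id]
        rows[case.case_id] = rx.extract_whole(vol, lesion)
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    meta = pd.DataFrame(
        {
            "batch": {c.case_id: c.batch_id for c in small_cohort},
            "vpi": {c.case_id: c.vpi_label for c in small_cohort},
        }
    ).loc[table.index]
    return table, meta


@pytest.fixture(scope="session")
def fitted_habitats(small_cohort, preprocessed_cohort):
    """SLIC maps, a frozen 3-habitat cluster model, and habitat maps."""
    spmaps, spfeats = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cid, (vol, lesion, norm, *_rest) in preprocessed_cohort.items():
            spmaps[cid] = hb.slic3d(norm, lesion)
            spfeats[cid] = hb.superpixel_features(norm, spmaps[cid])
    pool = pd.concat(list(spfeats.values()), ignore_index=True)
    model = hb.fit_habitat_model(pool, k=3, seed=0)
    maps = {
        cid: hb.assign_habitats(preprocessed_cohort[cid][2], spmaps[cid], model)
        for cid in preprocessed_cohort
    }
    return spmaps, model, maps


def sphere_mask(shape, center, radius):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
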