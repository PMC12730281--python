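import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import omicnet as on

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_sim_config():
    """A small, fast cohort: 60 samples, 40 features per modality."""
    return on.SimConfig(
        n_samples=60,
        n_features=40,
        planted={
            "gene_expression": [(5, 2.0), (15, 2.0)],
            "snp": [(25, 2.0)],
            "cnv": [(35, 2.0)],
        },
        interactions=[],
        seed=11,
    )


@pytest.fixture
def tiny_bundle(tiny_sim_config):
    mats, _, truth = on.generate_cohort(tiny_sim_config)
    encoded = [on.encode_modality(mats[m]) for m in tiny_sim_config.modalities]
    return on.merge_modalities(encoded, on.phenotype_from_truth(truth))


@pytest.fixture
def continuous_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
        index=["s1", "s2"],
        columns=["f1", "f2", "f3"],
    )
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return on.OmicsMatrix(
        modality=on.get_modality("gene_expression"), values=values, missing_mask=mask
    )


def write_csv(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def csv_writer(tmp_path):
    def _write(name, text):
        return write_csv(tmp_path / name, text)

    return _write
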