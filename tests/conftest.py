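import numpy as np
import pandas as pd
import pytest

import frperturb as fp


@pytest.fixture(scope="session")
def tiny_screen():
    """Small guide-pooled screen with known sparse low-rank truth."""
    truth = fp.make_truth(
        n_perturbations=20, n_genes=200, rank=3, max_cofunctional=3,
        effect_scale=0.5, seed=1, n_non_targeting=6, n_safe_targeting=6,
    )
    model = fp.make_control_model(200, seed=2)
    return fp.simulate_guide_pooled(truth, model, 900, 2, seed=3)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_screen):
    Y, profile, norm = fp.prepare_expression(tiny_screen.counts, tiny_screen.design)
    return Y, profile, norm


@pytest.fixture()
def simple_guide_map():
    return pd.DataFrame(
        {
            "guide_id": ["geneA_g1", "geneA_g3", "geneB_g1", "NT_1", "SAFE_1"],
            "target_gene": ["geneA", "geneA", "geneB", "", ""],
            "guide_class": [
                "targeting", "targeting", "targeting",
                "non_targeting", "safe_targeting",
            ],
        }
    )


def make_assignments(rows):
    return pd.DataFrame(rows, columns=["droplet_id", "guide_id", "umi_count"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
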