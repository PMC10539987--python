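import numpy as np
import pandas as pd
import pytest

import painattrib as pa


@pytest.fixture(scope="session")
def small_trial():
    """One modest synthetic trial shared across read-only tests."""
    cfg = pa.SimulationConfig(n_per_arm=40, seed=11)
    dataset, truth = pa.generate_trial(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def lexicon():
    return pa.default_lexicon()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_scores_frame(scores: dict[str, int], timepoint: str = "post") -> pd.DataFrame:
    """Helper: wide dict participant -> score into the long scores schema."""
    return pd.DataFrame(
        {
            "participant_id": list(scores),
            "timepoint": timepoint,
            "score": list(scores.values()),
            "n_attributions_scored": 3,
        }
    )
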