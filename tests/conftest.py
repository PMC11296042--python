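import warnings

import numpy as np
import pandas as pd
import pytest

from emospace.simulate import default_truth, generate_latent_dataset, generate_rater_ratings

warnings.filterwarnings("ignore", message="Heywood case")


def make_table(rows):
    """Long-format table from (participant, session, domain, stimulus,
    scale, rating, trial_type[, rt, fails]) tuples."""
    cols = [
        "participant_id", "session_id", "domain", "stimulus_id",
        "scale_id", "rating", "trial_type", "reaction_time_ms",
        "attention_fails",
    ]
    full = [tuple(r) + (2000.0, 0)[len(r) - 7 :] for r in rows]
    return pd.DataFrame(full, columns=cols[: len(full[0])])


@pytest.fixture(scope="session")
def narrative_truth():
    return default_truth("narrative", seed=0)


@pytest.fixture(scope="session")
def narrative_matrix(narrative_truth):
    mat, _ = generate_latent_dataset(narrative_truth)
    return mat


@pytest.fixture(scope="session")
def small_rater_table():
    """Trial-level data: 40 stimuli x 23 scales x 12 raters, low noise."""
    truth = default_truth("narrative", seed=7)
    truth.n_stimuli = 40
    truth.rater.n_raters = 12
    return generate_rater_ratings(truth)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
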