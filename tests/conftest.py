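import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def e1_dataset():
    """One simulated old/new recognition experiment at the default truth."""
    from recallmix.datasets import GenParams, experiment_design, generate_experiment

    return generate_experiment(experiment_design("e1"), GenParams(), seed=424)


@pytest.fixture(scope="session")
def e4_dataset():
    """One simulated color-report-only experiment at the default truth."""
    from recallmix.datasets import GenParams, experiment_design, generate_experiment

    return generate_experiment(experiment_design("e4"), GenParams(), seed=925)


def make_trials(participant, item_type, signed_error=None, phase="test",
                recognition_response="none", recognition_rt_ms=None,
                probe_present=False, probe_rt_ms=None):
    """Small hand-built trial table with the standard columns."""
    n = len(participant)

    def col(v, default):
        if v is None:
            return [default] * n
        return v

    return pd.DataFrame({
        "participant": participant,
        "phase": col(None, phase) if isinstance(phase, str) else phase,
        "trial_index": np.arange(1, n + 1),
        "item_id": [f"i{i}" for i in range(n)],
        "item_type": item_type,
        "probe_present": col(probe_present if not isinstance(probe_present, bool)
                             else None, probe_present),
        "probe_rt_ms": col(probe_rt_ms, np.nan),
        "recognition_response": col(
            recognition_response if not isinstance(recognition_response, str)
            else None, recognition_response),
        "recognition_rt_ms": col(recognition_rt_ms, np.nan),
        "studied_color": [0.0] * n,
        "response_color": [0.0] * n,
        "signed_error": col(signed_error, np.nan),
        "color_rt_ms": col(None, np.nan),
    })
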