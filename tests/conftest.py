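"""Shared fixtures: reduced-scale synthetic cohorts reused across test modules.

EEG cohorts run at a reduced problem size (2 blocks, 16 channels, epochs
-0.2..0.6 s) that preserves the planted 188-262 ms effect window and the
38-participant group level where a test needs it.
"""

import numpy as np
import pandas as pd
import pytest

from eegsurprise import synthetic_data as sd


SMALL_KW = dict(n_channels=16, epoch_window=(-0.2, 0.6))


@pytest.fixture(scope="session")
def small_cohort():
    """10-participant cohort with the default planted high-level effect."""
    spec = sd.GeneratorSpec(n_participants=10, n_blocks=2, seed=11, **SMALL_KW)
    stimuli, rdms, trials, epochs = sd.synth_cohort(spec, lazy=False)
    return spec, stimuli, rdms, trials, epochs


@pytest.fixture(scope="session")
def toy_trials():
    """Minimal hand-written labeled trial table with behavior columns."""
    rows = [
        # block, trial, cue, image, expected, expectedness, nogo, resp, corr, rt
        (0, 0, "b", "cat", "cat", "expected", False, "animate", True, 480.0),
        (0, 1, "c", "dog", "car", "unexpected_different_response", False, "animate", True, 530.0),
        (0, 2, "d", "cat", "dog", "unexpected_same_response", False, "animate", True, 510.0),
        (0, 3, "a", "car", "", "nogo", True, "none", True, np.nan),
        (0, 4, "b", "dog", "cat", "unexpected_same_response", False, "inanimate", False, 600.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["block", "trial", "cue", "image", "expected_image",
                 "expectedness", "nogo", "response", "correct", "rt_ms"],
    )
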