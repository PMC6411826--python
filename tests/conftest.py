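import numpy as np
import pytest

from emonback.synthio import Block, Paradigm, ParadigmRun


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_paradigm(blocks, n_volumes=40, tr=1.0):
    """Single-run paradigm from (onset, duration, condition) triples."""
    run = ParadigmRun(blocks=[Block(*b) for b in blocks], n_volumes=n_volumes, tr=tr)
    return Paradigm(runs=[run], tr=tr, trials_per_block=9,
                    trial_fixation_s=2.0, trial_stimulus_s=1.6)


@pytest.fixture
def six_condition_paradigm():
    """One run containing every task condition once (8 s blocks, tr 1 s)."""
    conds = ["happy", "vertical", "sad", "horizontal", "neutral", "checked"]
    blocks = [(10.0 + 18.0 * i, 8.0, c) for i, c in enumerate(conds)]
    return make_paradigm(blocks, n_volumes=130, tr=1.0)
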