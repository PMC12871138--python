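import numpy as np
import pandas as pd
import pytest

from secretomap.io_tables import ChannelDesign, QuantExperiment


def make_design(specs):
    """specs: iterable of (channel_id, genotype, condition[, plex]) tuples."""
    out = []
    reps = {}
    for spec in specs:
        cid, geno, cond = spec[:3]
        plex = spec[3] if len(spec) > 3 else "plex1"
        key = (plex, geno, cond)
        reps[key] = reps.get(key, 0) + 1
        out.append(ChannelDesign(cid, geno, cond, "iWAT", reps[key], plex))
    return out


def make_experiment(values: dict[str, list[float]], specs) -> QuantExperiment:
    """Build a QuantExperiment from {protein: [intensity per channel]}."""
    design = make_design(specs)
    mat = pd.DataFrame.from_dict(values, orient="index",
                                 columns=[c.channel_id for c in design]).astype(float)
    mat.index.name = "protein"
    return QuantExperiment(mat, design)


FOUR_CHANNEL = [("c1", "cre_pos", "basal"), ("c2", "cre_pos", "basal"),
                ("c3", "cre_neg", "basal"), ("c4", "cre_neg", "basal")]


@pytest.fixture
def simple_experiment():
    return make_experiment(
        {"A": [800, 800, 100, 100], "B": [50, 50, 50, 50], "C": [10, 30, 20, 40]},
        FOUR_CHANNEL)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
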