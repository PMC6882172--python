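import numpy as np
import pytest

import ppilstm as pl


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_lstm_layer(input_size, cells, seed=0, scale=0.5, **kwargs):
    return pl.init_lstm_layer(input_size, cells, np.random.default_rng(seed),
                              scale=scale, **kwargs)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Nine synthetic dimers run through the full pair pipeline, split 6:2:2."""
    spec = pl.SyntheticDimerSpec(seed=0)
    dimers, split = pl.generate_dataset(9, spec, seed=0)
    psets = {d.dimer_id: pl.prepare_dimer(d) for d in dimers}
    return {
        "spec": spec,
        "dimers": {d.dimer_id: d for d in dimers},
        "train": [psets[i] for i in split.train],
        "validation": [psets[i] for i in split.validation],
        "test": [psets[i] for i in split.test],
    }


@pytest.fixture(scope="session")
def toy_dimer():
    """One small synthetic dimer plus its raw cross pairs and labels."""
    spec = pl.SyntheticDimerSpec(len_receptor=8, len_ligand=10, patch_size=2,
                                 seed=7)
    dimer = pl.generate_dimer(spec, dimer_id="TOY", seed=7)
    cross = pl.build_cross_pairs(dimer.chains["R"], dimer.chains["L"])
    labelled = pl.label_interface(cross, dimer.contact_areas)
    return {"spec": spec, "dimer": dimer, "cross": cross, "labelled": labelled}
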