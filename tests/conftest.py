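import numpy as np
import pytest

import obscuredgp as og


@pytest.fixture(scope="session")
def small_sim():
    """An 80×150 simulated panel shared by read-only tests."""
    return og.simulate(og.SimConfig(n_individuals=80, n_markers=150, seed=11))


@pytest.fixture(scope="session")
def tiny_trained_net():
    """A small trained obscured net (25 lines × 24 markers, 5 epochs).

    Session-scoped: training is deterministic and the net is never mutated
    by the tests that share it.
    """
    genos, phenos, _ = og.simulate(
        og.SimConfig(n_individuals=25, n_markers=24, block_size=6, n_qtl=4,
                     heritability=0.8, duplicate_frac=0.0, seed=5)
    )
    y = og.zscore_apply(phenos.trait("trait"), og.zscore_fit(phenos.trait("trait")))
    cfg = og.NetConfig(n_features=24, epochs=5, seed=5)
    net = og.ObscuredNet(cfg).train(og.build_pair_dataset(genos.codes, y))
    return net, genos.codes, y


@pytest.fixture()
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "ID,m1,m2,m3,m4,yield\n"
        "g1,0,1,2,0,1.5\n"
        "g2,2,1,0,0,-0.5\n"
        "g3,0,0,2,1,2.0\n"
    )
    return path
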