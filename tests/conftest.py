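import numpy as np
import pytest

import callometry as cm

RATE = 22050.0


@pytest.fixture(scope="session")
def rate():
    return RATE


@pytest.fixture(scope="session")
def five_call_recording():
    """Five tonal calls over background noise, with ground truth."""
    spec = cm.RecordingSpec(
        calls=tuple(
            (cm.CallSpec(f0_hz=200.0 + 50 * i, duration_s=0.4), 1.5 * i)
            for i in range(5)
        ),
        noise_snr_db=20.0,
        rate=RATE,
        seed=3,
    )
    return cm.synthesize_recording(spec)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact synthetic study on disk plus its pipeline results."""
    from callometry.pipeline import RunConfig, run_all
    from callometry.synth import make_study

    out = tmp_path_factory.mktemp("study")
    truth = make_study(str(out), n_species=8, calls_per_species=24, seed=11)
    config = RunConfig.from_json(str(out / "config.json"))
    manifest = run_all(config)
    return {"dir": out, "truth": truth, "config": config,
            "manifest": manifest}


@pytest.fixture
def balanced_tree_tables():
    """Deterministic 6-taxon tree + small trait table for exact GLS checks."""
    from callometry.phyloreg import Phylogeny, TraitTable

    newick = "(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);"
    tree = Phylogeny.from_newick(newick)
    rng = np.random.default_rng(42)
    x = np.array([2.1, 2.4, 2.5, 2.8, 3.0, 3.1])
    y = 5.0 - 1.2 * x + 0.1 * rng.standard_normal(6)
    table = TraitTable(["a", "b", "c", "d", "e", "f"], x, y)
    return tree, table
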