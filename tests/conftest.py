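import numpy as np
import pytest

from tumorlr import (FrequencyTable, KitMap, apply_analytical_threshold,
                     default_kit, sample_reference_profile,
                     simulate_frequency_table, simulate_tumor_profile)
from tumorlr.simulate import SimConfig


@pytest.fixture(scope="session")
def toy_freqs() -> FrequencyTable:
    """Two small loci with fully enumerated alleles (no residual Q mass
    beyond the complement)."""
    return FrequencyTable(freqs={
        "L1": {"10": 0.3, "12": 0.5, "13": 0.2},
        "L2": {"8": 0.6, "9.3": 0.4},
    }, floor=1e-4)


@pytest.fixture(scope="session")
def toy_kit() -> KitMap:
    return KitMap(loci={
        "L1": {"offset": 60.0, "motif": 4.0, "dye": "B"},
        "L2": {"offset": 120.0, "motif": 4.0, "dye": "G"},
    })


@pytest.fixture(scope="session")
def sim_setup():
    """A full synthetic case under the study defaults: frequency table, kit,
    reference and thresholded tumor evidence."""
    cfg = SimConfig(seed=42, mxn=0.4)
    freqs = simulate_frequency_table(cfg)
    kit = default_kit(list(freqs.freqs))
    ref = sample_reference_profile(freqs, seed=43, sample_id="HBD0001", kit=kit)
    ev = simulate_tumor_profile(ref, cfg, freqs, kit, sample_id="HTFD0001")
    ev = apply_analytical_threshold(ev, cfg.at)
    return {"cfg": cfg, "freqs": freqs, "kit": kit, "ref": ref, "ev": ev}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
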