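import numpy as np
import pytest

from gcscore import (
    ChipDefinition,
    IntensityArray,
    ProbeRecord,
    ProbesetDefinition,
    SimulationSpec,
    make_synthetic_chip,
    simulate_experiment,
)


@pytest.fixture
def tiny_chip():
    """10 probes: 8 PM in two TC probesets, 2 BG probes (gc 3 and 12)."""
    probes = [ProbeRecord(i, 10 + (i % 5), "PM") for i in range(8)]
    probes += [ProbeRecord(8, 3, "BG"), ProbeRecord(9, 12, "BG")]
    probesets = {
        "TC01": ProbesetDefinition("TC01", "TC", (0, 1, 2, 3), {"symbol": "GeneA"}),
        "TC02": ProbesetDefinition("TC02", "TC", (4, 5, 6, 7), {"symbol": "GeneB"}),
    }
    return ChipDefinition("tiny", probes, probesets)


@pytest.fixture
def mm_chip():
    """3' IVT-style chip: 4 PM + 4 MM pairs + 2 BG, one TC probeset."""
    probes = [ProbeRecord(i, 8 + i, "PM") for i in range(4)]
    probes += [ProbeRecord(4 + i, 8 + i, "MM") for i in range(4)]
    probes += [ProbeRecord(8, 8, "BG"), ProbeRecord(9, 11, "BG")]
    probesets = {"TC01": ProbesetDefinition("TC01", "TC", (0, 1, 2, 3))}
    return ChipDefinition("ivt", probes, probesets, {i: 4 + i for i in range(4)})


def random_arrays(chip, seed, n=2):
    """Positive random intensity arrays for a chip."""
    rng = np.random.default_rng(seed)
    return [
        IntensityArray(f"s{k}", rng.lognormal(5.0, 1.0, chip.n_probes))
        for k in range(n)
    ]


@pytest.fixture
def small_sim():
    """A small simulated null experiment shared by several tests."""
    spec = SimulationSpec(n_probesets=60, probes_per_set=6, n_bg_per_gc=3, seed=42)
    chip = make_synthetic_chip(spec)
    treats, ctrls, truth = simulate_experiment(chip, spec, truth_seed=7)
    return chip, treats, ctrls, truth, spec
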