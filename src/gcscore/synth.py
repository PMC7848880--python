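"""Synthetic chips and arrays with known ground truth.

The generator reproduces the features of real oligonucleotide arrays that
the scoring method relies on: non-specific binding that rises with probe GC
content (estimated on real chips from antigenomic probes), a broad lognormal
distribution of transcript abundances, probe-specific affinities that are a
property of the probe sequence and therefore identical across arrays (so
probe-level differencing cancels them), and multiplicative measurement
noise with a fixed coefficient of variation. What it deliberately does not
model: spatial artifacts, scanner saturation and cross-hybridization.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chip import ChipDefinition, ProbeRecord, ProbesetDefinition, write_chip_definition
from .errors import ValidationError
from .io import IntensityArray, write_intensity_table


@dataclass
class SimulationSpec:
    """Parameters of one synthetic experiment.

    Defaults emulate a small whole-transcriptome study: a 3 vs 3 replicate
    design, 10 probes per transcript cluster, antigenomic background probes
    for every GC count from 3 to 25, transcript abundances lognormal around
    ~300 units with a wide spread (log-SD 1), non-specific background rising
    linearly from ~50 to ~140 units across the GC range, and 10% measurement
    CV per probe.
    """

    n_probesets: int = 1000
    probes_per_set: int | tuple[int, int] = 10
    n_bg_per_gc: int = 25
    gc_range: tuple[int, int] = (3, 25)
    baseline_log_mean: float = math.log(300.0)
    baseline_log_sd: float = 1.0
    bg_base: float = 40.0
    bg_slope: float = 4.0
    affinity_log_sd: float = 0.25
    noise_cv: float = 0.1
    de_fraction: float = 0.0
    de_log2fc: float | tuple[float, float] = 1.0
    n_treat: int = 3
    n_ctrl: int = 3
    seed: int = 0
    with_psr: bool = False
    with_mm: bool = False

    def __post_init__(self):
        if self.n_probesets < 1 or self.n_bg_per_gc < 1:
            raise ValidationError("counts must be >= 1")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValidationError("de_fraction must be in [0, 1]")
        if self.n_treat < 1 or self.n_ctrl < 1:
            raise ValidationError("need >= 1 treatment and control array")
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 25):
            raise ValidationError("gc_range must satisfy 0 <= lo <= hi <= 25")


@dataclass
class GroundTruth:
    """Signed log2 fold changes of the truly differential probesets."""

    log2fc: dict[str, float] = field(default_factory=dict)

    @property
    def de_probesets(self) -> set[str]:
        return set(self.log2fc)


def _set_sizes(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    pps = spec.probes_per_set
    if isinstance(pps, tuple):
        return rng.integers(pps[0], pps[1] + 1, size=spec.n_probesets)
    return np.full(spec.n_probesets, int(pps), dtype=np.int64)


def make_synthetic_chip(spec: SimulationSpec) -> ChipDefinition:
    """Build a chip: TC probesets of PM probes with random GC counts, one
    block of BG probes per GC bin, optional mirrored PSR probesets and
    optional MM partners (3' IVT emulation). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _set_sizes(spec, rng)
    n_pm = int(sizes.sum())
    gc_lo, gc_hi = spec.gc_range
    pm_gc = rng.integers(gc_lo, gc_hi + 1, size=n_pm)

    probes: list[ProbeRecord] = [
        ProbeRecord(i, int(pm_gc[i]), "PM") for i in range(n_pm)
    ]
    mm_pairing: dict[int, int] | None = None
    nxt = n_pm
    if spec.with_mm:
        mm_pairing = {}
        for i in range(n_pm):
            probes.append(ProbeRecord(nxt, int(pm_gc[i]), "MM"))
            mm_pairing[i] = nxt
            nxt += 1
    for g in range(gc_lo, gc_hi + 1):
        for _ in range(spec.n_bg_per_gc):
            probes.append(ProbeRecord(nxt, g, "BG"))
            nxt += 1

    probesets: dict[str, ProbesetDefinition] = {}
    start = 0
    width = len(str(spec.n_probesets))
    for k, sz in enumerate(sizes):
        members = tuple(range(start, start + int(sz)))
        tc = f"TC{k:0{width}d}"
        probesets[tc] = ProbesetDefinition(tc, "TC", members,
                                           {"symbol": f"Gene{k}"})
        if spec.with_psr:
            psr = f"PSR{k:0{width}d}"
            probesets[psr] = ProbesetDefinition(psr, "PSR", members,
                                                {"symbol": f"Gene{k}"})
        start += int(sz)
    return ChipDefinition(f"synthchip_s{spec.seed}", probes, probesets, mm_pairing)


def _background(spec: SimulationSpec, gc: np.ndarray) -> np.ndarray:
    return spec.bg_base + spec.bg_slope * gc


def simulate_experiment(chip: ChipDefinition, spec: SimulationSpec,
                        truth_seed: int = 0):
    """Simulate treatment and control arrays on ``chip``.

    Per TC probeset k a baseline abundance theta_k ~ lognormal; per probe a
    fixed affinity multiplier; a ``de_fraction`` of probesets carries a
    signed log2 fold change in the treatment arm. Probe intensity is
    ``(affinity * theta_k * 2^lfc + bg(gc)) * noise`` with lognormal noise of
    mean 1 and CV ``noise_cv``; background (and MM) probes see ``bg(gc) *
    noise`` only. Returns (treatment arrays, control arrays, GroundTruth).
    """
    rng = np.random.default_rng(truth_seed)
    tc_sets = chip.probesets_at({"TC"})
    if not tc_sets:
        raise ValidationError("chip has no TC probesets to simulate")

    theta = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                              size=len(tc_sets)))
    n = chip.n_probes
    affinity = np.exp(rng.normal(0.0, spec.affinity_log_sd, size=n))

    n_de = int(round(spec.de_fraction * len(tc_sets)))
    de_idx = rng.choice(len(tc_sets), size=n_de, replace=False) if n_de else []
    lfc = np.zeros(len(tc_sets))
    truth = GroundTruth()
    for j in de_idx:
        mag = spec.de_log2fc
        if isinstance(mag, tuple):
            mag = rng.uniform(mag[0], mag[1])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc[j] = sign * mag
        truth.log2fc[tc_sets[j].probeset_id] = float(lfc[j])
    # mirrored exon-level sets share their TC's probes, hence its fold change
    mirrored = {ps.probeset_id: set(ps.probe_indices)
                for ps in chip.probesets_at({"PSR", "JUC"})}

    sig_ctrl = np.zeros(n)
    sig_treat = np.zeros(n)
    for j, ps in enumerate(tc_sets):
        sel = np.asarray(ps.probe_indices)
        base = affinity[sel] * theta[j]
        sig_ctrl[sel] = base
        sig_treat[sel] = base * 2.0 ** lfc[j]
        if lfc[j] != 0.0:
            for pid, members in mirrored.items():
                if members & set(ps.probe_indices):
                    truth.log2fc.setdefault(pid, float(lfc[j]))
    bg = _background(spec, np.maximum(chip.gc, 0).astype(float))
    # MM and BG probes measure non-specific binding only
    is_signal = chip.roles == "PM"

    sigma = math.sqrt(math.log1p(spec.noise_cv ** 2))

    def one_array(sid: str, sig: np.ndarray) -> IntensityArray:
        mean = np.where(is_signal, sig + bg, bg)
        noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))
        return IntensityArray(sid, mean * noise)

    controls = [one_array(f"ctrl{i+1}", sig_ctrl) for i in range(spec.n_ctrl)]
    treats = [one_array(f"treat{i+1}", sig_treat) for i in range(spec.n_treat)]
    return treats, controls, truth


def null_spec(**overrides) -> SimulationSpec:
    """A no-differential-expression spec (both groups exchangeable)."""
    overrides.setdefault("de_fraction", 0.0)
    return SimulationSpec(**overrides)


def write_simulation(out_dir: str, chip: ChipDefinition,
                     treats: list[IntensityArray], ctrls: list[IntensityArray],
                     truth: GroundTruth) -> str:
    """Materialize a simulated experiment: chip bundle, intensity TSVs,
    truth.csv and a design.csv wired to the written files. Returns the path
    of the design file."""
    os.makedirs(out_dir, exist_ok=True)
    write_chip_definition(chip, os.path.join(out_dir, "chip"))
    rows = []
    for group, arrays in (("treatment", treats), ("control", ctrls)):
        for arr in arrays:
            fn = f"{arr.sample_id}.tsv"
            write_intensity_table(arr, os.path.join(out_dir, fn))
            rows.append({"sample_id": arr.sample_id, "path": fn, "group": group})
    design_path = os.path.join(out_dir, "design.csv")
    pd.DataFrame(rows).to_csv(design_path, index=False)
    pd.DataFrame(
        sorted(truth.log2fc.items()),
        columns=["probeset_id", "log2fc"],
    ).to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return design_path


__all__ = [
    "SimulationSpec", "GroundTruth", "make_synthetic_chip",
    "simulate_experiment", "null_spec", "write_simulation", "replace",
]
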