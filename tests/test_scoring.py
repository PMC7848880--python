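import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcscore import (
    DegenerateDistributionError,
    DegenerateInputError,
    IntensityArray,
    SimulationSpec,
    build_background_index,
    compute_rawq,
    compute_sdt,
    compute_sf,
    correct_gc,
    correct_pm_mm,
    gc_background_medians,
    make_synthetic_chip,
    normalize_scores,
    probe_epsilon,
    score_pair,
    score_probeset,
    simulate_experiment,
)
from gcscore.scoring import ScalingInfo, make_scaling

from conftest import random_arrays


# ---------------------------------------------------------------------------
# straight-line oracle: an independent, loop-based re-implementation of the
# scaling, background-correction and score equations

def _oracle_percentile(sorted_vals, frac):
    # linear interpolation between order statistics, inclusive bounds
    h = (len(sorted_vals) - 1) * frac
    lo = math.floor(h)
    hi = math.ceil(h)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def oracle_score_pair(arr_a, arr_b, chip, gamma=0.1, tgt=500.0):
    """Brute-force scoring of all TC probesets of two arrays (GC method)."""
    level_idx = sorted(
        {i for ps in chip.probesets.values() if ps.level == "TC"
         for i in ps.probe_indices}
    )
    out = {}
    per_array = {}
    for name, arr in (("A", arr_a), ("B", arr_b)):
        vals = list(arr.values)
        sf = tgt / statistics.median([vals[i] for i in level_idx])
        m = math.ceil(0.02 * len(vals))
        rawq = statistics.stdev(sorted(vals)[:m])
        sdt = 4.0 * rawq * sf
        scaled = [v * sf for v in vals]
        by_gc = {}
        for p in chip.probes:
            if p.role == "BG":
                by_gc.setdefault(p.gc_count, []).append(scaled[p.probe_index])
        med = {g: statistics.median(v) for g, v in by_gc.items()}
        for g in range(26):
            if g not in med:
                nearest = min(med, key=lambda a: (abs(a - g), a))
                med[g] = med[nearest]
        corrected = {
            i: scaled[i] - med[chip.probes[i].gc_count] for i in level_idx
        }
        per_array[name] = (corrected, sdt)
    corr_a, sdt_a = per_array["A"]
    corr_b, sdt_b = per_array["B"]
    for pid, ps in sorted(chip.probesets.items()):
        if ps.level != "TC":
            continue
        n = len(ps.probe_indices)
        total = 0.0
        for i in ps.probe_indices:
            la, lb = corr_a[i], corr_b[i]
            eps = math.sqrt(gamma ** 2 * (la ** 2 + lb ** 2)
                            + sdt_a ** 2 + sdt_b ** 2)
            total += (lb - la) / (eps * math.sqrt(n))
        out[pid] = total
    return out


# ---------------------------------------------------------------------------
# scaling

class TestScalingFactor:
    def test_identity_when_median_equals_target(self, tiny_chip):
        arr = IntensityArray("a", np.full(10, 500.0))
        assert compute_sf(arr, tiny_chip, {"TC"}) == 1.0

    def test_simple_ratio(self):
        from gcscore import ChipDefinition, ProbeRecord, ProbesetDefinition

        chip = ChipDefinition(
            "c",
            [ProbeRecord(0, 10, "PM"), ProbeRecord(1, 10, "PM"),
             ProbeRecord(2, 10, "PM"), ProbeRecord(3, 5, "BG")],
            {"TC1": ProbesetDefinition("TC1", "TC", (0, 1, 2))},
        )
        arr = IntensityArray("a", np.array([100.0, 200.0, 300.0, 7.0]))
        assert compute_sf(arr, chip, {"TC"}) == pytest.approx(2.5, rel=1e-15)

    def test_scales_median_to_target(self, tiny_chip):
        rng = np.random.default_rng(11)
        arr = IntensityArray("a", rng.lognormal(5, 1, 10))
        sf = compute_sf(arr, tiny_chip, {"TC"}, tgt=500.0)
        med = np.median(arr.values[:8])
        assert sf * med == pytest.approx(500.0, rel=1e-12)

    def test_zero_median_rejected(self, tiny_chip):
        arr = IntensityArray("a", np.zeros(10))
        with pytest.raises(DegenerateInputError):
            compute_sf(arr, tiny_chip, {"TC"})


class TestRawQ:
    def test_forced_two_value_subset(self):
        vals = np.concatenate([[1.0, 3.0], np.full(98, 1000.0)])
        arr = IntensityArray("a", vals)
        assert compute_rawq(arr) == pytest.approx(math.sqrt(2.0), rel=1e-15)

    def test_constant_array_gives_zero(self):
        arr = IntensityArray("a", np.full(200, 7.0))
        assert compute_rawq(arr) == 0.0

    def test_matches_sort_and_sd_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(4, 1.5, 731)
        arr = IntensityArray("a", vals)
        m = math.ceil(0.02 * 731)
        expected = statistics.stdev(sorted(vals)[:m])
        assert compute_rawq(arr) == pytest.approx(expected, rel=1e-12)

    def test_too_few_probes_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_rawq(IntensityArray("a", np.array([1.0, 2.0, 3.0])))


@pytest.mark.parametrize(
    "rawq,sf,expected", [(2.5, 1.0, 10.0), (0.0, 3.0, 0.0), (1.5, 2.2, 13.2)]
)
def test_sdt_arithmetic(rawq, sf, expected):
    assert compute_sdt(rawq, sf) == pytest.approx(expected, rel=1e-15)


# ---------------------------------------------------------------------------
# background correction

class TestGcBackground:
    def test_median_per_bin(self, tiny_chip):
        from gcscore import ChipDefinition, ProbeRecord, ProbesetDefinition

        chip = ChipDefinition(
            "c",
            [ProbeRecord(0, 12, "PM"),
             ProbeRecord(1, 12, "BG"), ProbeRecord(2, 12, "BG"),
             ProbeRecord(3, 12, "BG")],
            {"TC1": ProbesetDefinition("TC1", "TC", (0,))},
        )
        bg = build_background_index(chip)
        scaled = np.array([999.0, 10.0, 20.0, 30.0])
        med = gc_background_medians(scaled, bg)
        assert med[12] == 20.0

    def test_nearest_bin_fallback_and_tie_to_lower(self):
        from gcscore import ChipDefinition, ProbeRecord, ProbesetDefinition

        chip = ChipDefinition(
            "c",
            [ProbeRecord(0, 10, "PM"),
             ProbeRecord(1, 3, "BG"), ProbeRecord(2, 25, "BG")],
            {"TC1": ProbesetDefinition("TC1", "TC", (0,))},
        )
        bg = build_background_index(chip)
        med = gc_background_medians(np.array([0.0, 100.0, 900.0]), bg)
        assert med[10] == 100.0  # |10-3|=7 < |10-25|=15
        assert med[14] == 100.0  # distance tie (11, 11) -> lower gc wins
        assert med[20] == 900.0

    def test_subtraction_arithmetic(self):
        from gcscore import ChipDefinition, ProbeRecord, ProbesetDefinition

        chip = ChipDefinition(
            "c",
            [ProbeRecord(0, 12, "PM"), ProbeRecord(1, 12, "BG")],
            {"TC1": ProbesetDefinition("TC1", "TC", (0,))},
        )
        arr = IntensityArray("a", np.array([100.0, 40.0]))
        scaling = ScalingInfo(sf=1.0, rawq=0.0, sdt=0.0)
        corr = correct_gc(arr, chip, {"TC"}, scaling)
        assert corr.values.tolist() == [60.0]
        # below-background probes go negative, not clipped
        arr2 = IntensityArray("a", np.array([10.0, 40.0]))
        corr2 = correct_gc(arr2, chip, {"TC"}, scaling)
        assert corr2.values.tolist() == [-30.0]

    def test_scale_invariance_with_recomputed_sf(self):
        spec = SimulationSpec(n_probesets=30, probes_per_set=5, n_bg_per_gc=3,
                              seed=3)
        chip = make_synthetic_chip(spec)
        arr = random_arrays(chip, seed=3, n=1)[0]
        doubled = IntensityArray("a2", arr.values * 2.0)
        s1 = make_scaling(arr, chip, {"TC"})
        s2 = make_scaling(doubled, chip, {"TC"})
        c1 = correct_gc(arr, chip, {"TC"}, s1)
        c2 = correct_gc(doubled, chip, {"TC"}, s2)
        np.testing.assert_allclose(c1.values, c2.values, rtol=1e-12)


class TestPmMm:
    def test_difference_arithmetic(self, mm_chip):
        vals = np.array([120.0, 50.0, 60.0, 70.0, 20.0, 50.0, 10.0, 30.0,
                         5.0, 6.0])
        arr = IntensityArray("a", vals)
        scaling = ScalingInfo(sf=1.0, rawq=0.0, sdt=0.0)
        corr = correct_pm_mm(arr, mm_chip, {"TC"}, scaling)
        assert corr.values.tolist() == [100.0, 0.0, 50.0, 40.0]

    def test_unpaired_pm_rejected(self, tiny_chip):
        arr = random_arrays(tiny_chip, seed=0, n=1)[0]
        scaling = ScalingInfo(sf=1.0, rawq=0.0, sdt=0.0)
        from gcscore import ValidationError

        with pytest.raises(ValidationError):
            correct_pm_mm(arr, tiny_chip, {"TC"}, scaling)


# ---------------------------------------------------------------------------
# the probe error term and the probeset score

@pytest.mark.parametrize(
    "la,lb,sa,sb,gamma,expected",
    [
        (0.0, 0.0, 3.0, 4.0, 0.1, 5.0),
        (0.0, 10.0, 0.0, 0.0, 0.1, 1.0),
        (10.0, 10.0, 0.0, 0.0, 0.1, math.sqrt(2.0)),
    ],
)
def test_probe_epsilon_values(la, lb, sa, sb, gamma, expected):
    assert probe_epsilon(la, lb, sa, sb, gamma) == pytest.approx(expected, rel=1e-12)


def test_probe_epsilon_zero_is_degenerate():
    with pytest.raises(DegenerateInputError):
        probe_epsilon(0.0, 0.0, 0.0, 0.0)


class TestScoreProbeset:
    def test_two_probe_arithmetic(self):
        from gcscore.scoring import CorrectedArray

        scaling0 = ScalingInfo(sf=1.0, rawq=0.25, sdt=1.0)
        # choose l values so both eps come out exactly 1 with gamma=0:
        # eps = sqrt(sdtA^2 + sdtB^2) with sdtA=1, sdtB=0 -> 1
        ca = CorrectedArray("a", np.array([0.0, 0.0]), np.array([0, 1]),
                            ScalingInfo(1.0, 0.25, 1.0), "GC")
        cb = CorrectedArray("b", np.array([3.0, 4.0]), np.array([0, 1]),
                            ScalingInfo(1.0, 0.0, 0.0), "GC")
        from gcscore import ProbesetDefinition

        ps = ProbesetDefinition("TC1", "TC", (0, 1))
        got = score_probeset(ca, cb, ps, gamma=0.0)
        assert got == pytest.approx(7.0 / math.sqrt(2.0), rel=1e-12)

    def test_identical_arrays_score_zero(self, small_sim):
        chip, treats, ctrls, _, _ = small_sim
        tab = score_pair(ctrls[0], ctrls[0], chip, {"TC"})
        assert np.all(tab.raw_scores == 0.0)
        assert tab.degenerate_normalization

    def test_matches_straight_line_oracle(self, small_sim):
        chip, treats, ctrls, _, _ = small_sim
        tab = score_pair(ctrls[0], treats[0], chip, {"TC"})
        oracle = oracle_score_pair(ctrls[0], treats[0], chip)
        got = dict(zip(tab.probeset_ids, tab.raw_scores))
        assert set(got) == set(oracle)
        for pid in oracle:
            assert got[pid] == pytest.approx(oracle[pid], rel=1e-12)


# ---------------------------------------------------------------------------
# normalization

class TestNormalizeScores:
    def test_symmetric_scores_center_to_zero(self):
        raw = np.array([-5.0, -4, -3, -2, -1, 1, 2, 3, 4, 5])
        norm = normalize_scores(raw)
        assert np.mean(norm) == pytest.approx(0.0, abs=1e-12)

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            normalize_scores(np.full(100, 3.3))

    def test_too_few_scores_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_scores(np.array([-2.0, -1, 0, 1, 2]))

    def test_outliers_survive_and_null_sd_is_one(self):
        rng = np.random.default_rng(8)
        raw = np.concatenate([rng.normal(0, 1, 10_000),
                              np.full(10, 50.0), np.full(10, -50.0)])
        norm = normalize_scores(raw)
        core = norm[:10_000]
        assert np.std(core, ddof=1) == pytest.approx(1.0, abs=0.05)
        assert np.mean(core) == pytest.approx(0.0, abs=0.03)
        assert np.all(np.abs(norm[10_000:]) > 3.0)

    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_equivariance(self, shift, scale):
        """Normalized scores are invariant under affine maps of the raw scores."""
        rng = np.random.default_rng(123)
        raw = rng.normal(2.0, 3.0, 500)
        base = normalize_scores(raw)
        moved = normalize_scores(raw * scale + shift)
        np.testing.assert_allclose(moved, base, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# score_pair properties

class TestScorePairProperties:
    def test_antisymmetry(self, small_sim):
        chip, treats, ctrls, _, _ = small_sim
        ab = score_pair(ctrls[0], treats[0], chip, {"TC"})
        ba = score_pair(treats[0], ctrls[0], chip, {"TC"})
        np.testing.assert_allclose(ab.raw_scores, -ba.raw_scores, atol=1e-9)
        np.testing.assert_allclose(ab.norm_scores, -ba.norm_scores, atol=1e-9)

    def test_scale_invariance(self, small_sim):
        chip, treats, ctrls, _, _ = small_sim
        base = score_pair(ctrls[0], treats[0], chip, {"TC"})
        for factor, side in ((10.0, "B"), (0.2, "A")):
            a, b = ctrls[0], treats[0]
            if side == "A":
                a = IntensityArray("ax", a.values * factor)
            else:
                b = IntensityArray("bx", b.values * factor)
            scaled = score_pair(a, b, chip, {"TC"})
            np.testing.assert_allclose(
                scaled.raw_scores, base.raw_scores, rtol=1e-9
            )
            np.testing.assert_allclose(
                scaled.norm_scores, base.norm_scores, rtol=1e-9, atol=1e-9
            )

    def test_gamma_bounds_scores_at_high_expression(self):
        """With SDT fixed, |score| saturates as expression grows (gamma cap)."""
        from gcscore import ProbesetDefinition
        from gcscore.scoring import CorrectedArray

        ps = ProbesetDefinition("TC1", "TC", tuple(range(10)))
        scaling = ScalingInfo(sf=1.0, rawq=2.5, sdt=10.0)
        prev = 0.0
        scores = []
        for mag in [10.0 ** k for k in range(6)]:
            ca = CorrectedArray("a", np.full(10, mag), np.arange(10), scaling, "GC")
            cb = CorrectedArray("b", np.full(10, 2 * mag), np.arange(10), scaling, "GC")
            s = score_probeset(ca, cb, ps, gamma=0.1)
            scores.append(s)
        assert all(b > a for a, b in zip(scores, scores[1:]))  # monotone rise
        ceiling = math.sqrt(10) * 1.0 / (0.1 * math.sqrt(5.0))
        assert scores[-1] < ceiling
        assert scores[-1] == pytest.approx(ceiling, rel=1e-3)  # saturates

    def test_pm_mm_equals_gc_when_mm_is_bin_median(self):
        """MM set to the raw BG median of its PM's GC bin reproduces the GC
        method exactly (the two corrections become the same subtraction)."""
        spec = SimulationSpec(n_probesets=40, probes_per_set=5, n_bg_per_gc=5,
                              seed=21, with_mm=True)
        chip = make_synthetic_chip(spec)
        treats, ctrls, _ = simulate_experiment(chip, spec, truth_seed=3)
        arrays = []
        bg = build_background_index(chip)
        for arr in (ctrls[0], treats[0]):
            vals = arr.values.copy()
            raw_medians = {g: np.median(arr.values[idx])
                           for g, idx in bg.gc_to_probes.items()}
            for pm, mm in chip.mm_pairing.items():
                vals[mm] = raw_medians[chip.probes[pm].gc_count]
            arrays.append(IntensityArray(arr.sample_id, vals))
        a, b = arrays
        t_gc = score_pair(a, b, chip, {"TC"}, method="GC")
        t_mm = score_pair(a, b, chip, {"TC"}, method="PMMM")
        assert t_gc.probeset_ids == t_mm.probeset_ids
        np.testing.assert_allclose(t_mm.raw_scores, t_gc.raw_scores, rtol=1e-12)
        np.testing.assert_allclose(t_mm.norm_scores, t_gc.norm_scores,
                                   rtol=1e-12, atol=1e-12)
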