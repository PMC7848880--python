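"""Core of the GCS-score algorithm.

The method compares two arrays probe by probe. Each array is scaled so the
median intensity of the probes at the chosen grouping level hits a target
value (default 500, the MAS5 convention); its noise floor ``rawQ`` is the
sample standard deviation of the bottom 2% of all probe intensities, and the
significant difference threshold is

    SDT = 4 * rawQ * SF.

Non-specific binding is removed either by subtracting, per PM probe, the
median of the scaled antigenomic background probes sharing its GC count
("GC" method, whole-transcriptome designs), or by subtracting the paired MM
probe ("PMMM" method, 3' IVT designs). For a probeset k of N probes the raw
score is the standardized sum of probe differences

    GCSs_k = sum_i (l_iB - l_iA) / (eps_i * sqrt(N)),
    eps_i  = sqrt(gamma^2 * (l_iA^2 + l_iB^2) + SDT_A^2 + SDT_B^2),

where l_i are background-corrected scaled intensities and gamma (default
0.1) caps the contribution of strongly expressed probes so scores measure
relative rather than absolute change. Raw scores are then centred and
scaled using the middle 98% of their distribution so that, absent widespread
differential expression, the output is approximately standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chip import (
    BackgroundIndex,
    ChipDefinition,
    MAX_GC,
    ProbesetDefinition,
    build_background_index,
    probes_for_level,
)
from .errors import DegenerateDistributionError, DegenerateInputError, ValidationError
from .io import IntensityArray

DEFAULT_GAMMA = 0.1
DEFAULT_TGT = 500.0
DEFAULT_TRIM = 0.01  # per tail, for score normalization
SF_TRIM = 0.02  # two-sided trim for the scaling median (no-op for a median)


@dataclass(frozen=True)
class ScalingInfo:
    """Per-array scaling metadata: SF, rawQ and SDT = 4*rawQ*SF."""

    sf: float
    rawq: float
    sdt: float
    tgt: float = DEFAULT_TGT


@dataclass
class CorrectedArray:
    """Background-corrected, scaled intensities over the grouping-level PM probes."""

    sample_id: str
    values: np.ndarray  # aligned with probe_index
    probe_index: np.ndarray
    scaling: ScalingInfo
    method: str  # "GC" | "PMMM"


@dataclass
class ScoreTable:
    """Raw and normalized GCS-scores of one array pair."""

    probeset_ids: list[str]
    levels: list[str]
    symbols: list[str]
    raw_scores: np.ndarray
    norm_scores: np.ndarray | None
    pair: tuple[str, str]
    level_set: frozenset[str]
    params: dict = field(default_factory=dict)
    scaling_a: ScalingInfo | None = None
    scaling_b: ScalingInfo | None = None

    @property
    def degenerate_normalization(self) -> bool:
        return self.norm_scores is None

    def effective_scores(self) -> np.ndarray:
        """Normalized scores, or raw scores when normalization was degenerate."""
        return self.raw_scores if self.norm_scores is None else self.norm_scores


# ---------------------------------------------------------------------------
# scaling

def compute_sf(intens: IntensityArray, chip: ChipDefinition,
               level_set, tgt: float = DEFAULT_TGT) -> float:
    """Scaling factor bringing the grouping-level median intensity to ``tgt``.

    The trimmed median of MAS5 is a plain median here: symmetric trimming
    does not move the median statistic.
    """
    idx = probes_for_level(chip, set(level_set))
    if idx.size == 0:
        raise DegenerateInputError(f"no probes at level(s) {sorted(level_set)}")
    med = float(np.median(intens.values[idx]))
    if med <= 0:
        raise DegenerateInputError(
            f"{intens.sample_id}: median grouping-level intensity is {med}; "
            "cannot scale"
        )
    return tgt / med


def compute_rawq(intens: IntensityArray) -> float:
    """Noise floor: sample SD of the bottom 2% of all probe intensities."""
    n = intens.values.size
    m = math.ceil(0.02 * n)
    if m < 2:
        raise DegenerateInputError(
            f"{intens.sample_id}: bottom-2% subset has {m} probe(s); "
            "need at least 2 to estimate the noise floor"
        )
    lowest = np.partition(intens.values, m - 1)[:m]
    return float(np.std(lowest, ddof=1))


def compute_sdt(rawq: float, sf: float) -> float:
    """Significant difference threshold, 4 * rawQ * SF."""
    if rawq < 0 or sf <= 0:
        raise DegenerateInputError(f"invalid rawq={rawq}, sf={sf}")
    return 4.0 * rawq * sf


def make_scaling(intens: IntensityArray, chip: ChipDefinition,
                 level_set, tgt: float = DEFAULT_TGT) -> ScalingInfo:
    """Compute SF, rawQ and SDT for one array."""
    sf = compute_sf(intens, chip, level_set, tgt)
    rawq = compute_rawq(intens)
    return ScalingInfo(sf=sf, rawq=rawq, sdt=compute_sdt(rawq, sf), tgt=tgt)


# ---------------------------------------------------------------------------
# background correction

def gc_background_medians(scaled: np.ndarray, bg: BackgroundIndex) -> np.ndarray:
    """Median scaled background intensity per GC count, dense over 0..25.

    GC bins without background probes borrow the nearest available bin,
    breaking distance ties toward the lower GC count.
    """
    if not bg.available_gc:
        raise ValidationError("background index is empty")
    med = np.full(MAX_GC + 1, np.nan)
    for g, idx in bg.gc_to_probes.items():
        med[g] = np.median(scaled[idx])
    avail = np.array(bg.available_gc)
    for g in range(MAX_GC + 1):
        if np.isnan(med[g]):
            dist = np.abs(avail - g)
            # argmin returns the first minimum; avail ascending -> lower gc wins ties
            med[g] = med[avail[int(np.argmin(dist))]]
    return med


def correct_gc(intens: IntensityArray, chip: ChipDefinition, level_set,
               scaling: ScalingInfo,
               bg: BackgroundIndex | None = None) -> CorrectedArray:
    """GC-content background correction: l_i = SF*raw_i - median_bg[gc_i].

    Background medians are computed on SF-scaled intensities, so signal and
    background live on the same scale. Values are not floored at zero — the
    score is difference-based and tolerates negative corrected intensities.
    """
    if bg is None:
        bg = build_background_index(chip)
    idx = probes_for_level(chip, set(level_set))
    scaled = intens.values * scaling.sf
    med = gc_background_medians(scaled, bg)
    gc = chip.gc[idx]
    if np.any(gc < 0):
        bad = idx[gc < 0][:5]
        raise ValidationError(f"PM probe(s) lacking gc_count: {bad.tolist()}")
    return CorrectedArray(intens.sample_id, scaled[idx] - med[gc], idx, scaling, "GC")


def correct_pm_mm(intens: IntensityArray, chip: ChipDefinition, level_set,
                  scaling: ScalingInfo) -> CorrectedArray:
    """Legacy mismatch correction: l_i = SF * (PM_i - MM_i)."""
    idx = probes_for_level(chip, set(level_set))
    if not chip.mm_pairing:
        raise ValidationError(f"chip {chip.name!r} defines no PM->MM pairing")
    try:
        mm_idx = np.array([chip.mm_pairing[i] for i in idx], dtype=np.int64)
    except KeyError as e:
        raise ValidationError(f"PM probe {e.args[0]} has no MM partner") from e
    vals = scaling.sf * (intens.values[idx] - intens.values[mm_idx])
    return CorrectedArray(intens.sample_id, vals, idx, scaling, "PMMM")


# ---------------------------------------------------------------------------
# the score

def probe_epsilon(la: float, lb: float, sdt_a: float, sdt_b: float,
                  gamma: float = DEFAULT_GAMMA) -> float:
    """Heteroscedastic per-probe error term.

    eps = sqrt(gamma^2*(la^2 + lb^2) + sdt_a^2 + sdt_b^2); the proportional
    part uses the *sum* of squared corrected intensities, the only reading
    that keeps the radicand non-negative and the error symmetric in the two
    arrays.
    """
    eps = math.sqrt(gamma * gamma * (la * la + lb * lb)
                    + sdt_a * sdt_a + sdt_b * sdt_b)
    if eps == 0.0:
        raise DegenerateInputError(
            "probe error term is zero (all of l_A, l_B, SDT_A, SDT_B vanish)"
        )
    return eps


def _epsilon_vector(la: np.ndarray, lb: np.ndarray, sdt_a: float, sdt_b: float,
                    gamma: float) -> np.ndarray:
    return np.sqrt(gamma * gamma * (la * la + lb * lb)
                   + sdt_a * sdt_a + sdt_b * sdt_b)


def score_probeset(corr_a: CorrectedArray, corr_b: CorrectedArray,
                   probeset: ProbesetDefinition,
                   gamma: float = DEFAULT_GAMMA) -> float:
    """Raw GCS-score of one probeset: sum_i (l_iB - l_iA) / (eps_i*sqrt(N))."""
    pos = {int(i): k for k, i in enumerate(corr_a.probe_index)}
    try:
        sel = [pos[i] for i in probeset.probe_indices]
    except KeyError as e:
        raise ValidationError(
            f"probeset {probeset.probeset_id}: probe {e.args[0]} not in "
            "corrected array"
        ) from e
    la = corr_a.values[sel]
    lb = corr_b.values[sel]
    eps = _epsilon_vector(la, lb, corr_a.scaling.sdt, corr_b.scaling.sdt, gamma)
    if np.any(eps == 0.0):
        bad = probeset.probe_indices[int(np.argmax(eps == 0.0))]
        raise DegenerateInputError(
            f"probeset {probeset.probeset_id}: probe {bad} has zero error term"
        )
    n = len(sel)
    return float(np.sum((lb - la) / (eps * math.sqrt(n))))


def _trunc_consistency(trim: float) -> float:
    """SD of a standard normal truncated to its middle (1-2*trim) mass.

    Dividing the trimmed sample SD by this factor makes it a consistent
    estimator of the full SD for Gaussian-like scores, so that a null score
    distribution is normalized to SD 1 overall (not just inside the trim).
    """
    if trim <= 0:
        return 1.0
    z = stats.norm.ppf(1.0 - trim)
    return math.sqrt(1.0 - 2.0 * z * stats.norm.pdf(z) / (1.0 - 2.0 * trim))


def normalize_scores(raw_scores: np.ndarray, trim: float = DEFAULT_TRIM) -> np.ndarray:
    """Centre and scale raw scores using their middle (1-2*trim) mass.

    The location and spread are estimated from the scores between the
    ``trim`` and ``1-trim`` percentiles (linear interpolation, inclusive
    bounds); the trimmed SD is rescaled by the Gaussian truncation constant
    so the estimate targets the full-distribution SD. All scores — including
    the trimmed tails — are transformed, so genuine outliers survive with
    large |score|.
    """
    raw = np.asarray(raw_scores, dtype=np.float64)
    finite = raw[np.isfinite(raw)]
    if finite.size < 10:
        raise DegenerateInputError(
            f"need at least 10 finite raw scores to normalize, got {finite.size}"
        )
    lo, hi = np.percentile(finite, [100.0 * trim, 100.0 * (1.0 - trim)])
    core = finite[(finite >= lo) & (finite <= hi)]
    m = float(np.mean(core))
    s = float(np.std(core, ddof=1))
    if s == 0.0:
        raise DegenerateDistributionError(
            "trimmed score distribution has zero spread; normalization undefined"
        )
    return (raw - m) / (s / _trunc_consistency(trim))


def score_pair(arr_a: IntensityArray, arr_b: IntensityArray,
               chip: ChipDefinition, level_set,
               method: str = "GC",
               gamma: float = DEFAULT_GAMMA,
               tgt: float = DEFAULT_TGT,
               trim: float = DEFAULT_TRIM) -> ScoreTable:
    """Score every probeset at ``level_set`` between two arrays.

    Orchestration: per-array SF/rawQ/SDT, background correction by
    ``method`` ("GC" or "PMMM"), raw probeset scores, then middle-98%
    normalization. If the raw score distribution is degenerate (e.g. the two
    arrays are identical) the table is returned with ``norm_scores=None``.
    """
    level_set = frozenset(level_set)
    for arr in (arr_a, arr_b):
        if arr.values.size != chip.n_probes:
            raise ValidationError(
                f"{arr.sample_id}: length {arr.values.size} != chip n_probes "
                f"{chip.n_probes}"
            )
    scal_a = make_scaling(arr_a, chip, level_set, tgt)
    scal_b = make_scaling(arr_b, chip, level_set, tgt)
    if method == "GC":
        bg = build_background_index(chip)
        corr_a = correct_gc(arr_a, chip, level_set, scal_a, bg)
        corr_b = correct_gc(arr_b, chip, level_set, scal_b, bg)
    elif method == "PMMM":
        corr_a = correct_pm_mm(arr_a, chip, level_set, scal_a)
        corr_b = correct_pm_mm(arr_b, chip, level_set, scal_b)
    else:
        raise ValidationError(f"unknown correction method {method!r}")

    psets = chip.probesets_at(set(level_set))
    if not psets:
        raise ValidationError(f"no probesets at level(s) {sorted(level_set)}")

    pos = np.full(chip.n_probes, -1, dtype=np.int64)
    pos[corr_a.probe_index] = np.arange(corr_a.probe_index.size)
    eps = _epsilon_vector(corr_a.values, corr_b.values,
                          scal_a.sdt, scal_b.sdt, gamma)
    if np.any(eps == 0.0):
        bad = corr_a.probe_index[int(np.argmax(eps == 0.0))]
        raise DegenerateInputError(f"probe {bad} has zero error term")
    ratio = (corr_b.values - corr_a.values) / eps

    # segment-sum the per-probe ratios into probesets
    seg_ids = np.concatenate(
        [np.full(len(ps.probe_indices), k, dtype=np.int64)
         for k, ps in enumerate(psets)]
    )
    flat = pos[np.concatenate([np.asarray(ps.probe_indices) for ps in psets])]
    sums = np.bincount(seg_ids, weights=ratio[flat], minlength=len(psets))
    sizes = np.bincount(seg_ids, minlength=len(psets))
    raw = sums / np.sqrt(sizes)

    try:
        norm = normalize_scores(raw, trim)
    except DegenerateDistributionError:
        norm = None
    return ScoreTable(
        probeset_ids=[ps.probeset_id for ps in psets],
        levels=[ps.level for ps in psets],
        symbols=[ps.symbol for ps in psets],
        raw_scores=raw,
        norm_scores=norm,
        pair=(arr_a.sample_id, arr_b.sample_id),
        level_set=level_set,
        params={"gamma": gamma, "tgt": tgt, "trim": trim, "method": method,
                "level_set": sorted(level_set)},
        scaling_a=scal_a,
        scaling_b=scal_b,
    )
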