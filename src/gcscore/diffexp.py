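"""Replicated-design workflow: batch pairwise scoring, replicate averaging,
one-class SAM permutation FDR, and significance calling.

Every treatment array is scored against every control array (T*C pairs,
control as array A so positive scores mean "up in treatment"). Scores are
averaged per treatment replicate over its C control comparisons — keeping T
semi-independent values per probeset instead of inflating n to T*C — and the
mean of those T replicate averages is the effect-size summary AvgSs. The T
replicate averages feed a one-class SAM test of mean != 0, and probesets are
called significant when q <= fdr_cut and |AvgSs| > avgss_cut (default 1.8).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .chip import ChipDefinition
from .errors import GcscoreError, ValidationError
from .io import read_intensities
from .scoring import DEFAULT_GAMMA, DEFAULT_TGT, DEFAULT_TRIM, score_pair

DEFAULT_AVGSS_CUT = 1.8


@dataclass
class ComparisonDesign:
    """Treatment and control samples of one comparison."""

    treatments: list[tuple[str, str]]  # (sample_id, intensity path)
    controls: list[tuple[str, str]]

    def __post_init__(self):
        if not self.treatments or not self.controls:
            raise ValidationError(
                "design needs at least one treatment and one control sample"
            )
        ids = [s for s, _ in self.treatments] + [s for s, _ in self.controls]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in design")


def read_design(path: str) -> ComparisonDesign:
    """Read a design CSV with columns sample_id, path, group(treatment|control).

    Relative intensity paths are resolved against the design file's directory.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    for col in ("sample_id", "path", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    base = os.path.dirname(os.path.abspath(path))
    treats, ctrls = [], []
    for row in df.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        g = row.group.strip().lower()
        if g == "treatment":
            treats.append((row.sample_id, p))
        elif g == "control":
            ctrls.append((row.sample_id, p))
        else:
            raise ValidationError(
                f"{path}: sample {row.sample_id}: group must be "
                f"'treatment' or 'control', got {row.group!r}"
            )
    return ComparisonDesign(treats, ctrls)


@dataclass
class ScoreMatrix:
    """Normalized scores of all T*C treatment-control pairs (treatment-major)."""

    probeset_ids: list[str]
    symbols: list[str]
    pair_labels: list[tuple[str, str]]  # (treatment_id, control_id)
    scores: np.ndarray  # (n_probesets, T*C)


@dataclass
class RepAverages:
    """Per-treatment-replicate mean scores and their grand mean AvgSs."""

    probeset_ids: list[str]
    symbols: list[str]
    treatment_ids: list[str]
    columns: np.ndarray  # (n_probesets, T)
    avg_ss: np.ndarray  # row mean of columns

    @classmethod
    def from_columns(cls, probeset_ids, treatment_ids, columns, symbols=None):
        columns = np.asarray(columns, dtype=np.float64)
        return cls(
            probeset_ids=list(probeset_ids),
            symbols=list(symbols) if symbols is not None else [""] * len(probeset_ids),
            treatment_ids=list(treatment_ids),
            columns=columns,
            avg_ss=columns.mean(axis=1),
        )


@dataclass
class SamResult:
    """One-class SAM output: d statistics, fudge factor s0 and q-values."""

    probeset_ids: list[str]
    d: np.ndarray
    s0: float
    qvalue: np.ndarray
    n_permutations: int
    seed: int
    pi0: float = 1.0


def run_batch(design: ComparisonDesign, chip: ChipDefinition, level_set,
              method: str = "GC",
              gamma: float = DEFAULT_GAMMA,
              tgt: float = DEFAULT_TGT,
              trim: float = DEFAULT_TRIM) -> ScoreMatrix:
    """Score every (treatment, control) pair; columns in treatment-major order.

    Each column holds the normalized scores of ``score_pair(control,
    treatment)``; when normalization is degenerate for a pair (identical
    arrays) the raw scores are used for that column.
    """
    arrays = {}
    for sid, path in design.treatments + design.controls:
        try:
            arrays[sid] = read_intensities(path, chip, sample_id=sid)
        except Exception as e:
            raise type(e)(f"sample {sid} ({path}): {e}") from e
    cols = []
    labels = []
    ids = symbols = None
    for t_id, _ in design.treatments:
        for c_id, _ in design.controls:
            try:
                tab = score_pair(arrays[c_id], arrays[t_id], chip, level_set,
                                 method=method, gamma=gamma, tgt=tgt, trim=trim)
            except GcscoreError as e:
                raise type(e)(f"pair ({t_id}, {c_id}): {e}") from e
            if ids is None:
                ids, symbols = tab.probeset_ids, tab.symbols
            cols.append(tab.effective_scores())
            labels.append((t_id, c_id))
    return ScoreMatrix(ids, symbols, labels, np.column_stack(cols))


def replicate_averages(m: ScoreMatrix, design: ComparisonDesign) -> RepAverages:
    """Average each treatment replicate over its control comparisons."""
    n_c = len(design.controls)
    t_ids = [t for t, _ in design.treatments]
    expected = [(t, c) for t, _ in design.treatments for c, _ in design.controls]
    if m.pair_labels != expected:
        raise ValidationError("score matrix columns do not match the design")
    cols = np.column_stack(
        [m.scores[:, k * n_c:(k + 1) * n_c].mean(axis=1) for k in range(len(t_ids))]
    )
    return RepAverages.from_columns(m.probeset_ids, t_ids, cols, m.symbols)


# ---------------------------------------------------------------------------
# one-class SAM

_EXHAUSTIVE_LIMIT = 4096
_S0_ALPHAS = np.arange(0, 101, 5) / 100.0


def _d_stat(x: np.ndarray, s0: float) -> np.ndarray:
    t = x.shape[1]
    xbar = x.mean(axis=1)
    se = x.std(axis=1, ddof=1) / math.sqrt(t)
    return xbar / (se + s0)


def _choose_s0(x: np.ndarray) -> float:
    """Fudge factor: percentile of the row standard errors minimizing the
    coefficient of variation of binwise MADs of d (canonical SAM selection).
    """
    t = x.shape[1]
    xbar = x.mean(axis=1)
    se = x.std(axis=1, ddof=1) / math.sqrt(t)
    candidates = np.quantile(se, _S0_ALPHAS)
    edges = np.quantile(se, np.linspace(0.0, 1.0, 101))
    bins = np.clip(np.searchsorted(edges, se, side="right") - 1, 0, 99)
    best_cv, best_s0 = np.inf, None
    for s0 in candidates:
        d = xbar / (se + s0)
        mads = []
        for b in np.unique(bins):
            grp = d[bins == b]
            if grp.size:
                mads.append(median_abs_deviation(grp, scale="normal"))
        mads = np.asarray(mads)
        if mads.size < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads)
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    if best_s0 is None:
        best_s0 = float(np.median(se))
    return best_s0


def _sign_matrix(t: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Sign-flip vectors: exhaustive when 2^T <= 4096, else sampled
    without replacement."""
    total = 2 ** t
    if total <= _EXHAUSTIVE_LIMIT:
        codes = np.arange(total)
    else:
        n_perm = min(n_perm, _EXHAUSTIVE_LIMIT)
        chosen: set[int] = set()
        while len(chosen) < n_perm:
            chosen.update(
                int(v) for v in rng.integers(0, total, size=n_perm - len(chosen))
            )
        codes = np.array(sorted(chosen))
    bits = (codes[:, None] >> np.arange(t)) & 1
    return np.where(bits == 1, 1.0, -1.0)


def sam_one_class(reps: RepAverages, n_perm: int = 1000,
                  seed: int = 0) -> SamResult:
    """One-class SAM test of mean score != 0 across treatment replicates.

    d_i = xbar_i / (se_i + s0); the null distribution of d comes from
    sign-flipping the T columns (exhaustive enumeration of all 2^T
    assignments when 2^T <= 4096, otherwise ``n_perm`` sampled sign
    vectors). The q-value of probeset i is

        q_i = pi0 * median_b #{ |d_b| >= |d_i| } / #{ |d_obs| >= |d_i| },

    monotonized to be non-increasing in |d| and clipped to [0, 1], with
    pi0 = min(1, 2 * fraction of observed d inside the permuted-d IQR).
    """
    x = np.asarray(reps.columns, dtype=np.float64)
    n, t = x.shape
    if t < 2:
        raise ValidationError(
            f"one-class SAM needs >= 2 treatment replicates, got {t}"
        )
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValidationError("replicate averages contain non-finite values")

    rng = np.random.default_rng(seed)
    s0 = _choose_s0(x)
    d = _d_stat(x, s0)
    signs = _sign_matrix(t, n_perm, rng)
    b = signs.shape[0]

    absd = np.abs(d)
    order = np.sort(absd)
    # r_i = #{j : |d_j| >= |d_i|}
    r = n - np.searchsorted(order, absd, side="left")

    counts = np.empty((b, n))
    perm_all = np.empty((b, n))
    for k in range(b):
        dp = _d_stat(x * signs[k], s0)
        perm_all[k] = dp
        sp = np.sort(np.abs(dp))
        counts[k] = n - np.searchsorted(sp, absd, side="left")
    med_counts = np.median(counts, axis=0)

    q25, q75 = np.percentile(perm_all.ravel(), [25.0, 75.0])
    pi0 = min(1.0, 2.0 * float(np.mean((d >= q25) & (d <= q75))))

    q = pi0 * med_counts / np.maximum(r, 1)
    # monotonize: larger |d| never gets a larger q (running min from the
    # least significant end), then clip into [0, 1]
    desc = np.argsort(-absd, kind="mergesort")
    q_desc = q[desc]
    q_desc = np.minimum.accumulate(q_desc[::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[desc] = q_desc
    q_mono = np.clip(q_mono, 0.0, 1.0)

    return SamResult(
        probeset_ids=list(reps.probeset_ids),
        d=d,
        s0=s0,
        qvalue=q_mono,
        n_permutations=b,
        seed=seed,
        pi0=pi0,
    )


def select_significant(sam: SamResult, reps: RepAverages, fdr_cut: float,
                       avgss_cut: float = DEFAULT_AVGSS_CUT):
    """Probesets with q <= fdr_cut and |AvgSs| > avgss_cut, by |AvgSs| desc."""
    if sam.probeset_ids != reps.probeset_ids:
        raise ValidationError("SAM result and replicate averages are misaligned")
    keep = (sam.qvalue <= fdr_cut) & (np.abs(reps.avg_ss) > avgss_cut)
    rows = [
        (reps.probeset_ids[i], float(reps.avg_ss[i]), float(sam.qvalue[i]))
        for i in np.flatnonzero(keep)
    ]
    rows.sort(key=lambda r: (-abs(r[1]), r[0]))
    return rows


# ---------------------------------------------------------------------------
# result writers

def write_score_matrix(m: ScoreMatrix, path: str) -> None:
    cols = {"probeset_id": m.probeset_ids, "symbol": m.symbols}
    for (t, c), col in zip(m.pair_labels, m.scores.T):
        cols[f"{t}_vs_{c}"] = col
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_rep_averages(reps: RepAverages, path: str) -> None:
    cols = {"probeset_id": reps.probeset_ids, "symbol": reps.symbols}
    for t, col in zip(reps.treatment_ids, reps.columns.T):
        cols[t] = col
    cols["avg_ss"] = reps.avg_ss
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_rep_averages(path: str) -> RepAverages:
    """Read a replicate-averages CSV written by :func:`write_rep_averages`."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("probeset_id", "avg_ss"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    t_cols = [c for c in df.columns if c not in ("probeset_id", "symbol", "avg_ss")]
    if not t_cols:
        raise ValidationError(f"{path}: no treatment-replicate columns")
    return RepAverages.from_columns(
        df["probeset_id"].tolist(), t_cols, df[t_cols].to_numpy(),
        df["symbol"].tolist() if "symbol" in df.columns else None,
    )


def write_results(sam: SamResult, reps: RepAverages, fdr_cut: float,
                  avgss_cut: float, path: str) -> None:
    """Full per-probeset results: probeset_id, symbol, avg_ss, d, qvalue, selected."""
    sel = (sam.qvalue <= fdr_cut) & (np.abs(reps.avg_ss) > avgss_cut)
    pd.DataFrame(
        {
            "probeset_id": reps.probeset_ids,
            "symbol": reps.symbols,
            "avg_ss": reps.avg_ss,
            "d": sam.d,
            "qvalue": sam.qvalue,
            "selected": sel.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_run_metadata(path: str, **fields) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
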