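"""Array intensity readers and score writers.

Two intensity formats are supported: a plain two-column TSV
(``probe_index``, ``intensity``) and the legacy plain-text CEL dialect
(version 3). Binary Calvin/AGCC CEL files are detected and rejected with a
message advising external conversion — decoding a vendor binary container is
orthogonal to the scoring method.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip import ChipDefinition
from .errors import UnsupportedFormatError, ValidationError


@dataclass
class IntensityArray:
    """Raw probe intensities of one array, dense over probe_index."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("intensity vector must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.sample_id}: non-finite intensity")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.sample_id}: negative intensity")


def _check_length(sample_id: str, n: int, chip: ChipDefinition) -> None:
    if n != chip.n_probes:
        raise ValidationError(
            f"{sample_id}: {n} intensities but chip {chip.name!r} has "
            f"{chip.n_probes} probes"
        )


def read_intensity_table(path: str, chip: ChipDefinition,
                         sample_id: str | None = None) -> IntensityArray:
    """Read a two-column TSV (probe_index, intensity) into a dense vector.

    Every probe_index ``0 .. n_probes-1`` must appear exactly once; row
    order is irrelevant.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    for col in ("probe_index", "intensity"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    idx = df["probe_index"].to_numpy(dtype=np.int64)
    vals = df["intensity"].to_numpy(dtype=np.float64)
    n = chip.n_probes
    if len(idx) != n or not np.array_equal(np.sort(idx), np.arange(n)):
        counts = np.bincount(idx[(idx >= 0) & (idx < n)], minlength=n)
        missing = np.flatnonzero(counts == 0)
        dupes = np.flatnonzero(counts > 1)
        detail = []
        if missing.size:
            detail.append(f"missing probe_index {missing[:5].tolist()}")
        if dupes.size:
            detail.append(f"duplicate probe_index {dupes[:5].tolist()}")
        out = np.flatnonzero((idx < 0) | (idx >= n))
        if out.size:
            detail.append(f"out-of-range probe_index {idx[out[:5]].tolist()}")
        raise ValidationError(f"{path}: " + "; ".join(detail))
    dense = np.empty(n, dtype=np.float64)
    dense[idx] = vals
    return IntensityArray(sample_id or _stem(path), dense)


def write_intensity_table(arr: IntensityArray, path: str) -> None:
    """Write an intensity vector as a two-column TSV (full float precision)."""
    pd.DataFrame(
        {"probe_index": np.arange(len(arr.values)), "intensity": arr.values}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _stem(path: str) -> str:
    return os.path.splitext(os.path.basename(path))[0]


# ---------------------------------------------------------------------------
# text CEL (version 3)

_CALVIN_MAGICS = (b";\x01", b"@\x00", b"\x40", b"\x3b")


def read_cel_text(path: str, chip: ChipDefinition,
                  sample_id: str | None = None) -> IntensityArray:
    """Read a plain-text CEL (version 3) file.

    The cell at grid position (X, Y) maps to ``probe_index = Y*Cols + X``
    (row-major in Y); the MEAN column is taken as the probe intensity and
    STDV/NPIXELS are ignored.
    """
    with open(path, "rb") as fh:
        head = fh.read(64)
    if not head.lstrip().startswith(b"[CEL]"):
        if b"\x00" in head or head[:1] in (b";", b"@", b"\x3b", b"\x40"):
            raise UnsupportedFormatError(
                f"{path}: binary (Calvin/AGCC or XDA) CEL file; only the "
                "plain-text version-3 dialect is read natively — convert "
                "externally (e.g. with Affymetrix apt-cel-convert) first"
            )
        raise ValidationError(f"{path}: not a CEL file (no [CEL] section)")

    section = None
    version = None
    cols = rows = None
    n_cells = None
    header_fields: dict[str, str] = {}
    values: np.ndarray | None = None
    seen = None
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].upper()
                continue
            if "=" in line:
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if section == "CEL" and key == "Version":
                    version = val
                    if val != "3":
                        raise UnsupportedFormatError(
                            f"{path}: CEL version {val}; only version 3 "
                            "(plain text) is supported — convert externally"
                        )
                elif section == "HEADER":
                    header_fields[key] = val
                elif section == "INTENSITY":
                    if key == "NumberCells":
                        n_cells = int(val)
                    elif key == "CellHeader":
                        cols = int(header_fields.get("Cols", "0"))
                        rows = int(header_fields.get("Rows", "0"))
                        if cols <= 0 or rows <= 0:
                            raise ValidationError(
                                f"{path}: [HEADER] lacks positive Cols/Rows"
                            )
                        values = np.full(cols * rows, np.nan)
                        seen = np.zeros(cols * rows, dtype=bool)
                continue
            if section == "INTENSITY" and values is not None:
                parts = line.split()
                if len(parts) < 3:
                    raise ValidationError(f"{path}: malformed intensity row {line!r}")
                x, y = int(parts[0]), int(parts[1])
                if not (0 <= x < cols and 0 <= y < rows):
                    raise ValidationError(
                        f"{path}: cell ({x},{y}) outside {cols}x{rows} grid"
                    )
                i = y * cols + x
                if seen[i]:
                    raise ValidationError(f"{path}: duplicate cell ({x},{y})")
                seen[i] = True
                values[i] = float(parts[2])
    if version is None:
        raise ValidationError(f"{path}: [CEL] section lacks Version")
    if values is None:
        raise ValidationError(f"{path}: no [INTENSITY] section")
    if not seen.all():
        first = int(np.flatnonzero(~seen)[0])
        raise ValidationError(
            f"{path}: missing intensity for cell index {first} "
            f"(x={first % cols}, y={first // cols})"
        )
    if n_cells is not None and n_cells != values.size:
        raise ValidationError(
            f"{path}: NumberCells={n_cells} but grid holds {values.size}"
        )
    _check_length(path, values.size, chip)
    return IntensityArray(sample_id or _stem(path), values)


def write_cel_text(arr: IntensityArray, path: str, cols: int | None = None) -> None:
    """Write an intensity vector as a version-3 plain-text CEL file.

    ``cols`` defaults to the largest divisor of ``n`` not exceeding
    ``sqrt(n)`` being used as the row count — any (Cols, Rows) factorisation
    with ``Cols*Rows == n`` round-trips identically.
    """
    n = len(arr.values)
    if cols is None:
        rows = max(d for d in range(1, int(math.isqrt(n)) + 1) if n % d == 0)
        cols = n // rows
    else:
        if n % cols != 0:
            raise ValidationError(f"cols={cols} does not divide n={n}")
        rows = n // cols
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("[CEL]\nVersion=3\n\n[HEADER]\n")
        fh.write(f"Cols={cols}\nRows={rows}\n\n[INTENSITY]\n")
        fh.write(f"NumberCells={n}\nCellHeader=X\tY\tMEAN\tSTDV\tNPIXELS\n")
        for i, v in enumerate(arr.values):
            x, y = i % cols, i // cols
            fh.write(f"{x}\t{y}\t{float(v)!r}\t0.0\t9\n")


def read_intensities(path: str, chip: ChipDefinition,
                     sample_id: str | None = None) -> IntensityArray:
    """Dispatch on content: text CEL if the file starts with ``[CEL]``, else TSV."""
    with open(path, "rb") as fh:
        head = fh.read(16)
    if head.lstrip().startswith(b"[CEL]") or b"\x00" in head:
        return read_cel_text(path, chip, sample_id)
    return read_intensity_table(path, chip, sample_id)


# ---------------------------------------------------------------------------
# score output

def write_score_table(table, path: str) -> None:
    """Write a :class:`~gcscore.scoring.ScoreTable` as CSV.

    Columns: probeset_id, level, symbol, gcs_score (normalized; falls back
    to the raw score when normalization was degenerate), raw_score. Rows are
    ordered by ascending probeset_id.
    """
    df = pd.DataFrame(
        {
            "probeset_id": table.probeset_ids,
            "level": table.levels,
            "symbol": table.symbols,
            "gcs_score": table.effective_scores(),
            "raw_score": table.raw_scores,
        }
    ).sort_values("probeset_id", kind="mergesort")
    df.to_csv(path, index=False, float_format="%.17g")
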