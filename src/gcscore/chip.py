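"""Chip layout model: probes, GC counts, probeset groupings, background index.

A chip definition describes everything the scoring algorithm needs to know
about an array design: which linear probe positions are perfect-match (PM)
probes, which are mismatch (MM) partners (3' IVT designs only), and which are
antigenomic background (BG) probes with no genomic target; the G+C base count
of each 25-mer probe; and how PM probes group into probesets at up to three
analysis levels — transcript clusters (TC, gene level), probe selection
regions (PSR, exon level) and exon-exon junctions (JUC).

Chip definitions are stored as an open three-table TSV bundle
(``probes.tsv``, ``probesets.tsv``, ``mapping.tsv``) in one directory; see
:func:`load_chip_definition` / :func:`write_chip_definition`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LEVELS = ("TC", "PSR", "JUC")
ROLES = ("PM", "MM", "BG")

#: 25-mer convention: a probe contains between 0 and 25 G+C bases.
MAX_GC = 25


@dataclass(frozen=True)
class ProbeRecord:
    """One physical probe cell.

    ``probe_index`` is the 0-based position of the probe in the per-array
    intensity vector. ``gc_count`` is the number of G+C bases in the 25-mer
    (required for PM and BG probes; may be ``None`` for MM probes).
    """

    probe_index: int
    gc_count: int | None
    role: str


@dataclass(frozen=True)
class ProbesetDefinition:
    """A named group of PM probes at one analysis level."""

    probeset_id: str
    level: str
    probe_indices: tuple[int, ...]
    annotation: dict = field(default_factory=dict)

    @property
    def symbol(self) -> str:
        return self.annotation.get("symbol", "")


class ChipDefinition:
    """Validated chip layout.

    Parameters
    ----------
    name
        Free-text chip name.
    probes
        One :class:`ProbeRecord` per probe cell; ``probe_index`` values must
        be exactly ``0 .. len(probes)-1`` (the intensity vector is dense).
    probesets
        Mapping probeset_id -> :class:`ProbesetDefinition`.
    mm_pairing
        Optional mapping PM probe_index -> MM probe_index (3' IVT designs).
    """

    def __init__(
        self,
        name: str,
        probes: list[ProbeRecord],
        probesets: dict[str, ProbesetDefinition],
        mm_pairing: dict[int, int] | None = None,
    ):
        self.name = name
        self.probes = list(probes)
        self.probesets = dict(probesets)
        self.mm_pairing = dict(mm_pairing) if mm_pairing else None
        self._validate()
        # cached role/gc vectors for fast scoring
        self.roles = np.array([p.role for p in self.probes])
        self.gc = np.array(
            [-1 if p.gc_count is None else p.gc_count for p in self.probes],
            dtype=np.int64,
        )

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def levels(self) -> set[str]:
        return {ps.level for ps in self.probesets.values()}

    def probesets_at(self, level_set: set[str]) -> list[ProbesetDefinition]:
        """Probesets whose level is in ``level_set``, ascending by id."""
        bad = set(level_set) - set(LEVELS)
        if bad:
            raise ValidationError(f"unknown analysis level(s): {sorted(bad)}")
        return sorted(
            (ps for ps in self.probesets.values() if ps.level in level_set),
            key=lambda ps: ps.probeset_id,
        )

    def _validate(self) -> None:
        n = len(self.probes)
        if n == 0:
            raise ValidationError("chip has no probes")
        idx = [p.probe_index for p in self.probes]
        if sorted(idx) != list(range(n)):
            raise ValidationError(
                "probe_index values must be exactly 0..n_probes-1 without gaps "
                "or duplicates"
            )
        self.probes.sort(key=lambda p: p.probe_index)
        for p in self.probes:
            if p.role not in ROLES:
                raise ValidationError(
                    f"probe {p.probe_index}: invalid role {p.role!r}"
                )
            if p.role in ("PM", "BG"):
                if p.gc_count is None:
                    raise ValidationError(
                        f"probe {p.probe_index}: {p.role} probe lacks gc_count"
                    )
            if p.gc_count is not None and not (0 <= p.gc_count <= MAX_GC):
                raise ValidationError(
                    f"probe {p.probe_index}: gc_count {p.gc_count} outside "
                    f"[0, {MAX_GC}]"
                )
        role_of = {p.probe_index: p.role for p in self.probes}
        # per-level membership uniqueness; PSR and JUC share one exon-level
        # namespace (a PM probe sits in at most one TC and one PSR-or-JUC set)
        seen: dict[str, set[int]] = {"TC": set(), "EXON": set()}
        for ps in self.probesets.values():
            if ps.level not in LEVELS:
                raise ValidationError(
                    f"probeset {ps.probeset_id}: invalid level {ps.level!r}"
                )
            if len(ps.probe_indices) == 0:
                raise ValidationError(f"probeset {ps.probeset_id}: empty")
            if len(set(ps.probe_indices)) != len(ps.probe_indices):
                raise ValidationError(
                    f"probeset {ps.probeset_id}: duplicate probe_index"
                )
            ns = "TC" if ps.level == "TC" else "EXON"
            for i in ps.probe_indices:
                if i not in role_of:
                    raise ValidationError(
                        f"probeset {ps.probeset_id} references probe_index {i} "
                        f"not on the chip"
                    )
                if role_of[i] != "PM":
                    raise ValidationError(
                        f"probeset {ps.probeset_id} references probe_index {i} "
                        f"with role {role_of[i]} (must be PM)"
                    )
                if i in seen[ns]:
                    raise ValidationError(
                        f"probe_index {i} belongs to more than one probeset at "
                        f"the {'gene' if ns == 'TC' else 'exon'} level"
                    )
                seen[ns].add(i)
        if self.mm_pairing:
            mm_targets = list(self.mm_pairing.values())
            if len(set(mm_targets)) != len(mm_targets):
                raise ValidationError("mm_pairing maps two PM probes to one MM")
            for pm, mm in self.mm_pairing.items():
                if role_of.get(pm) != "PM":
                    raise ValidationError(
                        f"mm_pairing key {pm} is not a PM probe"
                    )
                if role_of.get(mm) != "MM":
                    raise ValidationError(
                        f"mm_pairing value {mm} is not an MM probe"
                    )


@dataclass
class BackgroundIndex:
    """Antigenomic background probes grouped by GC count."""

    gc_to_probes: dict[int, np.ndarray]
    available_gc: list[int]


def build_background_index(chip: ChipDefinition) -> BackgroundIndex:
    """Group the chip's BG probes by GC count.

    Raises :class:`ValidationError` if the chip carries no antigenomic
    probes (GC background correction is then impossible).
    """
    groups: dict[int, list[int]] = {}
    for p in chip.probes:
        if p.role == "BG":
            groups.setdefault(p.gc_count, []).append(p.probe_index)
    if not groups:
        raise ValidationError(
            f"chip {chip.name!r} has no antigenomic (BG) probes; "
            "GC background correction is unavailable"
        )
    return BackgroundIndex(
        gc_to_probes={g: np.array(v, dtype=np.int64) for g, v in groups.items()},
        available_gc=sorted(groups),
    )


def probes_for_level(chip: ChipDefinition, level_set: set[str]) -> np.ndarray:
    """Deduplicated, ascending PM probe indices used by ``level_set``."""
    sets = chip.probesets_at(set(level_set))
    if not sets:
        return np.array([], dtype=np.int64)
    idx = np.unique(np.concatenate([np.array(ps.probe_indices) for ps in sets]))
    return idx.astype(np.int64)


# ---------------------------------------------------------------------------
# TSV bundle I/O

_PROBE_COLS = ["probe_index", "gc_count", "role", "mm_partner"]
_PSET_COLS = ["probeset_id", "level", "symbol", "annotation"]
_MAP_COLS = ["probeset_id", "probe_index"]


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df


def load_chip_definition(path: str) -> ChipDefinition:
    """Load and validate a chip-definition bundle from directory ``path``.

    The bundle holds three UTF-8 TSV files with header rows ('#' comment
    lines ignored): ``probes.tsv`` (probe_index, gc_count, role, mm_partner),
    ``probesets.tsv`` (probeset_id, level, symbol, annotation) and
    ``mapping.tsv`` (probeset_id, probe_index).
    """
    probes_df = _read_tsv(os.path.join(path, "probes.tsv"), _PROBE_COLS[:3])
    psets_df = _read_tsv(os.path.join(path, "probesets.tsv"), _PSET_COLS[:2])
    map_df = _read_tsv(os.path.join(path, "mapping.tsv"), _MAP_COLS)

    probes = []
    mm_pairing: dict[int, int] = {}
    for row in probes_df.itertuples(index=False):
        try:
            idx = int(row.probe_index)
        except ValueError as e:
            raise ValidationError(f"probes.tsv: bad probe_index {row.probe_index!r}") from e
        gc = None if row.gc_count == "" else int(row.gc_count)
        probes.append(ProbeRecord(probe_index=idx, gc_count=gc, role=row.role))
        partner = getattr(row, "mm_partner", "")
        if partner != "":
            mm_pairing[idx] = int(partner)

    members: dict[str, list[int]] = {}
    for row in map_df.itertuples(index=False):
        members.setdefault(row.probeset_id, []).append(int(row.probe_index))

    probesets = {}
    for row in psets_df.itertuples(index=False):
        pid = row.probeset_id
        ann: dict = {}
        sym = getattr(row, "symbol", "")
        if sym:
            ann["symbol"] = sym
        extra = getattr(row, "annotation", "")
        if extra:
            ann["annotation"] = extra
        if pid not in members:
            raise ValidationError(
                f"probesets.tsv: probeset {pid} has no rows in mapping.tsv"
            )
        probesets[pid] = ProbesetDefinition(
            probeset_id=pid,
            level=row.level,
            probe_indices=tuple(members[pid]),
            annotation=ann,
        )
    orphans = set(members) - set(probesets)
    if orphans:
        raise ValidationError(
            f"mapping.tsv references undeclared probeset(s): {sorted(orphans)[:5]}"
        )
    name = os.path.basename(os.path.normpath(path))
    return ChipDefinition(name, probes, probesets, mm_pairing or None)


def write_chip_definition(chip: ChipDefinition, path: str) -> None:
    """Write ``chip`` as a three-table TSV bundle into directory ``path``."""
    os.makedirs(path, exist_ok=True)
    mm = chip.mm_pairing or {}
    pd.DataFrame(
        {
            "probe_index": [p.probe_index for p in chip.probes],
            "gc_count": ["" if p.gc_count is None else p.gc_count for p in chip.probes],
            "role": [p.role for p in chip.probes],
            "mm_partner": ["" if p.probe_index not in mm else mm[p.probe_index]
                           for p in chip.probes],
        }
    ).to_csv(os.path.join(path, "probes.tsv"), sep="\t", index=False)
    psets = sorted(chip.probesets.values(), key=lambda ps: ps.probeset_id)
    pd.DataFrame(
        {
            "probeset_id": [ps.probeset_id for ps in psets],
            "level": [ps.level for ps in psets],
            "symbol": [ps.symbol for ps in psets],
            "annotation": [ps.annotation.get("annotation", "") for ps in psets],
        }
    ).to_csv(os.path.join(path, "probesets.tsv"), sep="\t", index=False)
    rows_id, rows_ix = [], []
    for ps in psets:
        for i in ps.probe_indices:
            rows_id.append(ps.probeset_id)
            rows_ix.append(i)
    pd.DataFrame({"probeset_id": rows_id, "probe_index": rows_ix}).to_csv(
        os.path.join(path, "mapping.tsv"), sep="\t", index=False
    )
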