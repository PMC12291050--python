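"""Reading and writing evidence-style identification tables.

Input tables follow the MaxQuant ``evidence.txt`` dialect: one row per MS1
feature, tab separated, with at least a modified-sequence, charge, CCS,
intensity and raw-file column.  Column names can be overridden through a
``column_map``.  The curated dataset produced downstream is written as a
plain TSV with a deterministic column order so that write→read round trips
are lossless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default MaxQuant evidence column names.
DEFAULT_COLUMNS: dict[str, str] = {
    "peptidoform": "Modified sequence",
    "charge": "Charge",
    "ccs": "CCS",
    "intensity": "Intensity",
    "run_id": "Raw file",
    "type": "Type",
}

#: How the MaxQuant ``Type`` column maps onto (has_msms, has_ms1_feature).
#: ``MULTI-MSMS`` rows carry both an MS/MS identification and a distinct
#: MS1 feature; ``MSMS`` rows lack the feature; ``MULTI-MATCH`` rows are
#: match-between-runs transfers without an MS/MS spectrum.
DEFAULT_TYPE_FLAGS: dict[str, tuple[bool, bool]] = {
    "MULTI-MSMS": (True, True),
    "MULTI-SECPEP": (True, True),
    "MSMS": (True, False),
    "MULTI-MATCH": (False, True),
}

MAX_INGEST_CHARGE = 6


class EvidenceFormatError(ValueError):
    """Raised when a mandatory column is missing from an evidence table."""


def normalize_peptidoform(raw: str) -> str:
    """Normalize a modified-sequence string to the internal notation.

    MaxQuant wraps sequences in underscores (``_AAC(cm)K_``); plain
    ProForma strings pass through unchanged.
    """
    s = str(raw).strip()
    if s.startswith("_"):
        s = s.strip("_")
    if not s:
        raise ValueError("empty peptidoform")
    return s


@dataclass(frozen=True, order=True)
class PeptideIon:
    """A peptidoform (sequence with modifications) plus its charge state."""

    peptidoform: str
    charge: int

    def __post_init__(self) -> None:
        if not self.peptidoform:
            raise ValueError("peptidoform must be non-empty")
        if not 1 <= self.charge <= MAX_INGEST_CHARGE:
            raise ValueError(f"charge {self.charge} outside [1, {MAX_INGEST_CHARGE}]")

    @property
    def sequence(self) -> str:
        """Bare residue sequence with modification annotations stripped."""
        out = []
        depth = 0
        for ch in self.peptidoform:
            if ch in "([":
                depth += 1
            elif ch in ")]":
                depth -= 1
            elif depth == 0 and ch.isalpha():
                out.append(ch)
        return "".join(out)


@dataclass(frozen=True)
class Observation:
    """One MS1 feature: a peptide ion seen in one run with one CCS value."""

    ion: PeptideIon
    run_id: str
    ccs: float
    intensity: float = float("nan")
    has_msms: bool = True
    has_ms1_feature: bool = True

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValueError("run_id must be non-empty")
        if not math.isfinite(self.ccs) or self.ccs <= 0:
            raise ValueError(f"ccs must be finite and positive, got {self.ccs}")


@dataclass
class RunTable:
    """All observations from one LC–IM–MS/MS run."""

    run_id: str
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for obs in self.observations:
            if obs.run_id != self.run_id:
                raise ValueError(
                    f"observation run_id {obs.run_id!r} != table run_id {self.run_id!r}"
                )

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class CuratedRecord:
    """Final curated row: one ion with its sorted conformer CCS values."""

    ion: PeptideIon
    ccs_values: tuple[float, ...]
    supports: tuple[int, ...]
    label: str  # "uni" | "multi"

    def __post_init__(self) -> None:
        if self.label not in ("uni", "multi"):
            raise ValueError(f"label must be 'uni' or 'multi', got {self.label!r}")
        if len(self.ccs_values) != len(self.supports):
            raise ValueError("ccs_values and supports must have equal length")
        if list(self.ccs_values) != sorted(self.ccs_values):
            raise ValueError("ccs_values must be ascending")
        if self.label == "uni" and len(self.ccs_values) != 1:
            raise ValueError("uni records carry exactly one CCS value")
        if self.label == "multi" and len(self.ccs_values) < 2:
            raise ValueError("multi records carry at least two CCS values")


def read_evidence(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    type_flags: Mapping[str, tuple[bool, bool]] | None = None,
    drop_prefixes: Sequence[str] = (),
) -> list[RunTable]:
    """Read an evidence TSV and group it into one :class:`RunTable` per run.

    Parameters
    ----------
    path:
        Tab-separated evidence file.
    column_map:
        Overrides for :data:`DEFAULT_COLUMNS` (keys: peptidoform, charge,
        ccs, intensity, run_id, type).
    type_flags:
        Mapping from the ``Type`` column value to
        ``(has_msms, has_ms1_feature)``; unknown values map to
        ``(False, False)``.  When the table has no type column both flags
        default to True.
    drop_prefixes:
        Optional peptidoform prefixes (e.g. decoy/contaminant markers)
        whose rows are dropped before grouping.

    Returns
    -------
    list of RunTable, sorted by run_id.  Rows with missing or non-positive
    CCS are dropped with a logged count.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    flags = dict(DEFAULT_TYPE_FLAGS if type_flags is None else type_flags)

    df = pd.read_csv(
        path, sep="\t", dtype={cols["run_id"]: str},
        float_precision="round_trip",
    )
    if df.empty and len(df.columns) <= 1:
        logger.warning("evidence file %s is empty", path)
        return []

    for key in ("peptidoform", "charge", "ccs", "run_id"):
        if cols[key] not in df.columns:
            raise EvidenceFormatError(
                f"evidence table missing mandatory column {cols[key]!r}"
            )

    n0 = len(df)
    ccs = pd.to_numeric(df[cols["ccs"]], errors="coerce")
    keep = ccs.notna() & (ccs > 0) & (ccs != float("inf"))
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("dropped %d/%d rows with missing or invalid CCS", dropped, n0)
    df = df.loc[keep].copy()
    df[cols["ccs"]] = ccs[keep]

    has_type = cols["type"] in df.columns
    has_intensity = cols["intensity"] in df.columns

    tables: dict[str, list[Observation]] = {}
    # Positional access avoids pandas' identifier mangling of column names.
    idx = {name: i for i, name in enumerate(df.columns)}
    for row in df.itertuples(index=False, name=None):
        pform = normalize_peptidoform(row[idx[cols["peptidoform"]]])
        if any(pform.startswith(p) for p in drop_prefixes):
            continue
        charge = int(row[idx[cols["charge"]]])
        if not 1 <= charge <= MAX_INGEST_CHARGE:
            continue
        if has_type:
            tval = str(row[idx[cols["type"]]])
            has_msms, has_feature = flags.get(tval, (False, False))
        else:
            has_msms, has_feature = True, True
        intensity = float("nan")
        if has_intensity:
            try:
                intensity = float(row[idx[cols["intensity"]]])
            except (TypeError, ValueError):
                intensity = float("nan")
        run_id = str(row[idx[cols["run_id"]]])
        obs = Observation(
            ion=PeptideIon(pform, charge),
            run_id=run_id,
            ccs=float(row[idx[cols["ccs"]]]),
            intensity=intensity,
            has_msms=has_msms,
            has_ms1_feature=has_feature,
        )
        tables.setdefault(run_id, []).append(obs)

    return [RunTable(rid, obs) for rid, obs in sorted(tables.items())]


def filter_identified(runs: Iterable[RunTable]) -> list[RunTable]:
    """Keep only observations with both an MS/MS spectrum and an MS1 feature.

    Empty run tables are removed.  Idempotent; never increases counts.
    """
    out = []
    for table in runs:
        kept = [o for o in table.observations if o.has_msms and o.has_ms1_feature]
        if kept:
            out.append(RunTable(table.run_id, kept))
    return out


CURATED_FIXED_COLUMNS = ["peptidoform", "charge", "n_conformers", "label"]


def write_curated(records: Iterable[CuratedRecord], path: str | Path) -> None:
    """Write curated records as a TSV with deterministic order.

    Columns: peptidoform, charge, n_conformers, label, ccs_1..ccs_k,
    support_1..support_k (k = max conformer count in the collection).
    Rows sorted by (peptidoform, charge).
    """
    records = sorted(records, key=lambda r: (r.ion.peptidoform, r.ion.charge))
    k = max((len(r.ccs_values) for r in records), default=1)
    columns = (
        CURATED_FIXED_COLUMNS
        + [f"ccs_{i + 1}" for i in range(k)]
        + [f"support_{i + 1}" for i in range(k)]
    )
    rows = []
    for r in records:
        row: dict[str, object] = {
            "peptidoform": r.ion.peptidoform,
            "charge": r.ion.charge,
            "n_conformers": len(r.ccs_values),
            "label": r.label,
        }
        for i in range(k):
            row[f"ccs_{i + 1}"] = (
                repr(r.ccs_values[i]) if i < len(r.ccs_values) else ""
            )
            row[f"support_{i + 1}"] = (
                r.supports[i] if i < len(r.supports) else ""
            )
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_curated(path: str | Path) -> list[CuratedRecord]:
    """Read a curated TSV written by :func:`write_curated`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in CURATED_FIXED_COLUMNS:
        if col not in df.columns:
            raise EvidenceFormatError(f"curated table missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        n = int(row.n_conformers)
        ccs = tuple(float(getattr(row, f"ccs_{i + 1}")) for i in range(n))
        sup = tuple(int(getattr(row, f"support_{i + 1}")) for i in range(n))
        records.append(
            CuratedRecord(
                ion=PeptideIon(str(row.peptidoform), int(row.charge)),
                ccs_values=ccs,
                supports=sup,
                label=str(row.label),
            )
        )
    return records
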