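"""Cross-run CCS alignment by charge-specific additive offsets.

Runs are merged by greedy accretion: starting from the run with the most
identifications, each remaining run (in descending identification count)
is aligned onto the growing reference set with one additive offset per
charge (``y = x + b``) and merged.  Runs sharing fewer than ``min_overlap``
peptide-charge pairs with the current reference are skipped.

The per-ion alignment reference is the CCS of the highest-intensity
identification seen so far; less abundant identifications are aligned and
retained as well.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .evidence_io import Observation, PeptideIon, RunTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentOffset:
    """Additive offset ``b`` for one (run, charge), with its support count."""

    run_id: str
    charge: int
    b: float
    n_overlap: int

    @property
    def usable(self) -> bool:
        return self.n_overlap > 0 and math.isfinite(self.b)


@dataclass
class ReferenceEntry:
    """Per-ion reference CCS plus every aligned member observation."""

    ion: PeptideIon
    ref_ccs: float
    ref_intensity: float
    members: list[Observation] = field(default_factory=list)


@dataclass
class AlignedDataset:
    """Result of merging runs into one aligned collection."""

    entries: dict[PeptideIon, ReferenceEntry] = field(default_factory=dict)
    offsets: list[AlignmentOffset] = field(default_factory=list)
    skipped_runs: dict[str, str] = field(default_factory=dict)

    def ions(self) -> list[PeptideIon]:
        return sorted(self.entries, key=lambda i: (i.peptidoform, i.charge))

    def observations(self) -> list[Observation]:
        return [o for e in self.entries.values() for o in e.members]


def _intensity_key(obs: Observation) -> float:
    # NaN intensities sort below any number.
    return obs.intensity if math.isfinite(obs.intensity) else -math.inf


def order_runs(runs: Sequence[RunTable]) -> list[str]:
    """Run ids by identification count, descending; ties broken by run_id."""
    if not runs:
        raise ValueError("order_runs requires at least one run")
    return [t.run_id for t in sorted(runs, key=lambda t: (-len(t), t.run_id))]


def _top_obs_per_ion(table: RunTable) -> dict[PeptideIon, Observation]:
    """Highest-intensity observation per ion within one run."""
    best: dict[PeptideIon, Observation] = {}
    for obs in table.observations:
        cur = best.get(obs.ion)
        if cur is None or _intensity_key(obs) > _intensity_key(cur):
            best[obs.ion] = obs
    return best


def estimate_offset(
    incoming: RunTable,
    reference: AlignedDataset,
    charge: int,
    estimator: str = "median",
) -> AlignmentOffset:
    """Estimate ``b`` for one charge from overlapping ions.

    Pairs the incoming run's highest-intensity observation per ion with
    the reference CCS; ``b`` is the median (default) or mean of
    ``reference − incoming`` differences.
    """
    top = _top_obs_per_ion(incoming)
    diffs = []
    for ion, obs in top.items():
        if ion.charge != charge:
            continue
        entry = reference.entries.get(ion)
        if entry is not None:
            diffs.append(entry.ref_ccs - obs.ccs)
    if not diffs:
        return AlignmentOffset(incoming.run_id, charge, float("nan"), 0)
    arr = np.asarray(diffs, dtype=float)
    b = float(np.median(arr)) if estimator == "median" else float(arr.mean())
    return AlignmentOffset(incoming.run_id, charge, b, len(diffs))


def _merge_run(
    aligned: AlignedDataset, table: RunTable, offsets: dict[int, float]
) -> None:
    shifted = [
        Observation(
            ion=o.ion,
            run_id=o.run_id,
            ccs=o.ccs + offsets.get(o.ion.charge, 0.0),
            intensity=o.intensity,
            has_msms=o.has_msms,
            has_ms1_feature=o.has_ms1_feature,
        )
        for o in table.observations
    ]
    best = _top_obs_per_ion(RunTable(table.run_id, shifted))
    for obs in shifted:
        entry = aligned.entries.get(obs.ion)
        if entry is None:
            top = best[obs.ion]
            entry = ReferenceEntry(obs.ion, top.ccs, _intensity_key(top))
            aligned.entries[obs.ion] = entry
        entry.members.append(obs)
    for ion, top in best.items():
        entry = aligned.entries[ion]
        if _intensity_key(top) > entry.ref_intensity:
            entry.ref_ccs = top.ccs
            entry.ref_intensity = _intensity_key(top)


def align_all(
    runs: Sequence[RunTable],
    min_overlap: int = 100,
    offset_estimator: str = "median",
    min_pairs_per_charge: int = 10,
) -> AlignedDataset:
    """Merge runs into one aligned dataset.

    The seed run (most identifications) is never skipped and receives no
    offset.  Each later run is gated on the total number of distinct
    (peptidoform, charge) pairs it shares with the current aligned set;
    below ``min_overlap`` the run is recorded in ``skipped_runs``.  Charges
    with fewer than ``min_pairs_per_charge`` overlapping pairs fall back
    to ``b = 0`` (logged).
    """
    order = order_runs(runs)
    by_id = {t.run_id: t for t in runs}
    aligned = AlignedDataset()

    for i, run_id in enumerate(order):
        table = by_id[run_id]
        if i == 0:
            _merge_run(aligned, table, {})
            continue
        run_ions = {o.ion for o in table.observations}
        overlap_ions = run_ions & aligned.entries.keys()
        if len(overlap_ions) < min_overlap:
            aligned.skipped_runs[run_id] = (
                f"overlap {len(overlap_ions)} < min_overlap {min_overlap}"
            )
            continue
        charges = sorted({ion.charge for ion in run_ions})
        applied: dict[int, float] = {}
        for z in charges:
            off = estimate_offset(table, aligned, z, estimator=offset_estimator)
            if off.n_overlap >= min_pairs_per_charge:
                applied[z] = off.b
                aligned.offsets.append(off)
            else:
                logger.info(
                    "run %s charge %d: only %d pairs (< %d), offset set to 0",
                    run_id, z, off.n_overlap, min_pairs_per_charge,
                )
                applied[z] = 0.0
                aligned.offsets.append(
                    AlignmentOffset(run_id, z, 0.0, off.n_overlap)
                )
        _merge_run(aligned, table, applied)
    return aligned


def write_offsets(aligned: AlignedDataset, path: str | Path) -> None:
    """Write the alignment audit trail as a TSV."""
    with open(path, "w") as fh:
        fh.write("run_id\tcharge\tb\tn_overlap\n")
        for off in aligned.offsets:
            fh.write(f"{off.run_id}\t{off.charge}\t{off.b!r}\t{off.n_overlap}\n")
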