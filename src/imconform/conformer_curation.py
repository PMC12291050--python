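"""Conformer detection, cross-run matching and uni/multi classification.

Within each run, repeated identifications of the same ion whose CCS values
differ by more than a relative tolerance (default 2%) are treated as
distinct conformers.  Candidate conformers are then matched across runs at
the same tolerance; conformers must recur in at least ``min_run_support``
runs to count.  Ions with two or more recurrent conformers form the
multiconformer set; ions whose observations all agree within tolerance
form the uniconformer set; everything else (e.g. a second conformer seen
in only one run) is discarded from both.

Clustering uses optimal contiguous segmentation of the CCS-sorted values:
every within-cluster pair must satisfy the tolerance, and among feasible
partitions the one with the fewest clusters (then the smallest total
within-cluster spread, then the longest leading clusters) is chosen.  On
sorted data an optimal partition is always contiguous, so this matches an
exhaustive search over all feasible partitions.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .evidence_io import CuratedRecord, Observation, PeptideIon
from .run_alignment import AlignedDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurationConfig:
    """Tolerances and filters for conformer curation."""

    tau: float = 0.02
    min_run_support: int = 2
    max_charge: int = 4
    denominator: str = "min"  # "min" | "mean"
    within_run_representative: str = "intensity_weighted"  # | "unweighted"

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.min_run_support < 2:
            raise ValueError("min_run_support must be >= 2")
        if self.denominator not in ("min", "mean"):
            raise ValueError("denominator must be 'min' or 'mean'")


@dataclass
class Cluster:
    """One conformer cluster: member (run_id, ccs) pairs and summaries."""

    members: list[tuple[str, float]]
    mean_ccs: float
    run_support: int


@dataclass
class ConformerGroup:
    """Cross-run conformer clusters for one ion, sorted by mean CCS."""

    ion: PeptideIon
    clusters: list[Cluster] = field(default_factory=list)


def relative_difference(a: float, b: float, denominator: str = "min") -> float:
    """Relative CCS difference |a − b| / min(a, b) (or /mean, by config)."""
    if a <= 0 or b <= 0:
        raise ValueError("CCS values must be positive")
    if denominator == "mean":
        return abs(a - b) / ((a + b) / 2.0)
    return abs(a - b) / min(a, b)


def _segment_ok(values: Sequence[float], lo: int, hi: int, cfg: CurationConfig) -> bool:
    """All pairs in values[lo..hi] (sorted ascending) within tau?"""
    return relative_difference(values[lo], values[hi], cfg.denominator) <= cfg.tau


def _segment(values: Sequence[float], cfg: CurationConfig) -> list[tuple[int, int]]:
    """Optimal contiguous segmentation of ascending `values`.

    Minimizes (cluster count, total spread); among ties prefers longer
    leading segments.  Returns [lo, hi] index pairs, inclusive.
    """
    n = len(values)
    INF = (math.inf, math.inf)
    # best[i] = (count, spread) for values[i:], choice[i] = segment end j
    best: list[tuple[float, float]] = [INF] * (n + 1)
    best[n] = (0.0, 0.0)
    choice = [0] * n
    for i in range(n - 1, -1, -1):
        for j in range(i, n):
            if not _segment_ok(values, i, j, cfg):
                break
            tail = best[j + 1]
            cand = (1.0 + tail[0], (values[j] - values[i]) + tail[1])
            if cand < best[i] or (cand == best[i] and j > choice[i]):
                best[i] = cand
                choice[i] = j
    segments = []
    i = 0
    while i < n:
        j = choice[i]
        segments.append((i, j))
        i = j + 1
    return segments


def split_within_run(
    observations: Sequence[Observation], cfg: CurationConfig
) -> list[tuple[float, float]]:
    """Split one ion's observations within one run into conformer candidates.

    Returns (representative_ccs, total_intensity) per candidate, ascending
    by CCS.  The representative is the intensity-weighted mean CCS of the
    cluster (unweighted when intensities are missing or by config).
    """
    if not observations:
        raise ValueError("split_within_run requires >= 1 observation")
    obs = sorted(observations, key=lambda o: o.ccs)
    values = [o.ccs for o in obs]
    out = []
    for lo, hi in _segment(values, cfg):
        group = obs[lo : hi + 1]
        ccs = np.array([o.ccs for o in group])
        inten = np.array([o.intensity for o in group], dtype=float)
        usable = (
            cfg.within_run_representative == "intensity_weighted"
            and np.isfinite(inten).all()
            and inten.sum() > 0
        )
        if usable:
            rep = float(np.average(ccs, weights=inten))
            total = float(inten.sum())
        else:
            rep = float(ccs.mean())
            total = float(np.nansum(inten))
        out.append((rep, total))
    return out


def match_across_runs(
    candidates: dict[str, Sequence[float]], cfg: CurationConfig, ion: PeptideIon
) -> ConformerGroup:
    """Match per-run conformer candidates across runs for one ion.

    ``candidates`` maps run_id → candidate CCS values from that run.  All
    candidates are pooled, sorted, and segmented with the same optimal
    within-tau rule as within runs.  If one run lands two candidates in
    the same cluster, the one nearer the cluster mean stays and the other
    is spun off into its own cluster (logged).
    """
    pooled: list[tuple[float, str]] = []
    for run_id in sorted(candidates):
        for ccs in candidates[run_id]:
            pooled.append((float(ccs), run_id))
    pooled.sort()
    values = [p[0] for p in pooled]

    raw: list[list[tuple[str, float]]] = []
    for lo, hi in _segment(values, cfg):
        raw.append([(pooled[k][1], pooled[k][0]) for k in range(lo, hi + 1)])

    clusters: list[list[tuple[str, float]]] = []
    for members in raw:
        per_run: dict[str, list[tuple[str, float]]] = defaultdict(list)
        for m in members:
            per_run[m[0]].append(m)
        if all(len(v) == 1 for v in per_run.values()):
            clusters.append(members)
            continue
        mean = sum(m[1] for m in members) / len(members)
        kept, spilled = [], []
        for run_id, ms in per_run.items():
            ms.sort(key=lambda m: abs(m[1] - mean))
            kept.append(ms[0])
            spilled.extend(ms[1:])
        if spilled:
            logger.info(
                "ion %s/%d: %d same-run duplicate candidate(s) spun off",
                ion.peptidoform, ion.charge, len(spilled),
            )
        clusters.append(kept)
        clusters.extend([[m] for m in spilled])

    built = [
        Cluster(
            members=sorted(ms),
            mean_ccs=float(np.mean([m[1] for m in ms])),
            run_support=len({m[0] for m in ms}),
        )
        for ms in clusters
    ]
    built.sort(key=lambda c: c.mean_ccs)
    return ConformerGroup(ion=ion, clusters=built)


def classify_ion(
    group: ConformerGroup, cfg: CurationConfig
) -> CuratedRecord | None:
    """Classify one ion as multi, uni, or discard (None).

    * charge above ``max_charge`` → discard;
    * multi: ≥2 clusters, every cluster recurring in ≥ ``min_run_support``
      runs;
    * uni: exactly one cluster (all observations agreed within tau);
    * anything else (extra clusters without recurrence) → discard.
    """
    if group.ion.charge > cfg.max_charge:
        return None
    clusters = group.clusters
    if len(clusters) >= 2 and all(
        c.run_support >= cfg.min_run_support for c in clusters
    ):
        return CuratedRecord(
            ion=group.ion,
            ccs_values=tuple(c.mean_ccs for c in clusters),
            supports=tuple(c.run_support for c in clusters),
            label="multi",
        )
    if len(clusters) == 1:
        return CuratedRecord(
            ion=group.ion,
            ccs_values=(clusters[0].mean_ccs,),
            supports=(clusters[0].run_support,),
            label="uni",
        )
    return None


def curate(
    aligned: AlignedDataset, cfg: CurationConfig | None = None
) -> dict[str, list]:
    """Run the full curation pipeline on an aligned dataset.

    Returns ``{"multi": [CuratedRecord], "uni": [CuratedRecord],
    "discarded": [PeptideIon]}`` with deterministic ordering.
    """
    cfg = cfg or CurationConfig()
    multi: list[CuratedRecord] = []
    uni: list[CuratedRecord] = []
    discarded: list[PeptideIon] = []
    for ion in aligned.ions():
        entry = aligned.entries[ion]
        by_run: dict[str, list[Observation]] = defaultdict(list)
        for obs in entry.members:
            by_run[obs.run_id].append(obs)
        candidates = {
            run_id: [rep for rep, _ in split_within_run(obs_list, cfg)]
            for run_id, obs_list in by_run.items()
        }
        group = match_across_runs(candidates, cfg, ion)
        record = classify_ion(group, cfg)
        if record is None:
            discarded.append(ion)
        elif record.label == "multi":
            multi.append(record)
        else:
            uni.append(record)
    return {"multi": multi, "uni": uni, "discarded": discarded}


def proline_frequency(sequence: str) -> float:
    """Prolines divided by sequence length."""
    if not sequence:
        return 0.0
    return sequence.count("P") / len(sequence)


def _subset_summary(records: Sequence[CuratedRecord]) -> dict:
    seqs = [r.ion.sequence for r in records]
    lengths = np.array([len(s) for s in seqs])
    charges = np.array([r.ion.charge for r in records])
    pfreq = np.array([proline_frequency(s) for s in seqs])
    residue_counts: dict[str, int] = defaultdict(int)
    total_residues = 0
    for s in seqs:
        for ch in s:
            residue_counts[ch] += 1
        total_residues += len(s)
    return {
        "n": len(records),
        "mean_length": float(lengths.mean()),
        "length_hist": {int(k): int(v) for k, v in
                        zip(*np.unique(lengths, return_counts=True))},
        "charge_hist": {int(k): int(v) for k, v in
                        zip(*np.unique(charges, return_counts=True))},
        "mean_charge": float(charges.mean()),
        "proline_presence": float(np.mean([("P" in s) for s in seqs])),
        "mean_proline_frequency": float(pfreq.mean()),
        "residue_relative_abundance": {
            aa: residue_counts[aa] / total_residues
            for aa in sorted(residue_counts)
        },
    }


def characterize(
    multi: Sequence[CuratedRecord], uni: Sequence[CuratedRecord]
) -> dict:
    """Physicochemical summary of the two subsets.

    Per subset: length/charge distributions, proline presence and
    frequency, per-residue relative abundance; for the multi subset also
    the per-charge absolute CCS differences between adjacent conformers.
    """
    if not multi or not uni:
        raise ValueError("characterize requires non-empty multi and uni sets")
    delta_by_charge: dict[int, list[float]] = defaultdict(list)
    for r in multi:
        for a, b in zip(r.ccs_values, r.ccs_values[1:]):
            delta_by_charge[r.ion.charge].append(b - a)
    return {
        "multi": _subset_summary(multi),
        "uni": _subset_summary(uni),
        "delta_ccs_by_charge": {
            z: {
                "n": len(v),
                "mean_abs_delta": float(np.mean(v)),
                "median_abs_delta": float(np.median(v)),
            }
            for z, v in sorted(delta_by_charge.items())
        },
    }
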