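"""Extracted ion mobilogram (XIM) analysis.

Covers the Mason–Schamp conversion between inverse reduced mobility and
CCS, peak picking on sampled mobility profiles, multimodality statistics,
replicate intensity-order reversal rates, and annotation of observed peaks
with the nearest model prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .evidence_io import PeptideIon

# Physical constants (SI).
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
LOSCHMIDT = 101325.0 / (BOLTZMANN * 273.15)  # m^-3, gas number density at STP
DALTON = 1.66053906660e-27  # kg
N2_MASS = 28.0134  # Da


@dataclass(frozen=True)
class MobilityContext:
    """Physical context for the Mason–Schamp conversion."""

    mz: float
    charge: int
    gas_mass: float = N2_MASS
    temperature: float = 305.0

    def __post_init__(self) -> None:
        if min(self.mz, self.charge, self.gas_mass, self.temperature) <= 0:
            raise ValueError("all MobilityContext fields must be positive")

    @property
    def reduced_mass_kg(self) -> float:
        m_ion = self.mz * self.charge
        return (m_ion * self.gas_mass) / (m_ion + self.gas_mass) * DALTON


def _ms_factor(ctx: MobilityContext) -> float:
    """Å² per (V·s/cm²) of inverse reduced mobility, low-field limit."""
    mu = ctx.reduced_mass_kg
    factor = (
        (3.0 * ctx.charge * ELEMENTARY_CHARGE)
        / (16.0 * LOSCHMIDT)
        * math.sqrt(2.0 * math.pi / (mu * BOLTZMANN * ctx.temperature))
    )
    # inv_k0 [V s/cm^2] -> [V s/m^2] is *1e4; m^2 -> Å^2 is *1e20.
    return factor * 1e4 * 1e20


def ccs_from_mobility(inv_k0: float, ctx: MobilityContext) -> float:
    """CCS (Å²) from inverse reduced mobility (V·s/cm²), Mason–Schamp."""
    if inv_k0 <= 0:
        raise ValueError("inv_k0 must be positive")
    return _ms_factor(ctx) * inv_k0


def mobility_from_ccs(ccs: float, ctx: MobilityContext) -> float:
    """Inverse reduced mobility (V·s/cm²) from CCS (Å²); exact inverse."""
    if ccs <= 0:
        raise ValueError("ccs must be positive")
    return ccs / _ms_factor(ctx)


@dataclass
class Mobilogram:
    """Sampled ion-mobility intensity profile for one precursor."""

    ion: PeptideIon
    axis: np.ndarray  # strictly monotone grid (1/K0 or CCS)
    intensity: np.ndarray  # same length, >= 0
    axis_kind: str = "ccs"  # "ccs" | "inv_k0"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")


@dataclass(frozen=True)
class Peak:
    position: float
    intensity: float
    relative_height: float


@dataclass
class PeakSet:
    """Picked peaks, sorted by position; one peak has relative height 1."""

    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> list[float]:
        return [p.position for p in self.peaks]


@dataclass(frozen=True)
class PeakParams:
    """Peak-picking knobs (stand-in algorithm; all configurable)."""

    smooth_window: int = 5  # moving-average width, grid points
    min_prominence_frac: float = 0.05  # of the profile maximum
    min_separation: int = 3  # grid points between maxima


def pick_peaks(
    m: Mobilogram,
    rel_threshold: float = 0.10,
    params: PeakParams = PeakParams(),
) -> PeakSet:
    """Pick IM peaks: smooth, find prominent local maxima, threshold.

    Maxima below ``rel_threshold`` of the highest peak are discarded.
    Returns an empty set for an all-zero profile.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    y = m.intensity
    if y.max() <= 0:
        return PeakSet([])
    w = max(1, int(params.smooth_window))
    kernel = np.ones(w) / w
    smooth = np.convolve(y, kernel, mode="same")
    top = smooth.max()
    idx, _ = find_peaks(
        smooth,
        prominence=params.min_prominence_frac * top,
        distance=max(1, int(params.min_separation)),
    )
    # Edges cannot be scipy "peaks"; include the global max if it sits there.
    gmax = int(np.argmax(smooth))
    if gmax not in idx and (gmax == 0 or gmax == len(smooth) - 1):
        idx = np.sort(np.append(idx, gmax))
    if len(idx) == 0:
        idx = np.array([gmax])
    heights = smooth[idx]
    keep = heights >= rel_threshold * heights.max()
    idx = idx[keep]
    heights = heights[keep]
    ref = heights.max()
    peaks = [
        Peak(
            position=float(m.axis[i]),
            intensity=float(h),
            relative_height=float(h / ref),
        )
        for i, h in zip(idx, heights)
    ]
    peaks.sort(key=lambda p: p.position)
    return PeakSet(peaks)


def multimodal_fraction(
    mobilograms: Sequence[Mobilogram],
    rel_threshold: float,
    params: PeakParams = PeakParams(),
) -> float:
    """Fraction of XIMs with >= 2 peaks surviving the relative threshold."""
    if not mobilograms:
        raise ValueError("need at least one mobilogram")
    n_multi = sum(
        len(pick_peaks(m, rel_threshold, params)) >= 2 for m in mobilograms
    )
    return n_multi / len(mobilograms)


def _top_two(ps: PeakSet) -> list[Peak]:
    return sorted(ps.peaks, key=lambda p: -p.intensity)[:2]


def order_reversal_rate(
    rep_a: Sequence[Mobilogram],
    rep_b: Sequence[Mobilogram],
    rel_threshold: float = 0.25,
    secondary_cap: float | None = None,
    tau: float = 0.02,
    params: PeakParams = PeakParams(),
) -> float | None:
    """Fraction of bimodal ions whose peak intensity order flips between
    replicates.

    Mobilograms are matched by ion across the two replicate lists; an ion
    counts only when both replicates are bimodal at ``rel_threshold``.  The
    two most intense peaks are matched across replicates by nearest
    position within ``tau`` (relative).  ``secondary_cap`` excludes ions
    whose secondary peak reaches that relative height in either replicate.
    Returns None when no common bimodal ion exists.
    """
    by_ion_b = {m.ion: m for m in rep_b}
    n_eligible = 0
    n_reversed = 0
    for ma in rep_a:
        mb = by_ion_b.get(ma.ion)
        if mb is None:
            continue
        pa = _top_two(pick_peaks(ma, rel_threshold, params))
        pb = _top_two(pick_peaks(mb, rel_threshold, params))
        if len(pa) < 2 or len(pb) < 2:
            continue
        if secondary_cap is not None:
            if (
                min(p.relative_height for p in pa) >= secondary_cap
                or min(p.relative_height for p in pb) >= secondary_cap
            ):
                continue
        # Match by position: pair each A peak with the nearest B peak.
        pa_sorted = sorted(pa, key=lambda p: p.position)
        pb_sorted = sorted(pb, key=lambda p: p.position)
        matched = all(
            abs(x.position - y.position) / min(x.position, y.position) <= tau
            for x, y in zip(pa_sorted, pb_sorted)
        )
        if not matched:
            continue
        n_eligible += 1
        order_a = pa_sorted[0].intensity > pa_sorted[1].intensity
        order_b = pb_sorted[0].intensity > pb_sorted[1].intensity
        if order_a != order_b:
            n_reversed += 1
    if n_eligible == 0:
        return None
    return n_reversed / n_eligible


def write_mobilograms(mobilograms: Sequence[Mobilogram], path) -> None:
    """Write mobilograms as a long-format TSV (one row per grid point)."""
    with open(path, "w") as fh:
        fh.write("peptidoform\tcharge\taxis_kind\tposition\tintensity\n")
        for m in mobilograms:
            for x, y in zip(m.axis, m.intensity):
                fh.write(
                    f"{m.ion.peptidoform}\t{m.ion.charge}\t{m.axis_kind}\t"
                    f"{float(x)!r}\t{float(y)!r}\n"
                )


def read_mobilograms(path) -> list[Mobilogram]:
    """Read mobilograms from the long-format TSV written above."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for (pform, charge, kind), grp in df.groupby(
        ["peptidoform", "charge", "axis_kind"], sort=True
    ):
        grp = grp.sort_values("position")
        out.append(
            Mobilogram(
                ion=PeptideIon(str(pform), int(charge)),
                axis=grp["position"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                axis_kind=str(kind),
            )
        )
    return out


def nearest_prediction_annotation(
    peaks: PeakSet, pair
) -> list[dict]:
    """Annotate each observed apex with the closer of two predicted CCS.

    ``pair`` needs ``ccs_small``/``ccs_large`` attributes.  Ties go to the
    smaller prediction.  Peaks must be on the CCS axis.
    """
    out = []
    for p in peaks.peaks:
        d_small = abs(p.position - pair.ccs_small)
        d_large = abs(p.position - pair.ccs_large)
        if d_small <= d_large:
            chosen, err = pair.ccs_small, d_small
        else:
            chosen, err = pair.ccs_large, d_large
        out.append(
            {"position": p.position, "prediction": chosen, "error": err}
        )
    return out
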