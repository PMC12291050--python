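"""Seeded synthetic cohorts and mobilograms with full ground truth.

Everything a pipeline stage consumes can be generated here with planted
truth: multi-run evidence tables with per-(run, charge) CCS offsets,
planted conformer structure, intensity noise and dropout, plus
Gaussian-mixture mobilograms with replicate pairs.

The planted CCS surface is NOT a claim about peptide physics.  It is a
smooth, strictly positive, composition- and charge-dependent closed form
chosen only so that parameter-recovery experiments are well posed:

    base(ion) = 160 + 0.32 * M + 2.0 * L
    ccs(ion)  = base * (0.75 + 0.25 * sqrt(z))

with M the summed monoisotopic residue mass (Da), L the sequence length
and z the charge.  Worked example: "GGGG" at z = 1 has M = 228.0859 Da,
so base = 160 + 72.9875 + 8.0 = 240.9875 and ccs = 240.9875 Å².

Conformer deltas are by default a deterministic, learnable function of
length, charge and proline content mapped into the configured range, with
higher charges mapped to larger deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ccs_model.encoding import ELEMENT_MASSES, RESIDUE_COMPOSITIONS, ELEMENTS
from .evidence_io import Observation, PeptideIon, RunTable
from .xim_analysis import Mobilogram

#: Residue monoisotopic masses derived from the composition table.
RESIDUE_MASSES = {
    aa: sum(n * ELEMENT_MASSES[el] for n, el in zip(comp, ELEMENTS))
    for aa, comp in RESIDUE_COMPOSITIONS.items()
}

#: Rough natural residue frequencies (renormalized at use).
DEFAULT_ALPHABET = {
    "A": 8.3, "R": 5.5, "N": 4.0, "D": 5.4, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 6.0, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.9,
}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the evidence-cohort generator.  ``seed`` is mandatory."""

    seed: int
    n_peptides: int = 1000
    length_range: tuple[int, int] = (7, 25)
    alphabet: dict = field(default_factory=lambda: dict(DEFAULT_ALPHABET))
    charge_probs: dict = field(
        default_factory=lambda: {1: 0.08, 2: 0.55, 3: 0.27, 4: 0.10}
    )
    multiconf_base_rate: float = 0.05
    multiconf_len_coef: float = 0.12  # log-odds per residue above mean length
    multiconf_charge_coef: float = 0.8  # log-odds per charge above 2
    multiconf_proline_coef: float = 0.5  # log-odds if proline present
    n_conformer_probs: dict = field(default_factory=lambda: {2: 1.0})
    delta_range: tuple[float, float] = (0.025, 0.10)
    delta_mode: str = "deterministic"  # | "random"
    n_runs: int = 10
    offset_sd: float = 3.0  # Å², per-(run, charge) additive offset
    noise_sigma: float = 0.003  # relative CCS noise
    dropout: float = 0.2  # per-observation missingness
    intensity_mu: float = 14.0  # log-normal parameters
    intensity_sigma: float = 1.0
    contaminant_row_rate: float = 0.0  # rows failing the MS/MS+feature filter

    def __post_init__(self) -> None:
        if not 0 <= self.multiconf_base_rate <= 1:
            raise ValueError("multiconf_base_rate must be in [0, 1]")
        if self.delta_mode not in ("deterministic", "random"):
            raise ValueError("delta_mode must be 'deterministic' or 'random'")
        if self.delta_range[0] <= 0:
            raise ValueError("delta lower bound must be positive")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a synthetic cohort."""

    conformers: dict[PeptideIon, tuple[float, ...]] = field(default_factory=dict)
    is_multi: dict[PeptideIon, bool] = field(default_factory=dict)
    offsets: dict[tuple[str, int], float] = field(default_factory=dict)
    deltas: dict[PeptideIon, float] = field(default_factory=dict)


def true_ccs(ion: PeptideIon) -> float:
    """Planted base CCS surface (see module docstring; not physics)."""
    seq = ion.sequence
    mass = sum(RESIDUE_MASSES[aa] for aa in seq)
    base = 160.0 + 0.32 * mass + 2.0 * len(seq)
    return base * (0.75 + 0.25 * math.sqrt(ion.charge))


def conformer_delta(ion: PeptideIon, cfg: GeneratorConfig) -> float:
    """Deterministic relative conformer spacing in ``cfg.delta_range``.

    Larger for higher charges, longer sequences and more prolines, echoing
    the planted population contrasts.
    """
    seq = ion.sequence
    pf = seq.count("P") / len(seq)
    s = _sigmoid(1.5 * (ion.charge - 2) + 0.15 * (len(seq) - 14) + 6.0 * pf - 0.5)
    lo, hi = cfg.delta_range
    return lo + (hi - lo) * s


def _multiconf_probability(ion: PeptideIon, cfg: GeneratorConfig,
                           mean_len: float) -> float:
    base = min(max(cfg.multiconf_base_rate, 1e-9), 1 - 1e-9)
    logit = math.log(base / (1 - base))
    logit += cfg.multiconf_len_coef * (len(ion.sequence) - mean_len)
    logit += cfg.multiconf_charge_coef * (ion.charge - 2)
    logit += cfg.multiconf_proline_coef * (1.0 if "P" in ion.sequence else 0.0)
    return _sigmoid(logit)


def _sample_ions(cfg: GeneratorConfig, rng: np.random.Generator) -> list[PeptideIon]:
    letters = sorted(cfg.alphabet)
    freqs = np.array([cfg.alphabet[a] for a in letters], dtype=float)
    freqs /= freqs.sum()
    charges = sorted(cfg.charge_probs)
    cprobs = np.array([cfg.charge_probs[z] for z in charges], dtype=float)
    cprobs /= cprobs.sum()
    seen: set[PeptideIon] = set()
    ions: list[PeptideIon] = []
    while len(ions) < cfg.n_peptides:
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length, p=freqs))
        z = int(rng.choice(charges, p=cprobs))
        ion = PeptideIon(seq, z)
        if ion not in seen:
            seen.add(ion)
            ions.append(ion)
    return ions


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[RunTable], GroundTruth]:
    """Generate multi-run evidence tables plus their planted ground truth.

    Per ion: a multiconformer flag is sampled from the configured
    probability model; conformer CCS values are ``base * (1, 1+δ, 1+2δ,
    ...)``.  Per run: a per-(run, charge) additive offset, relative
    Gaussian CCS noise, dropout and log-normal intensities are applied.
    Fully deterministic under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ions = _sample_ions(cfg, rng)
    mean_len = float(np.mean([len(i.sequence) for i in ions]))
    truth = GroundTruth()

    n_conf_ks = sorted(cfg.n_conformer_probs)
    n_conf_ps = np.array([cfg.n_conformer_probs[k] for k in n_conf_ks], dtype=float)
    n_conf_ps /= n_conf_ps.sum()

    for ion in ions:
        p = _multiconf_probability(ion, cfg, mean_len)
        is_multi = bool(rng.random() < p)
        base = true_ccs(ion)
        if cfg.delta_mode == "random":
            delta = float(rng.uniform(*cfg.delta_range))
        else:
            delta = conformer_delta(ion, cfg)
        if is_multi:
            k = int(rng.choice(n_conf_ks, p=n_conf_ps))
        else:
            k = 1
        conformers = tuple(base * (1.0 + j * delta) for j in range(k))
        truth.conformers[ion] = conformers
        truth.is_multi[ion] = is_multi
        truth.deltas[ion] = delta

    run_ids = [f"run_{r:03d}" for r in range(cfg.n_runs)]
    charges = sorted({i.charge for i in ions})
    for rid in run_ids:
        for z in charges:
            truth.offsets[(rid, z)] = float(rng.normal(0.0, cfg.offset_sd))

    tables = []
    for rid in run_ids:
        obs_list = []
        for ion in ions:
            b = truth.offsets[(rid, ion.charge)]
            for conf_ccs in truth.conformers[ion]:
                if rng.random() < cfg.dropout:
                    continue
                noise = rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma else 0.0
                ccs = conf_ccs * (1.0 + noise) + b
                intensity = float(
                    np.exp(rng.normal(cfg.intensity_mu, cfg.intensity_sigma))
                )
                identified = rng.random() >= cfg.contaminant_row_rate
                obs_list.append(
                    Observation(
                        ion=ion,
                        run_id=rid,
                        ccs=float(ccs),
                        intensity=intensity,
                        has_msms=identified,
                        has_ms1_feature=True,
                    )
                )
        tables.append(RunTable(rid, obs_list))
    return tables, truth


def write_evidence_table(runs: Sequence[RunTable], path: str | Path) -> None:
    """Write run tables as one MaxQuant-dialect evidence TSV."""
    with open(path, "w") as fh:
        fh.write("Modified sequence\tCharge\tCCS\tIntensity\tRaw file\tType\n")
        for table in runs:
            for o in table.observations:
                typ = "MULTI-MSMS" if (o.has_msms and o.has_ms1_feature) else (
                    "MSMS" if o.has_msms else "MULTI-MATCH"
                )
                fh.write(
                    f"_{o.ion.peptidoform}_\t{o.ion.charge}\t{o.ccs!r}\t"
                    f"{o.intensity!r}\t{o.run_id}\t{typ}\n"
                )


@dataclass(frozen=True)
class MobilogramConfig:
    """Knobs for the Gaussian-mixture mobilogram generator."""

    seed: int
    n_ions: int = 100
    bimodal_fraction: float = 0.3
    center_range: tuple[float, float] = (400.0, 700.0)  # Å²
    sigma: float = 4.0  # peak width, axis units
    separation_sigmas: float = 6.0  # center-to-center distance / sigma
    secondary_height_range: tuple[float, float] = (0.3, 0.9)
    swap_probability: float = 0.0  # replicate-B intensity-order reversal
    noise_floor: float = 0.01  # relative to primary peak amplitude
    n_points: int = 240
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.bimodal_fraction <= 1:
            raise ValueError("bimodal_fraction must be in [0, 1]")


@dataclass
class MobilogramTruth:
    """Planted peak positions/heights per ion and replicate."""

    centers: dict[PeptideIon, tuple[float, ...]] = field(default_factory=dict)
    heights_a: dict[PeptideIon, tuple[float, ...]] = field(default_factory=dict)
    heights_b: dict[PeptideIon, tuple[float, ...]] = field(default_factory=dict)
    swapped: dict[PeptideIon, bool] = field(default_factory=dict)


def _mixture(axis, centers, heights, sigma, amplitude, noise_floor, rng):
    y = np.zeros_like(axis)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((axis - c) / sigma) ** 2)
    y *= amplitude
    if noise_floor > 0:
        y += np.abs(rng.normal(0.0, noise_floor * amplitude, size=axis.shape))
    return y


def generate_mobilograms(
    cfg: MobilogramConfig,
) -> tuple[dict[str, list[Mobilogram]], MobilogramTruth]:
    """Generate replicate mobilogram pairs on a CCS axis with known peaks.

    Returns ``({"A": [...], "B": [...]}, truth)``; replicate B shares peak
    centers with A and reverses the intensity order with the configured
    probability.
    """
    rng = np.random.default_rng(cfg.seed)
    gen_cfg = GeneratorConfig(seed=cfg.seed + 1, n_peptides=cfg.n_ions)
    ions = _sample_ions(gen_cfg, np.random.default_rng(cfg.seed + 1))
    truth = MobilogramTruth()
    reps: dict[str, list[Mobilogram]] = {"A": [], "B": []}
    for ion in ions:
        c0 = float(rng.uniform(*cfg.center_range))
        bimodal = bool(rng.random() < cfg.bimodal_fraction)
        if bimodal:
            c1 = c0 + cfg.separation_sigmas * cfg.sigma
            h2 = float(rng.uniform(*cfg.secondary_height_range))
            centers = (c0, c1)
            heights_a = (1.0, h2)
            swapped = bool(rng.random() < cfg.swap_probability)
            heights_b = (h2, 1.0) if swapped else heights_a
        else:
            centers = (c0,)
            heights_a = heights_b = (1.0,)
            swapped = False
        truth.centers[ion] = centers
        truth.heights_a[ion] = heights_a
        truth.heights_b[ion] = heights_b
        truth.swapped[ion] = swapped
        lo = centers[0] - 10 * cfg.sigma
        hi = centers[-1] + 10 * cfg.sigma
        axis = np.linspace(lo, hi, cfg.n_points)
        for rep, heights in (("A", heights_a), ("B", heights_b)):
            y = _mixture(
                axis, centers, heights, cfg.sigma, cfg.amplitude,
                cfg.noise_floor, rng,
            )
            reps[rep].append(
                Mobilogram(ion=ion, axis=axis, intensity=y, axis_kind="ccs")
            )
    return reps, truth
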