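"""Atomic-composition encoding of peptidoforms.

Each residue contributes its elemental residue composition (the free amino
acid minus one water) to a positional matrix; modification deltas are added
at the modified position.  Column sums of the positional matrix therefore
equal the molecular composition minus one terminal water.  A global feature
vector carries the total composition, sequence length and a charge one-hot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ..evidence_io import PeptideIon

#: Element channels, in column order.
ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Residue (amino acid minus water) compositions as (C, H, N, O, S, P).
RESIDUE_COMPOSITIONS: dict[str, tuple[int, ...]] = {
    "G": (2, 3, 1, 1, 0, 0),
    "A": (3, 5, 1, 1, 0, 0),
    "S": (3, 5, 1, 2, 0, 0),
    "P": (5, 7, 1, 1, 0, 0),
    "V": (5, 9, 1, 1, 0, 0),
    "T": (4, 7, 1, 2, 0, 0),
    "C": (3, 5, 1, 1, 1, 0),
    "L": (6, 11, 1, 1, 0, 0),
    "I": (6, 11, 1, 1, 0, 0),
    "N": (4, 6, 2, 2, 0, 0),
    "D": (4, 5, 1, 3, 0, 0),
    "Q": (5, 8, 2, 2, 0, 0),
    "K": (6, 12, 2, 1, 0, 0),
    "E": (5, 7, 1, 3, 0, 0),
    "M": (5, 9, 1, 1, 1, 0),
    "H": (6, 7, 3, 1, 0, 0),
    "F": (9, 9, 1, 1, 0, 0),
    "R": (6, 12, 4, 1, 0, 0),
    "Y": (9, 9, 1, 2, 0, 0),
    "W": (11, 10, 2, 1, 0, 0),
}

#: Monoisotopic element masses (Da), used by the synthetic CCS surface.
ELEMENT_MASSES = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
                  "O": 15.9949146221, "S": 31.97207069, "P": 30.97376151}

#: Modification delta compositions, keyed by lowercase token.
MODIFICATION_DELTAS: dict[str, tuple[int, ...]] = {
    "oxidation": (0, 0, 0, 1, 0, 0),
    "ox": (0, 0, 0, 1, 0, 0),
    "carbamidomethyl": (2, 3, 1, 1, 0, 0),
    "cam": (2, 3, 1, 1, 0, 0),
    "acetyl": (2, 2, 0, 1, 0, 0),
    "ac": (2, 2, 0, 1, 0, 0),
    "phospho": (0, 1, 0, 3, 0, 1),
    "ph": (0, 1, 0, 3, 0, 1),
    "methyl": (1, 2, 0, 0, 0, 0),
    "me": (1, 2, 0, 0, 0, 0),
    # Zero-mass tags: encode identically to the unmodified residue.
    "none": (0, 0, 0, 0, 0, 0),
    "unmodified": (0, 0, 0, 0, 0, 0),
}

MAX_CHARGE_ONEHOT = 6

_TOKEN_RE = re.compile(r"([A-Z])|\(([^()]*)\)|\[([^\[\]]*)\]")


class EncodingError(ValueError):
    """Raised when a residue or modification cannot be resolved."""


@dataclass(frozen=True)
class EncodedPeptide:
    """Positional atom-count matrix plus global features for one ion."""

    positional_composition: np.ndarray  # (max_len, len(ELEMENTS))
    global_features: np.ndarray  # totals + length + charge one-hot

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate(
            [self.positional_composition.ravel(), self.global_features]
        )


def parse_peptidoform(peptidoform: str) -> list[tuple[str, list[str]]]:
    """Tokenize a peptidoform into (residue, [modification tokens]) pairs.

    Accepts parenthesised or bracketed modification names after a residue;
    a leading modification attaches to the first residue (N-terminal tag).
    """
    residues: list[tuple[str, list[str]]] = []
    pending: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(peptidoform):
        if m.start() != pos:
            raise EncodingError(
                f"unparseable token at position {pos} in {peptidoform!r}"
            )
        pos = m.end()
        if m.group(1):
            residues.append((m.group(1), []))
        else:
            mod = (m.group(2) or m.group(3) or "").strip()
            if residues:
                residues[-1][1].append(mod)
            else:
                pending.append(mod)
    if pos != len(peptidoform):
        raise EncodingError(
            f"unparseable token at position {pos} in {peptidoform!r}"
        )
    if not residues:
        raise EncodingError(f"no residues found in {peptidoform!r}")
    if pending:
        residues[0] = (residues[0][0], pending + residues[0][1])
    return residues


def _mod_delta(token: str) -> np.ndarray:
    delta = MODIFICATION_DELTAS.get(token.lower())
    if delta is None:
        raise EncodingError(f"unknown modification token {token!r}")
    return np.asarray(delta, dtype=float)


def encode(ion: PeptideIon, max_len: int = 40) -> EncodedPeptide:
    """Encode one peptide ion at the atomic-composition level.

    Raises :class:`EncodingError` for unknown residues/modifications or a
    sequence longer than ``max_len``.
    """
    residues = parse_peptidoform(ion.peptidoform)
    if len(residues) > max_len:
        raise EncodingError(
            f"sequence length {len(residues)} exceeds max_len {max_len}"
        )
    pos = np.zeros((max_len, len(ELEMENTS)), dtype=float)
    for i, (aa, mods) in enumerate(residues):
        comp = RESIDUE_COMPOSITIONS.get(aa)
        if comp is None:
            raise EncodingError(f"unknown residue {aa!r}")
        pos[i] = np.asarray(comp, dtype=float)
        for mod in mods:
            pos[i] += _mod_delta(mod)
    totals = pos.sum(axis=0)
    onehot = np.zeros(MAX_CHARGE_ONEHOT, dtype=float)
    onehot[min(ion.charge, MAX_CHARGE_ONEHOT) - 1] = 1.0
    globals_ = np.concatenate([totals, [float(len(residues))], onehot])
    return EncodedPeptide(positional_composition=pos, global_features=globals_)


def n_features(max_len: int = 40) -> int:
    """Length of the flattened feature vector produced by :func:`encode`."""
    return max_len * len(ELEMENTS) + len(ELEMENTS) + 1 + MAX_CHARGE_ONEHOT


def encode_matrix(ions, max_len: int = 40) -> np.ndarray:
    """Encode a sequence of ions into a (n, n_features) design matrix."""
    return np.stack([encode(ion, max_len).flat for ion in ions])
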