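"""Exact mass and m/z computation for PTM-decorated histone H3 N-terminal proteoforms.

The species modelled throughout this package is the Glu-C limit peptide of
histone H3.1: cleavage C-terminal to glutamate leaves residues 1-50
(ARTK...ALRE) as the N-terminal tail peptide, observed as the [M+9H]9+
charge state in the 585-640 Th MS1 window.  Site-resolved K4 methylation is
read out from the singly charged ETD c4 fragment ion series (c-ions retain
the N-terminus and all PTMs up to the cleavage site), giving four targets at
nominal m/z 474 (me0), 488 (me1), 502 (me2) and 516 (me3) regardless of the
acetylation state of the rest of the tail.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Sequence, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "H3_1_50",
    "K4_ACETYL_SITES",
    "PTM_DELTAS",
    "WATER",
    "PROTON",
    "NH3",
    "Proteoform",
    "FragmentIon",
    "InvalidProteoformError",
    "proteoform_mass",
    "ion_mz",
    "c4_targets",
    "enumerate_h3_proteoforms",
    "parse_proteoform",
    "format_proteoform",
    "round_half_away",
]

#: Glu-C N-terminal limit peptide of histone H3.1 (residues 1-50).
H3_1_50 = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALRE"

#: Lysines quantified for acetyl degree (K4 carries the methyl readout).
K4_ACETYL_SITES: Tuple[int, ...] = (9, 14, 18, 23, 27)

# Monoisotopic constants (Da).
WATER = 18.010565
PROTON = 1.007276
NH3 = 17.026549

#: Monoisotopic mass shifts of the supported PTMs.  Note the near-isobaric
#: pair me3/ac: 42.046950 - 42.010565 = 0.036385 Da, resolvable in the
#: orbitrap MS1 but only 0.0040 Th apart at 9+.
PTM_DELTAS = {
    "me1": 14.015650,
    "me2": 28.031300,
    "me3": 42.046950,
    "ac": 42.010565,
}

_RESIDUE_MASS = dict(_pmass.std_aa_mass)


class InvalidProteoformError(ValueError):
    """Sequence or PTM set violates the proteoform invariants."""


@dataclass(frozen=True)
class Proteoform:
    """A peptide sequence with a site-resolved PTM set.

    Parameters
    ----------
    sequence:
        One-letter amino-acid string (non-empty, standard residues only).
    ptms:
        Set of ``(position, kind)`` pairs; positions are 1-based, kinds are
        one of ``me1``/``me2``/``me3``/``ac``.  Methylation and acetylation
        are only valid on lysine, and a position carries at most one PTM.
    """

    sequence: str
    ptms: FrozenSet[Tuple[int, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidProteoformError("empty sequence")
        for ch in self.sequence:
            if ch not in _RESIDUE_MASS:
                raise InvalidProteoformError(f"unknown residue {ch!r}")
        object.__setattr__(self, "ptms", frozenset(self.ptms))
        seen = set()
        for pos, kind in self.ptms:
            if not 1 <= pos <= len(self.sequence):
                raise InvalidProteoformError(f"PTM position {pos} out of range")
            if kind not in PTM_DELTAS:
                raise InvalidProteoformError(f"unknown PTM kind {kind!r}")
            if pos in seen:
                raise InvalidProteoformError(f"multiple PTMs at position {pos}")
            seen.add(pos)
            if self.sequence[pos - 1] != "K":
                raise InvalidProteoformError(
                    f"{kind} at position {pos} ({self.sequence[pos - 1]}): "
                    "methylation/acetylation only valid on K"
                )

    @property
    def acetyl_degree(self) -> int:
        return sum(1 for _, kind in self.ptms if kind == "ac")

    def k4_state(self) -> str:
        """K4 methyl state as ``me0``..``me3`` (``me0`` when unmodified)."""
        for pos, kind in self.ptms:
            if pos == 4:
                return kind
        return "me0"


@dataclass(frozen=True)
class FragmentIon:
    """A c-series or precursor ion with its computed m/z (Th)."""

    series: str  # "c" or "precursor"
    index: int  # residue count for c-ions; 0 for precursor
    charge: int
    mz: float


def proteoform_mass(p: Proteoform) -> float:
    """Monoisotopic neutral mass (Da): residues + water + PTM deltas."""
    m = sum(_RESIDUE_MASS[ch] for ch in p.sequence) + WATER
    m += sum(PTM_DELTAS[kind] for _, kind in p.ptms)
    return m


def ion_mz(p: Proteoform, series: str, index: int = 0, charge: int = 1) -> float:
    """m/z of a c-series fragment or the intact precursor.

    c-ions are the ETD N-terminal fragments: residues 1..index plus NH2
    transferred to the carbonyl, i.e. residue masses + NH3, protonated to the
    requested charge.  PTMs at positions <= index ride along, so the c4 ion
    reads out the K4 state independently of downstream acetylation.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if series == "precursor":
        return (proteoform_mass(p) + charge * PROTON) / charge
    if series == "c":
        if not 1 <= index < len(p.sequence):
            raise ValueError(
                f"c-ion index {index} out of range for length {len(p.sequence)}"
            )
        m = sum(_RESIDUE_MASS[ch] for ch in p.sequence[:index]) + NH3
        m += sum(PTM_DELTAS[kind] for pos, kind in p.ptms if pos <= index)
        return (m + charge * PROTON) / charge
    raise ValueError(f"unknown ion series {series!r}")


def c4_targets(sequence: str = H3_1_50) -> Tuple[float, float, float, float]:
    """The four targeted C4+1 m/z values for K4 me0/me1/me2/me3 (ascending)."""
    out = []
    for state in ("me0", "me1", "me2", "me3"):
        ptms = frozenset() if state == "me0" else frozenset({(4, state)})
        out.append(ion_mz(Proteoform(sequence, ptms), "c", 4, 1))
    return tuple(out)


def enumerate_h3_proteoforms(
    k4_states: Iterable[str] = ("me0", "me1", "me2", "me3"),
    acetyl_sites: Sequence[int] = K4_ACETYL_SITES,
    degrees: Iterable[int] = range(0, 6),
    sequence: str = H3_1_50,
) -> list[Proteoform]:
    """All proteoforms = K4 methyl states x acetyl-site combinations.

    Returns ``|k4_states| * sum_d C(|sites|, d)`` distinct proteoforms.
    ``acetyl_sites`` must be lysines distinct from K4.
    """
    k4_states = list(dict.fromkeys(k4_states))
    sites = list(acetyl_sites)
    if 4 in sites:
        raise ValueError("acetyl sites must be distinct from K4")
    degrees = list(degrees)
    for d in degrees:
        if d > len(sites):
            raise ValueError(f"acetyl degree {d} exceeds {len(sites)} sites")
        if d < 0:
            raise ValueError("acetyl degree must be >= 0")
    out = []
    for state in k4_states:
        if state not in ("me0", "me1", "me2", "me3"):
            raise ValueError(f"unknown K4 state {state!r}")
        base = frozenset() if state == "me0" else frozenset({(4, state)})
        for d in degrees:
            for combo in itertools.combinations(sites, d):
                out.append(
                    Proteoform(sequence, base | {(pos, "ac") for pos in combo})
                )
    return out


_NOTATION_HEAD = re.compile(r"^H3\((\d+)-(\d+)\)$")
_NOTATION_PTM = re.compile(r"^K(\d+)(me[123]|ac)$")


def parse_proteoform(text: str, sequence: str = H3_1_50) -> Proteoform:
    """Parse the text notation, e.g. ``"H3(1-50) K4me3 K9ac K14ac"``."""
    tokens = text.split()
    if not tokens:
        raise InvalidProteoformError("empty proteoform notation")
    m = _NOTATION_HEAD.match(tokens[0])
    if not m:
        raise InvalidProteoformError(f"bad proteoform header {tokens[0]!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    if (lo, hi) != (1, len(sequence)):
        raise InvalidProteoformError(
            f"residue range {lo}-{hi} does not match sequence length {len(sequence)}"
        )
    ptms = set()
    for tok in tokens[1:]:
        pm = _NOTATION_PTM.match(tok)
        if not pm:
            raise InvalidProteoformError(f"bad PTM token {tok!r}")
        ptms.add((int(pm.group(1)), pm.group(2)))
    return Proteoform(sequence, frozenset(ptms))


def format_proteoform(p: Proteoform) -> str:
    """Serialize to the text notation; round-trips with :func:`parse_proteoform`."""
    parts = [f"H3(1-{len(p.sequence)})"]
    for pos, kind in sorted(p.ptms):
        parts.append(f"K{pos}{kind}")
    return " ".join(parts)


def round_half_away(x: float) -> int:
    """Round half away from zero (matching printed integer m/z values)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
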