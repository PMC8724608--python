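"""Theoretical glycopeptide fragment ions and library slot allocation.

Glycopeptide MS/MS spectra carry three fragment families that a
peptide-centric DIA library format has no native column for: Y ions
(peptide with 0/1/2 core HexNAc retained), b/y ions that kept a single
HexNAc, and b/y ions that kept the intact glycan.  To fit them into the
fixed a/b/c/y ion vocabulary of a PeakView-style transition list they are
repurposed into "slots": Y0/Y1/Y2 become a1/a2/a3, b/y+HexNAc1 at peptide
positions >= 4 become aN, and b/y+glycan become cN.  b/y+HexNAc1 at
positions 1-3 would collide with the Y slots and are excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .chem import (
    MONOSACCHARIDE_MASSES,
    PROTON,
    RESIDUE_MASSES,
    WATER,
    GlycanComposition,
    Glycopeptide,
    precursor_mz,
)

__all__ = [
    "FragmentIon",
    "OxoniumIon",
    "SlotInfo",
    "enumerate_fragments",
    "allocate_slot",
    "parse_slot",
    "oxonium_table",
    "fragment_neutral_mass",
]

FRAGMENT_CHARGES = (1, 2)

_HEXNAC1 = GlycanComposition(hexnac=1)
_HEXNAC2 = GlycanComposition(hexnac=2)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment with its library slot allocation.

    ``series`` is ``b``/``y`` for backbone fragments or ``Y`` for
    glycopeptide Y ions; ``index`` is the backbone cleavage position, or
    the number of retained HexNAc for Y ions.  ``slot`` is ``None`` when
    the fragment class is excluded from the library.
    """

    series: str
    index: int
    glycan_remainder: GlycanComposition
    charge: int
    mz: float
    slot: str | None


@dataclass(frozen=True)
class OxoniumIon:
    monosaccharide: str
    mz: float  # singly protonated
    required: bool  # must be observed to confirm the composition


def _prefix_mass(sequence: str, index: int) -> float:
    """Neutral mass of a b fragment (first ``index`` residues, no water)."""
    return sum(RESIDUE_MASSES[aa] for aa in sequence[:index])


def _suffix_mass(sequence: str, index: int) -> float:
    """Neutral mass of a y fragment (last ``index`` residues + water)."""
    return sum(RESIDUE_MASSES[aa] for aa in sequence[-index:]) + WATER


def fragment_neutral_mass(
    gp: Glycopeptide, series: str, index: int, remainder: GlycanComposition
) -> float:
    """Neutral mass of a fragment, including mods and retained glycan.

    Explicit modifications are attributed to the backbone fragment that
    contains their residue; Y ions carry the whole peptide.
    """
    seq = gp.peptide.sequence
    n = len(seq)
    if series == "Y":
        return gp.peptide.neutral_mass + remainder.mass
    if series == "b":
        mass = _prefix_mass(seq, index)
        mass += sum(m.delta for m in gp.peptide.mods if m.position <= index)
    elif series == "y":
        mass = _suffix_mass(seq, index)
        mass += sum(m.delta for m in gp.peptide.mods if m.position > n - index)
    else:
        raise ValueError(f"unknown series {series!r}")
    return mass + remainder.mass


def _contains_site(series: str, index: int, n: int, site: int) -> bool:
    if series == "b":
        return site <= index
    return site > n - index  # y


def allocate_slot(
    series: str, index: int, remainder: GlycanComposition, glycan: GlycanComposition
) -> str | None:
    """Map a fragment to its library slot label, or None if excluded.

    Plain b/y keep their native labels.  Y0/Y1/Y2 take a1/a2/a3.  A b/y
    fragment retaining HexNAc1 takes "a<index>" but only from index 4
    upward (a1-a3 are reserved for the Y ions); retaining the intact
    glycan takes "c<index>".
    """
    if series == "Y":
        return f"a{index + 1}"
    if not remainder:
        return f"{series}{index}"
    if remainder == glycan:
        return f"c{index}"
    if remainder == _HEXNAC1:
        return f"a{index}" if index >= 4 else None
    raise ValueError(f"no slot class for remainder {remainder}")


_SLOT_RE = re.compile(r"^([abcy])(\d+)$")


@dataclass(frozen=True)
class SlotInfo:
    """What a slot label encodes: fragment kind, series (when determined),
    and backbone index or Y number."""

    kind: str  # "plain" | "Y" | "hexnac" | "intact"
    series: str | None
    index: int


def parse_slot(slot: str) -> SlotInfo:
    """Invert a slot label back to (kind, series, index).

    ``aN`` for N >= 4 is a b/y+HexNAc1 fragment whose series is not
    recoverable from the label alone (both map to the same slot by
    design); ``series`` is None in that case.
    """
    m = _SLOT_RE.match(slot)
    if m is None:
        raise ValueError(f"malformed slot label {slot!r}")
    letter, num = m.group(1), int(m.group(2))
    if letter in ("b", "y"):
        return SlotInfo("plain", letter, num)
    if letter == "c":
        return SlotInfo("intact", None, num)
    # "a" slots
    if num <= 3:
        return SlotInfo("Y", "Y", num - 1)
    return SlotInfo("hexnac", None, num)


def enumerate_fragments(gp: Glycopeptide) -> list[FragmentIon]:
    """All theoretical library-eligible fragments of a glycopeptide.

    At charges 1+ and 2+: plain b/y ions (full glycan loss); Y0 for
    O-linked or Y0/Y1/Y2 for N-linked; and, when the glycosite is
    localised, site-containing b/y ions with HexNAc1 (N-linked only) and
    with the intact glycan.  Excluded classes are emitted with
    ``slot=None`` so callers can count or log them.
    """
    seq = gp.peptide.sequence
    n = len(seq)
    if n < 2:
        raise ValueError("peptide must have at least 2 residues")
    glycan = gp.glycan
    empty = GlycanComposition()

    # (series, index, remainder) triples
    shapes: list[tuple[str, int, GlycanComposition]] = []
    for idx in range(1, n):
        shapes.append(("b", idx, empty))
        shapes.append(("y", idx, empty))
    shapes.append(("Y", 0, empty))
    if gp.linkage == "N":
        shapes.append(("Y", 1, _HEXNAC1))
        shapes.append(("Y", 2, _HEXNAC2))
    if gp.site is not None and glycan:
        for idx in range(1, n):
            for series in ("b", "y"):
                if not _contains_site(series, idx, n, gp.site):
                    continue
                if gp.linkage == "N" and glycan != _HEXNAC1:
                    shapes.append((series, idx, _HEXNAC1))
                shapes.append((series, idx, glycan))

    out: list[FragmentIon] = []
    for series, index, remainder in shapes:
        mass = fragment_neutral_mass(gp, series, index, remainder)
        slot = allocate_slot(series, index, remainder, glycan)
        for z in FRAGMENT_CHARGES:
            out.append(
                FragmentIon(
                    series=series,
                    index=index,
                    glycan_remainder=remainder,
                    charge=z,
                    mz=precursor_mz(mass, z),
                    slot=slot,
                )
            )
    return out


def oxonium_table(
    glycan: GlycanComposition, linkage: str = "N"
) -> list[OxoniumIon]:
    """Singly protonated oxonium m/z for each monosaccharide present.

    dHex and Pent oxonium ions are weak or absent in N-glycan spectra, so
    for N-linkage they are flagged not-required (exempt from the
    oxonium-presence validation rule); every other present monosaccharide
    must be observed.
    """
    out = []
    for name, count in glycan.counts().items():
        if count == 0:
            continue
        exempt = linkage == "N" and name in ("dHex", "Pent")
        out.append(
            OxoniumIon(
                monosaccharide=name,
                mz=MONOSACCHARIDE_MASSES[name] + PROTON,
                required=not exempt,
            )
        )
    return out
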