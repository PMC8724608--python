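"""Monoisotopic mass arithmetic for glycopeptides.

All masses in this package come from the single constants table below
(monoisotopic residue masses to five decimals), so precursor m/z and ppm
values are reproducible to the last printed digit.  Hydroxyproline is
written in-sequence as a lowercase ``p`` (the display convention used for
plant proline-rich glycoproteins); every other modification is carried as
an explicit (position, delta, label) triple.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "PROTON",
    "WATER",
    "MONOSACCHARIDE_MASSES",
    "RESIDUE_MASSES",
    "MOD_DEAMIDATION",
    "MOD_OXIDATION",
    "MOD_DEHYDRO",
    "GlycanComposition",
    "Modification",
    "ModifiedPeptide",
    "Glycopeptide",
    "parse_glycan",
    "glycan_mass",
    "peptide_neutral_mass",
    "precursor_mz",
    "ppm_error",
    "constants_table",
]

PROTON = 1.0072765
WATER = 18.010565

#: Monoisotopic residue (dehydrated) masses of the glycan building blocks, Da.
MONOSACCHARIDE_MASSES: dict[str, float] = {
    "HexNAc": 203.07937,  # N-acetylhexosamine (GlcNAc/GalNAc)
    "Hex": 162.05282,  # hexose (mannose/glucose/galactose)
    "dHex": 146.05791,  # deoxyhexose (fucose)
    "Pent": 132.04226,  # pentose (xylose/arabinose)
}

#: Monoisotopic amino-acid residue masses, Da.  Lowercase 'p' is
#: hydroxyproline (Pro + 15.99491).
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
    "p": 97.05276 + 15.99491,
}

# Deltas for the variable modifications used in the search space.
MOD_DEAMIDATION = 0.98402
MOD_OXIDATION = 15.99491
MOD_DEHYDRO = -1.00783

#: Cleavage classes relevant to validation stringency.
CLEAVAGE_CLASSES = ("tryptic", "semitryptic", "KR_P", "N_ragged")

_MONO_ORDER = ("HexNAc", "Hex", "dHex", "Pent")
# HexNAc before Hex so the longer name wins during tokenisation.
_GLYCAN_TOKEN = re.compile(r"(HexNAc|Hex|dHex|Pent)(\d+)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide count vector (Hex, HexNAc, dHex, Pent)."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    pent: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "pent"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative monosaccharide count: {name}")

    @property
    def mass(self) -> float:
        return (
            self.hex * MONOSACCHARIDE_MASSES["Hex"]
            + self.hexnac * MONOSACCHARIDE_MASSES["HexNAc"]
            + self.dhex * MONOSACCHARIDE_MASSES["dHex"]
            + self.pent * MONOSACCHARIDE_MASSES["Pent"]
        )

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.dhex + other.dhex,
            self.pent + other.pent,
        )

    def __bool__(self) -> bool:
        return any((self.hex, self.hexnac, self.dhex, self.pent))

    def counts(self) -> dict[str, int]:
        return {
            "HexNAc": self.hexnac,
            "Hex": self.hex,
            "dHex": self.dhex,
            "Pent": self.pent,
        }

    def __str__(self) -> str:
        return "".join(
            f"{name}{count}" for name, count in self.counts().items() if count
        )


def parse_glycan(text: str) -> GlycanComposition:
    """Parse a composition string like ``"HexNAc2Hex3dHex1Pent1"``.

    The grammar is a concatenation of monosaccharide names each followed by
    a positive integer count, in any order; omitted monosaccharides count
    zero and the empty string is the empty composition.
    """
    counts = {name: 0 for name in _MONO_ORDER}
    pos = 0
    while pos < len(text):
        m = _GLYCAN_TOKEN.match(text, pos)
        if m is None:
            raise ValueError(
                f"unknown monosaccharide token at {text[pos:]!r} in {text!r}"
            )
        counts[m.group(1)] += int(m.group(2))
        pos = m.end()
    return GlycanComposition(
        hex=counts["Hex"],
        hexnac=counts["HexNAc"],
        dhex=counts["dHex"],
        pent=counts["Pent"],
    )


def glycan_mass(glycan: GlycanComposition) -> float:
    """Neutral monoisotopic mass of a glycan composition, Da."""
    return glycan.mass


@dataclass(frozen=True)
class Modification:
    position: int  # 1-based residue index
    delta: float  # Da
    label: str = ""


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence plus positional modifications.

    ``sequence`` uses uppercase one-letter codes; lowercase ``p`` denotes
    hydroxyproline and already carries its +15.99491 Da in the residue
    table, so it needs no explicit modification entry.
    """

    sequence: str
    mods: tuple[Modification, ...] = ()
    protein_accession: str = ""
    cleavage: str = "tryptic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue {aa!r} at position {i}")
        if self.cleavage not in CLEAVAGE_CLASSES:
            raise ValueError(f"unknown cleavage class {self.cleavage!r}")
        seen: set[tuple[int, str]] = set()
        for mod in self.mods:
            if not 1 <= mod.position <= len(self.sequence):
                raise ValueError(
                    f"modification position {mod.position} outside peptide"
                )
            key = (mod.position, mod.label)
            if key in seen:
                raise ValueError(f"duplicate modification {key}")
            seen.add(key)
        object.__setattr__(self, "mods", tuple(self.mods))

    @property
    def stripped(self) -> str:
        """Sequence with modification annotations removed (uppercase)."""
        return self.sequence.upper()

    @property
    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self)

    def annotated(self) -> str:
        """Sequence with ``(label)`` after each explicitly modified residue."""
        out = []
        by_pos: dict[int, list[Modification]] = {}
        for mod in self.mods:
            by_pos.setdefault(mod.position, []).append(mod)
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            for mod in by_pos.get(i, ()):
                out.append(f"({mod.label or format(mod.delta, '+.5f')})")
        return "".join(out)


def peptide_neutral_mass(peptide: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residues + modification deltas + water."""
    mass = WATER
    for aa in peptide.sequence:
        mass += RESIDUE_MASSES[aa]
    for mod in peptide.mods:
        mass += mod.delta
    return mass


def _is_sequon(sequence: str, site: int) -> bool:
    """N-X-S/T with X != P, at 1-based ``site`` (the Asn)."""
    i = site - 1
    return (
        i + 2 < len(sequence)
        and sequence[i] == "N"
        and sequence[i + 1].upper() != "P"
        and sequence[i + 2] in ("S", "T")
    )


@dataclass(frozen=True)
class Glycopeptide:
    """A modified peptide carrying one glycan of known linkage class.

    ``site`` is the 1-based attachment residue when localised, else ``None``
    (site-ambiguous identifications are accepted: site specificity is not a
    requirement for library building).
    """

    peptide: ModifiedPeptide
    glycan: GlycanComposition
    linkage: str  # "N" or "O"
    site: int | None = None

    def __post_init__(self) -> None:
        if self.linkage not in ("N", "O"):
            raise ValueError(f"linkage must be 'N' or 'O', got {self.linkage!r}")
        if self.site is not None:
            seq = self.peptide.sequence
            if not 1 <= self.site <= len(seq):
                raise ValueError(f"site {self.site} outside peptide")
            if self.linkage == "N":
                if not _is_sequon(seq, self.site):
                    raise ValueError(
                        f"N-glycosite {self.site} is not on an N-X-S/T sequon"
                    )
            else:
                if seq[self.site - 1] not in ("S", "T", "p"):
                    raise ValueError(
                        f"O-glycosite {self.site} must be Ser/Thr/hydroxyproline"
                    )

    @property
    def neutral_mass(self) -> float:
        return self.peptide.neutral_mass + self.glycan.mass

    def modified_sequence(self) -> str:
        """Annotated peptide string with the glycan appended in brackets."""
        base = self.peptide.annotated()
        return f"{base}[{self.glycan}]" if self.glycan else base


def precursor_mz(neutral_mass: float, z: int) -> float:
    """m/z of an ion of ``neutral_mass`` carrying ``z`` protons."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON) / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error (observed - theoretical) in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def constants_table() -> list[tuple[str, float]]:
    """Machine-readable (name, monoisotopic mass) table of every constant."""
    rows: list[tuple[str, float]] = [("proton", PROTON), ("water", WATER)]
    rows += [(f"residue_{aa}", m) for aa, m in sorted(RESIDUE_MASSES.items())]
    rows += [
        (f"monosaccharide_{name}", MONOSACCHARIDE_MASSES[name])
        for name in _MONO_ORDER
    ]
    rows += [
        ("mod_deamidation", MOD_DEAMIDATION),
        ("mod_oxidation", MOD_OXIDATION),
        ("mod_dehydro", MOD_DEHYDRO),
    ]
    return rows


def write_constants_table(path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tmass\n")
        for name, mass in constants_table():
            fh.write(f"{name}\t{mass:.7f}\n")
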