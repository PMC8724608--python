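"""Deterministic glycopeptide PSM validation rules.

Encodes the manual-inspection criteria used to accept glycopeptide
identifications as a rule engine over a candidate glycopeptide and its
centroided MS/MS spectrum:

1. every required oxonium ion of the glycan must be present (dHex and
   Pent are exempt for N-glycans);
2. peptides from Lys/Arg-Pro or N-ragged cleavage are held to the strict
   path: the Y0 (O-linked) or Y1 (N-linked) ion AND >= 3 b ions AND >= 3
   y ions;
3. otherwise, with Y0/Y1 present, >= 3 backbone ions from the union of
   the b and y series suffice;
4. without Y0/Y1, the fallback requires >= 3 backbone ions with both
   series represented (a ``strict_fallback`` switch demands >= 3 of each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Glycopeptide
from .fragments import enumerate_fragments, oxonium_table

__all__ = [
    "SpectrumPeaks",
    "ValidationVerdict",
    "Evidence",
    "match_peaks",
    "validate",
]

DEFAULT_FRAGMENT_TOL_PPM = 50.0
DEFAULT_PRECURSOR_TOL_PPM = 20.0

_RAGGED = ("KR_P", "N_ragged")


@dataclass
class SpectrumPeaks:
    """A centroided peak list for one MS/MS scan.

    Peaks are stored sorted by ascending m/z; non-positive intensities are
    rejected at construction.
    """

    scan: int
    rt: float  # minutes
    precursor_mz: float
    precursor_z: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity <= 0):
            raise ValueError("peak intensities must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)


def match_peaks(
    spectrum: SpectrumPeaks, targets: list[float], tol_ppm: float
) -> np.ndarray:
    """Match target m/z values against a spectrum within ±tol_ppm.

    Returns a boolean mask over ``targets``.  Each peak is consumed by at
    most one target; ties go to the nearest peak in m/z, targets processed
    in ascending m/z order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    targets_arr = np.asarray(targets, dtype=float)
    matched = np.zeros(targets_arr.size, dtype=bool)
    if len(spectrum) == 0 or targets_arr.size == 0:
        return matched
    used = np.zeros(len(spectrum), dtype=bool)
    for ti in np.argsort(targets_arr, kind="stable"):
        t = targets_arr[ti]
        tol = t * tol_ppm * 1e-6
        lo = int(np.searchsorted(spectrum.mz, t - tol, side="left"))
        hi = int(np.searchsorted(spectrum.mz, t + tol, side="right"))
        best = -1
        best_d = np.inf
        for pi in range(lo, hi):
            if used[pi]:
                continue
            d = abs(spectrum.mz[pi] - t)
            if d < best_d:
                best_d = d
                best = pi
        if best >= 0:
            used[best] = True
            matched[ti] = True
    return matched


@dataclass
class Evidence:
    """Counts of matched ion classes backing a verdict."""

    oxonium_required: int = 0
    oxonium_matched: int = 0
    y0: bool = False
    y1: bool = False
    b_count: int = 0
    y_count: int = 0


@dataclass
class ValidationVerdict:
    accepted: bool
    rule_path: str  # "standard" | "no_Y_fallback" | "ragged_strict"
    evidence: Evidence
    notes: list[str] = field(default_factory=list)


def validate(
    gp: Glycopeptide,
    spectrum: SpectrumPeaks,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    strict_fallback: bool = False,
    co_elution_support: bool = False,
) -> ValidationVerdict:
    """Apply the acceptance rules to one (glycopeptide, spectrum) pair.

    ``co_elution_support`` records that other glycoforms of the same
    peptide co-elute; it is advisory only and never changes the verdict.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    notes: list[str] = []
    if co_elution_support:
        notes.append("co-elution of other glycoforms noted (advisory)")

    ev = Evidence()

    oxonium = oxonium_table(gp.glycan, gp.linkage)
    required = [o for o in oxonium if o.required]
    exempt = [o.monosaccharide for o in oxonium if not o.required]
    if exempt:
        notes.append(f"oxonium exempt ({gp.linkage}-glycan): {', '.join(exempt)}")
    ev.oxonium_required = len(required)
    if required:
        mask = match_peaks(spectrum, [o.mz for o in required], tol_ppm)
        ev.oxonium_matched = int(mask.sum())

    fragments = enumerate_fragments(gp)
    # Distinct backbone positions matched at any charge.
    b_targets: dict[int, list[float]] = {}
    y_targets: dict[int, list[float]] = {}
    y_ion_mz: dict[int, list[float]] = {}
    for f in fragments:
        if f.series == "Y":
            y_ion_mz.setdefault(f.index, []).append(f.mz)
        elif not f.glycan_remainder:
            (b_targets if f.series == "b" else y_targets).setdefault(
                f.index, []
            ).append(f.mz)

    def any_matched(mzs: list[float]) -> bool:
        return bool(match_peaks(spectrum, mzs, tol_ppm).any())

    ev.y0 = any_matched(y_ion_mz.get(0, []))
    ev.y1 = any_matched(y_ion_mz.get(1, []))
    ev.b_count = sum(any_matched(mzs) for mzs in b_targets.values())
    ev.y_count = sum(any_matched(mzs) for mzs in y_targets.values())

    y_anchor = ev.y0 if gp.linkage == "O" else ev.y1

    if gp.peptide.cleavage in _RAGGED:
        rule_path = "ragged_strict"
        accepted = y_anchor and ev.b_count >= 3 and ev.y_count >= 3
    elif y_anchor:
        rule_path = "standard"
        accepted = (ev.b_count + ev.y_count) >= 3
    else:
        rule_path = "no_Y_fallback"
        if strict_fallback:
            accepted = ev.b_count >= 3 and ev.y_count >= 3
        else:
            accepted = (
                (ev.b_count + ev.y_count) >= 3
                and ev.b_count >= 1
                and ev.y_count >= 1
            )

    if ev.oxonium_required and ev.oxonium_matched < ev.oxonium_required:
        accepted = False
        notes.append("missing required oxonium ion(s)")

    return ValidationVerdict(
        accepted=accepted, rule_path=rule_path, evidence=ev, notes=notes
    )
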