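"""DIA window schemes, transition quantification and glycoform fractions.

Quantification follows the SWATH extracted-ion-chromatogram convention:
per transition, signal within a ppm-width m/z tolerance around Q3 and a
retention-time window centred on the library RT is summed, inside the
acquisition window that isolates Q1.  Peptide-precursor intensities are
the sum of the top-k transitions ranked by library reference intensity
(k = 6 by default), proteins the sum of their peptides, and site-specific
glycoform relative abundances are each glycoform's share of the summed
intensity of all detected forms of its peptide family across charge
states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import IonLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "DiaWindowScheme",
    "AbundanceMatrix",
    "GlycoformProfile",
    "make_windows",
    "quantify_transitions",
    "rollup",
    "normalize_to_reference",
    "normalize_total",
    "glycoform_fractions",
    "transition_id",
]

DEFAULT_TOP_K = 6
DEFAULT_RT_WINDOW_MIN = 6.0
DEFAULT_XIC_PPM = 75.0


@dataclass(frozen=True)
class DiaWindowScheme:
    """Fixed-width overlapping isolation windows covering [low, high]."""

    low: float
    high: float
    width: float
    overlap: float
    windows: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.windows)

    def assign(self, mz: float) -> int | None:
        """Index of the acquisition window isolating ``mz``.

        m/z values inside an overlap region belong to two windows; the
        later (higher) window is returned so assignment is unique.
        """
        if mz < self.low or mz > self.windows[-1][1]:
            return None
        step = self.width - self.overlap
        i = int((mz - self.low) // step)
        return min(i, len(self.windows) - 1)


def make_windows(
    low: float, high: float, width: float, overlap: float
) -> DiaWindowScheme:
    """Build a DIA isolation-window scheme.

    Window i spans [low + i*(width-overlap), ... + width]; enough windows
    are emitted for full coverage of [low, high] with each consecutive
    pair overlapping by exactly ``overlap`` m/z.
    """
    if high <= low:
        raise ValueError("high must exceed low")
    if overlap < 0 or width <= overlap:
        raise ValueError("need width > overlap >= 0")
    step = width - overlap
    count = max(1, math.ceil((high - low - overlap) / step))
    windows = tuple(
        (low + i * step, low + i * step + width) for i in range(count)
    )
    return DiaWindowScheme(
        low=low, high=high, width=width, overlap=overlap, windows=windows
    )


def transition_id(modified_sequence: str, prec_z: int, slot: str, frg_z: int) -> str:
    return f"{modified_sequence}/{prec_z}/{slot}/{frg_z}"


@dataclass
class AbundanceMatrix:
    """Analyte-by-sample intensity matrix with level-specific metadata.

    ``data`` holds nonnegative intensities (rows = analytes, columns =
    samples).  ``meta`` maps transition rows back to their precursor,
    protein and library reference intensity; it is present at the
    transition and peptide levels and drives rollup.
    """

    data: pd.DataFrame
    level: str  # "transition" | "peptide" | "protein"
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative intensities are not allowed")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _xic_sum(
    peaks: pd.DataFrame,
    q3: float,
    rt: float,
    rt_half: float,
    xic_ppm: float,
    window_idx: int | None,
) -> float:
    mz = peaks["mz"].to_numpy(dtype=float)
    rt_arr = peaks["rt_min"].to_numpy(dtype=float)
    sel = (np.abs(mz - q3) <= q3 * xic_ppm * 1e-6) & (
        np.abs(rt_arr - rt) <= rt_half
    )
    if window_idx is not None and "q1_window" in peaks.columns:
        sel &= peaks["q1_window"].to_numpy(dtype=float) == window_idx
    return float(peaks.loc[sel, "intensity"].sum())


def quantify_transitions(
    lib: IonLibrary,
    samples: dict[str, pd.DataFrame],
    rt_window: float = DEFAULT_RT_WINDOW_MIN,
    xic_ppm: float = DEFAULT_XIC_PPM,
    scheme: DiaWindowScheme | None = None,
) -> AbundanceMatrix:
    """Quantify every library transition in every sample.

    Each sample is either a peak stream (columns ``mz``, ``rt_min``,
    ``intensity``, optional ``q1_window``) — quantified by XIC summation
    within ±xic_ppm of Q3 and ±rt_window/2 of the library RT — or a
    pre-extracted transition table (columns ``modified_sequence``,
    ``prec_z``, ``slot``, ``frg_z``, ``intensity``).  Absent signal
    yields 0.
    """
    if not samples:
        raise ValueError("no samples provided")
    ids = [
        transition_id(
            r.modified_sequence, r.precursor_charge, r.slot, r.fragment_charge
        )
        for r in lib.records
    ]
    if scheme is not None:
        for r in lib.records:
            if scheme.assign(r.q1) is None:
                logger.warning(
                    "Q1 %.4f of %s outside acquisition range", r.q1, r.modified_sequence
                )
    meta = pd.DataFrame(
        {
            "modified_sequence": [r.modified_sequence for r in lib.records],
            "stripped_sequence": [r.stripped_sequence for r in lib.records],
            "prec_z": [r.precursor_charge for r in lib.records],
            "slot": [r.slot for r in lib.records],
            "frg_z": [r.fragment_charge for r in lib.records],
            "protein": [r.protein for r in lib.records],
            "library_intensity": [r.relative_intensity for r in lib.records],
        },
        index=ids,
    )

    data = pd.DataFrame(0.0, index=ids, columns=list(samples))
    rt_half = rt_window / 2.0
    for name, table in samples.items():
        if table is None:
            raise ValueError(f"sample stream missing: {name}")
        if "modified_sequence" in table.columns:
            keyed = table.copy()
            keyed.index = [
                transition_id(
                    r.modified_sequence,
                    int(r.prec_z),
                    r.slot,
                    int(getattr(r, "frg_z", 1)),
                )
                for r in keyed.itertuples()
            ]
            keyed = keyed.groupby(level=0)["intensity"].sum()
            common = keyed.index.intersection(data.index)
            data.loc[common, name] = keyed.loc[common]
        elif {"mz", "rt_min", "intensity"}.issubset(table.columns):
            for rec, tid in zip(lib.records, ids):
                widx = scheme.assign(rec.q1) if scheme is not None else None
                data.loc[tid, name] = _xic_sum(
                    table, rec.q3, rec.rt, rt_half, xic_ppm, widx
                )
        else:
            raise ValueError(
                f"sample {name!r}: unrecognised columns {list(table.columns)}"
            )
    return AbundanceMatrix(data=data, level="transition", meta=meta)


def rollup(
    m: AbundanceMatrix, k: int = DEFAULT_TOP_K
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Roll transitions up to peptide-precursor and protein intensities.

    Peptide-precursor intensity is the sum of its k highest
    library-intensity transitions; protein intensity sums its peptide
    precursors.  A peptide shared between several proteins (``;``-joined
    accessions) contributes fully to every parent.
    """
    if m.level != "transition" or m.meta is None:
        raise ValueError("rollup expects a transition-level matrix with metadata")
    meta = m.meta
    pep_rows: dict[str, np.ndarray] = {}
    pep_meta_rows: list[dict] = []
    for (mod_seq, z), idx in meta.groupby(
        ["modified_sequence", "prec_z"], sort=False
    ).groups.items():
        sub = meta.loc[idx].sort_values(
            ["library_intensity", "slot"], ascending=[False, True]
        )
        top = sub.index[:k]
        pid = f"{mod_seq}/{z}"
        pep_rows[pid] = m.data.loc[top].sum(axis=0).to_numpy()
        pep_meta_rows.append(
            {
                "id": pid,
                "modified_sequence": mod_seq,
                "stripped_sequence": sub["stripped_sequence"].iloc[0],
                "prec_z": z,
                "protein": sub["protein"].iloc[0],
            }
        )
    pep_meta = pd.DataFrame(pep_meta_rows).set_index("id")
    pep_data = pd.DataFrame.from_dict(
        pep_rows, orient="index", columns=m.samples
    ).loc[pep_meta.index]
    peptides = AbundanceMatrix(data=pep_data, level="peptide", meta=pep_meta)

    prot_rows: dict[str, np.ndarray] = {}
    for pid, row in pep_meta.iterrows():
        for accession in str(row["protein"]).split(";"):
            accession = accession.strip()
            vals = pep_data.loc[pid].to_numpy()
            if accession in prot_rows:
                prot_rows[accession] = prot_rows[accession] + vals
            else:
                prot_rows[accession] = vals.copy()
    prot_data = pd.DataFrame.from_dict(
        prot_rows, orient="index", columns=m.samples
    )
    proteins = AbundanceMatrix(data=prot_data, level="protein")
    return peptides, proteins


def normalize_to_reference(m: AbundanceMatrix, reference: str) -> AbundanceMatrix:
    """Divide every protein's intensity by a reference protein per sample."""
    if reference not in m.data.index:
        raise ValueError(f"reference protein {reference!r} not in matrix")
    ref = m.data.loc[reference]
    zero = ref[ref <= 0]
    if len(zero):
        raise ValueError(
            f"reference {reference!r} has zero intensity in sample(s): "
            + ", ".join(map(str, zero.index))
        )
    return AbundanceMatrix(data=m.data.div(ref, axis=1), level=m.level, meta=m.meta)


def normalize_total(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample column by its total summed intensity."""
    totals = m.data.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index
        raise ValueError(f"all-zero sample column(s): {', '.join(map(str, bad))}")
    return AbundanceMatrix(data=m.data.div(totals, axis=1), level=m.level, meta=m.meta)


@dataclass
class GlycoformProfile:
    """Per-family glycoform relative abundances.

    ``fractions`` is indexed by (family, glycoform) with one column per
    sample; within a family and sample the fractions sum to 1, or are all
    NaN when nothing in the family was detected in that sample.
    """

    fractions: pd.DataFrame
    families: dict[str, list[str]] = field(default_factory=dict)


def _split_glycoform(modified_sequence: str) -> tuple[str, str]:
    """Split 'PEPTIDE[Hex6]' into the peptide part and glycan label."""
    if modified_sequence.endswith("]") and "[" in modified_sequence:
        base, glycan = modified_sequence.rsplit("[", 1)
        return base, glycan[:-1]
    return modified_sequence, "unmodified"


def glycoform_fractions(
    peptides: AbundanceMatrix,
    grouping: dict[str, str] | None = None,
) -> GlycoformProfile:
    """Site-specific glycoform relative abundances.

    Charge states of one glycoform are summed first; each glycoform's
    fraction is its share of the summed intensity of all detected forms
    (including the unmodified peptide) of the same site-peptide family in
    that sample.  ``grouping`` maps stripped sequences to a family id and
    is how ragged cleavage variants of one site are pooled; ungrouped
    sequences form singleton families.
    """
    if peptides.level != "peptide" or peptides.meta is None:
        raise ValueError("glycoform_fractions expects a peptide-level matrix")
    meta = peptides.meta
    grouping = grouping or {}

    rows: dict[tuple[str, str], np.ndarray] = {}
    for pid, mrow in meta.iterrows():
        _, glycan = _split_glycoform(mrow["modified_sequence"])
        family = grouping.get(mrow["stripped_sequence"], mrow["stripped_sequence"])
        key = (family, glycan)
        vals = peptides.data.loc[pid].to_numpy(dtype=float)
        rows[key] = rows.get(key, 0.0) + vals

    index = pd.MultiIndex.from_tuples(rows.keys(), names=["family", "glycoform"])
    summed = pd.DataFrame(
        np.vstack(list(rows.values())), index=index, columns=peptides.samples
    )
    fractions = summed.copy()
    families: dict[str, list[str]] = {}
    for family, sub in summed.groupby(level="family", sort=False):
        totals = sub.sum(axis=0)
        frac = sub.div(totals.where(totals > 0), axis=1)  # all-zero -> NaN
        fractions.loc[sub.index] = frac
        families[family] = [g for _, g in sub.index]
    return GlycoformProfile(fractions=fractions, families=families)
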