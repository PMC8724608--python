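"""Identification-report parsing and SWATH/DIA ion-library construction.

The identification report is a documented tab-separated dialect carrying
what a search engine's per-PSM debug export contains: one row per matched
fragment ion, grouped by scan, with the peptide, its modifications, the
glycan composition, charge, score, retention time and per-fragment
observations.  Columns::

    scan  peptide  mods  glycan  linkage  site  protein  z  observed_mz
    score  rt_min  frag_series  frag_index  frag_remainder  frag_z
    frag_intensity

``mods`` is ``pos:delta:label`` triples joined by ``;`` (empty for none);
``frag_series`` is ``b``/``y``/``Y``; ``frag_remainder`` is a glycan
composition string (empty = bare backbone fragment; for Y rows it is
implied by the Y number and ignored).

The output library uses the 14-column PeakView-style transition list; the
``isotype`` column carries the slot label (a/b/c/y repurposing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .chem import (
    GlycanComposition,
    Glycopeptide,
    ModifiedPeptide,
    Modification,
    parse_glycan,
    precursor_mz,
)
from .fragments import allocate_slot, fragment_neutral_mass

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentObservation",
    "PsmRecord",
    "TransitionRecord",
    "IonLibrary",
    "ReportParseResult",
    "read_id_report",
    "build_library",
    "write_peakview",
    "read_peakview",
    "merge_libraries",
]

REPORT_COLUMNS = [
    "scan",
    "peptide",
    "mods",
    "glycan",
    "linkage",
    "site",
    "protein",
    "z",
    "observed_mz",
    "score",
    "rt_min",
    "frag_series",
    "frag_index",
    "frag_remainder",
    "frag_z",
    "frag_intensity",
]

PEAKVIEW_COLUMNS = [
    "Q1",
    "Q3",
    "RT_detected",
    "protein_name",
    "isotype",
    "relative_intensity",
    "stripped_sequence",
    "modification_sequence",
    "prec_z",
    "frg_type",
    "frg_z",
    "frg_nr",
    "shared",
    "decoy",
]


@dataclass(frozen=True)
class FragmentObservation:
    series: str  # b / y / Y
    index: int
    remainder: GlycanComposition
    charge: int
    intensity: float


@dataclass
class PsmRecord:
    """One identified (glyco)peptide-spectrum match with its fragments."""

    scan: int
    peptide: ModifiedPeptide
    glycan: GlycanComposition
    linkage: str | None  # None for plain peptides
    site: int | None
    observed_mz: float
    charge: int
    score: float
    rt: float  # minutes
    fragments: list[FragmentObservation] = field(default_factory=list)

    def glycopeptide(self) -> Glycopeptide:
        if self.linkage is None:
            raise ValueError("plain peptide PSM has no glycopeptide view")
        return Glycopeptide(
            peptide=self.peptide,
            glycan=self.glycan,
            linkage=self.linkage,
            site=self.site,
        )

    def modified_sequence(self) -> str:
        base = self.peptide.annotated()
        return f"{base}[{self.glycan}]" if self.glycan else base


@dataclass(frozen=True)
class TransitionRecord:
    q1: float
    q3: float
    rt: float
    protein: str
    slot: str
    relative_intensity: float
    stripped_sequence: str
    modified_sequence: str
    precursor_charge: int
    fragment_charge: int
    decoy: bool = False
    shared: bool = False

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (
            self.modified_sequence,
            self.precursor_charge,
            self.slot,
            self.fragment_charge,
        )


@dataclass
class IonLibrary:
    """A deduplicated set of transitions.

    Invariant: no two records share (modified_sequence, precursor_charge,
    slot, fragment_charge).
    """

    records: list[TransitionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate transition key {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IonLibrary):
            return NotImplemented
        return sorted(self.records, key=lambda r: r.key) == sorted(
            other.records, key=lambda r: r.key
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "Q1": r.q1,
                "Q3": r.q3,
                "RT_detected": r.rt,
                "protein_name": r.protein,
                "isotype": r.slot,
                "relative_intensity": r.relative_intensity,
                "stripped_sequence": r.stripped_sequence,
                "modification_sequence": r.modified_sequence,
                "prec_z": r.precursor_charge,
                "frg_type": r.slot[0],
                "frg_z": r.fragment_charge,
                "frg_nr": int(r.slot[1:]),
                "shared": r.shared,
                "decoy": r.decoy,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=PEAKVIEW_COLUMNS)


@dataclass
class ReportParseResult:
    psms: list[PsmRecord]
    rejects: pd.DataFrame  # offending rows with a "reason" column


def _parse_mods(text: str) -> tuple[Modification, ...]:
    if not text or pd.isna(text):
        return ()
    out = []
    for token in str(text).split(";"):
        pos, delta, label = token.split(":")
        out.append(Modification(int(pos), float(delta), label))
    return tuple(out)


def read_id_report(path: str) -> ReportParseResult:
    """Parse an identification report into PSM records.

    Rows are grouped by scan number; malformed row-groups go to the
    rejects table with a reason instead of being silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    psms: list[PsmRecord] = []
    reject_rows: list[dict] = []
    for scan, group in df.groupby("scan", sort=False):
        first = group.iloc[0]
        try:
            linkage = first["linkage"] or None
            site = int(first["site"]) if first["site"] else None
            peptide = ModifiedPeptide(
                sequence=first["peptide"],
                mods=_parse_mods(first["mods"]),
                protein_accession=first["protein"],
            )
            glycan = parse_glycan(first["glycan"])
            fragments = []
            for _, row in group.iterrows():
                series = row["frag_series"]
                index = int(row["frag_index"])
                if series == "Y":
                    remainder = GlycanComposition(hexnac=index)
                else:
                    remainder = parse_glycan(row["frag_remainder"])
                fragments.append(
                    FragmentObservation(
                        series=series,
                        index=index,
                        remainder=remainder,
                        charge=int(row["frag_z"]),
                        intensity=float(row["frag_intensity"]),
                    )
                )
            psm = PsmRecord(
                scan=int(scan),
                peptide=peptide,
                glycan=glycan,
                linkage=linkage,
                site=site,
                observed_mz=float(first["observed_mz"]),
                charge=int(first["z"]),
                score=float(first["score"]),
                rt=float(first["rt_min"]),
                fragments=fragments,
            )
            if psm.rt < 0:
                raise ValueError("negative retention time")
            psms.append(psm)
        except (ValueError, KeyError) as exc:
            for _, row in group.iterrows():
                reject_rows.append({**row.to_dict(), "reason": str(exc)})
    rejects = pd.DataFrame(reject_rows, columns=REPORT_COLUMNS + ["reason"])
    return ReportParseResult(psms=psms, rejects=rejects)


def _round5(x: float) -> float:
    return round(float(x), 5)


def build_library(
    psms: list[PsmRecord],
    validated_scans: set[int] | None = None,
    max_transitions: int | None = None,
) -> IonLibrary:
    """Build a transition library from (validated) PSMs.

    Per unique (modified sequence, precursor charge) the best-scoring PSM
    is kept (ties break to the lowest scan number).  Q1 and Q3 are
    theoretical m/z values; fragments whose slot class is excluded are
    dropped; slot-key collisions keep the higher-intensity fragment and
    are logged.  ``max_transitions`` optionally truncates each precursor
    to its most intense transitions (selection to the usual six per
    peptide normally happens at quantification instead).
    """
    if validated_scans is not None:
        present = {p.scan for p in psms}
        for scan in sorted(validated_scans - present):
            logger.warning("validated scan %d absent from report; skipped", scan)
        psms = [p for p in psms if p.scan in validated_scans]

    best: dict[tuple[str, int], PsmRecord] = {}
    for psm in psms:
        key = (psm.modified_sequence(), psm.charge)
        cur = best.get(key)
        if (
            cur is None
            or psm.score > cur.score
            or (psm.score == cur.score and psm.scan < cur.scan)
        ):
            best[key] = psm

    records: list[TransitionRecord] = []
    for (mod_seq, z), psm in best.items():
        neutral = psm.peptide.neutral_mass + psm.glycan.mass
        q1 = _round5(precursor_mz(neutral, z))
        gp = (
            psm.glycopeptide()
            if psm.linkage is not None
            else Glycopeptide(psm.peptide, GlycanComposition(), "O")
        )
        chosen: dict[tuple[str, int, str, int], TransitionRecord] = {}
        for frag in psm.fragments:
            slot = allocate_slot(
                frag.series, frag.index, frag.remainder, psm.glycan
            )
            if slot is None:
                logger.debug(
                    "excluded %s%d+HexNAc1 (position <= 3) for %s",
                    frag.series,
                    frag.index,
                    mod_seq,
                )
                continue
            mass = fragment_neutral_mass(gp, frag.series, frag.index, frag.remainder)
            rec = TransitionRecord(
                q1=q1,
                q3=_round5(precursor_mz(mass, frag.charge)),
                rt=_round5(psm.rt),
                protein=psm.peptide.protein_accession,
                slot=slot,
                relative_intensity=_round5(frag.intensity),
                stripped_sequence=psm.peptide.stripped,
                modified_sequence=mod_seq,
                precursor_charge=z,
                fragment_charge=frag.charge,
            )
            prev = chosen.get(rec.key)
            if prev is not None:
                logger.info(
                    "slot collision %s for %s (z=%d): keeping higher intensity",
                    slot,
                    mod_seq,
                    z,
                )
                if rec.relative_intensity <= prev.relative_intensity:
                    continue
            chosen[rec.key] = rec
        recs = sorted(
            chosen.values(), key=lambda r: -r.relative_intensity
        )
        if max_transitions is not None:
            recs = recs[:max_transitions]
        records.extend(recs)
    return IonLibrary(records=records)


def write_peakview(lib: IonLibrary, path: str) -> None:
    """Write the 14-column tab-delimited PeakView-style transition list."""
    df = lib.to_dataframe()
    for col in ("Q1", "Q3", "RT_detected", "relative_intensity"):
        df[col] = df[col].map(lambda x: f"{x:.5f}")
    for col in ("shared", "decoy"):
        df[col] = df[col].map(lambda b: "TRUE" if b else "FALSE")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_peakview(path: str) -> IonLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PEAKVIEW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"not a PeakView library, missing: {', '.join(missing)}")
    records = [
        TransitionRecord(
            q1=float(row["Q1"]),
            q3=float(row["Q3"]),
            rt=float(row["RT_detected"]),
            protein=row["protein_name"],
            slot=row["isotype"],
            relative_intensity=float(row["relative_intensity"]),
            stripped_sequence=row["stripped_sequence"],
            modified_sequence=row["modification_sequence"],
            precursor_charge=int(row["prec_z"]),
            fragment_charge=int(row["frg_z"]),
            shared=row["shared"] == "TRUE",
            decoy=row["decoy"] == "TRUE",
        )
        for _, row in df.iterrows()
    ]
    return IonLibrary(records=records)


def merge_libraries(glyco: IonLibrary, peptide: IonLibrary) -> IonLibrary:
    """Union of a glycopeptide and a peptide-centric library.

    On a duplicate transition key the glycopeptide record wins; conflicts
    are logged.
    """
    merged = {r.key: r for r in peptide.records}
    conflicts = 0
    for r in glyco.records:
        if r.key in merged:
            conflicts += 1
            logger.info("merge conflict on %s: glycopeptide record kept", r.key)
        merged[r.key] = r
    if conflicts:
        logger.warning("%d merge conflict(s); glycopeptide records kept", conflicts)
    return IonLibrary(records=list(merged.values()))
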