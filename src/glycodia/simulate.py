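"""Ground-truthed synthetic glycoproteomics data.

The generator emulates the glycoproteome structure of sparkling wine:
yeast O-glycopeptides carrying ladders of one to nine hexoses, grape
O-glycopeptides on hydroxyproline carrying one to six pentoses, grape
N-glycopeptides with HexNAc/dHex/Pent-containing compositions, and
unglycosylated reference peptides (trypsin) for normalization.  It emits
the three artefacts the pipeline consumes — identification reports,
centroided MS/MS peak lists, and per-sample DIA transition tables —
together with ground-truth tables computed by independent plain
arithmetic, so every downstream stage can be checked against planted
values.

Everything is driven by one integer seed through
:func:`numpy.random.default_rng`; identical seed and config give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import (
    GlycanComposition,
    Glycopeptide,
    ModifiedPeptide,
    parse_glycan,
    precursor_mz,
)
from .fragments import enumerate_fragments, oxonium_table
from .library import REPORT_COLUMNS, IonLibrary
from .validation import SpectrumPeaks

__all__ = [
    "PeptideSim",
    "ProteinSim",
    "Effect",
    "SimulationConfig",
    "default_config",
    "simulate_identifications",
    "simulate_spectra",
    "simulate_dia",
    "simulate_null_fractions",
    "PlantedSpectrum",
    "SimulatedDia",
]


@dataclass(frozen=True)
class PeptideSim:
    """One (glyco)site-bearing peptide and its glycoform ladder.

    ``glycans`` lists composition strings; the empty string is the
    unmodified peptide.  ``glycan_weights`` sets the true relative
    abundance profile of the ladder (normalised internally); by default
    larger glycoforms are progressively less abundant, the typical shape
    of an O-glycan elongation ladder.
    """

    sequence: str
    linkage: str | None  # None = plain peptide
    site: int | None
    glycans: tuple[str, ...]
    rt: float  # minutes
    base_intensity: float = 1e5
    charges: tuple[int, ...] = (2, 3)
    charge_shares: tuple[float, ...] = (0.6, 0.4)
    glycan_weights: tuple[float, ...] | None = None

    def weights(self) -> np.ndarray:
        if self.glycan_weights is not None:
            w = np.asarray(self.glycan_weights, dtype=float)
        else:
            w = 1.0 / (1.0 + np.arange(len(self.glycans)))
        return w / w.sum()


@dataclass(frozen=True)
class ProteinSim:
    accession: str
    peptides: tuple[PeptideSim, ...]


@dataclass(frozen=True)
class Effect:
    """A planted fold change on one analyte in one condition."""

    stripped_sequence: str
    glycan: str | None  # None applies to every glycoform of the peptide
    condition: str
    fold: float


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    proteins: tuple[ProteinSim, ...] = ()
    conditions: tuple[str, ...] = ("A", "B")
    n_replicates: int = 3
    cv: float = 0.10  # multiplicative intensity coefficient of variation
    ppm_mean: float = -15.0  # precursor mass-error distribution (TripleTOF-like)
    ppm_sd: float = 3.0
    noise_peaks: int = 20
    dropout: float = 0.0
    effects: tuple[Effect, ...] = ()


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard simulated glycoproteome.

    Three glycoprotein families mirror the dominant analytes of sparkling
    wine — a seripauperin O-glycopeptide with a Hex1-9 ladder, the shared
    seripauperin peptide with unmodified + Hex1-4 forms, a grape
    hydroxyproline-rich peptide with Pent1-6, and a grape N-glycopeptide —
    plus trypsin reference peptides.
    """
    proteins = (
        ProteinSim(
            accession="P43575",
            peptides=(
                PeptideSim(
                    sequence="VITGVPWYSSR",
                    linkage="O",
                    site=9,
                    glycans=tuple(f"Hex{i}" for i in range(1, 10)),
                    rt=10.0,
                    base_intensity=2e5,
                ),
            ),
        ),
        ProteinSim(
            accession="PAU1-24",
            peptides=(
                PeptideSim(
                    sequence="VNLVELGVYVSDIR",
                    linkage="O",
                    site=11,
                    glycans=("",) + tuple(f"Hex{i}" for i in range(1, 5)),
                    rt=12.0,
                    base_intensity=1.5e5,
                ),
            ),
        ),
        ProteinSim(
            accession="NP_001268136.1",
            peptides=(
                PeptideSim(
                    sequence="VVRPppTpKPpT",
                    linkage="O",
                    site=5,
                    glycans=tuple(f"Pent{i}" for i in range(1, 7)),
                    rt=8.0,
                    base_intensity=1e5,
                ),
            ),
        ),
        ProteinSim(
            accession="XP_002265534.1",
            peptides=(
                PeptideSim(
                    sequence="SNATLGR",
                    linkage="N",
                    site=2,
                    glycans=(
                        "HexNAc1",
                        "HexNAc2Hex3dHex1Pent1",
                        "HexNAc3Hex3dHex1Pent1",
                    ),
                    rt=14.0,
                    base_intensity=8e4,
                ),
            ),
        ),
        ProteinSim(
            accession="trypsin",
            peptides=(
                PeptideSim(
                    sequence="VATVSLPR",
                    linkage=None,
                    site=None,
                    glycans=("",),
                    rt=6.0,
                    base_intensity=5e5,
                    charges=(2,),
                    charge_shares=(1.0,),
                ),
                PeptideSim(
                    sequence="LSSPATLNSR",
                    linkage=None,
                    site=None,
                    glycans=("",),
                    rt=7.0,
                    base_intensity=4e5,
                    charges=(2,),
                    charge_shares=(1.0,),
                ),
            ),
        ),
    )
    return replace(SimulationConfig(seed=seed, proteins=proteins), **overrides)


def _iter_glycopeptides(cfg: SimulationConfig):
    """Yield (protein, peptide_sim, glycan_str, Glycopeptide, weight)."""
    for prot in cfg.proteins:
        for pep in prot.peptides:
            weights = pep.weights()
            for glycan_str, w in zip(pep.glycans, weights):
                glycan = parse_glycan(glycan_str)
                peptide = ModifiedPeptide(
                    sequence=pep.sequence, protein_accession=prot.accession
                )
                gp = Glycopeptide(
                    peptide=peptide,
                    glycan=glycan,
                    linkage=pep.linkage or "O",
                    site=pep.site if glycan else None,
                )
                yield prot, pep, glycan_str, gp, w


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with the requested CV and unit mean."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_identifications(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a synthetic identification report plus its ground truth.

    One PSM per glycopeptide x charge: the observed precursor m/z is the
    theoretical value perturbed by a drawn ppm error, fragments come from
    the theoretical fragment model with log-normal reference intensities.
    Returns (report, truth); the report follows the documented TSV
    dialect, the truth table carries the planted theoretical Q1 and the
    drawn ppm error per scan.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    scan = 1000
    for prot, pep, glycan_str, gp, _w in _iter_glycopeptides(cfg):
        for z in pep.charges:
            theo = precursor_mz(gp.neutral_mass, z)
            ppm = (
                rng.normal(cfg.ppm_mean, cfg.ppm_sd) if cfg.ppm_sd > 0 else cfg.ppm_mean
            )
            observed = theo * (1.0 + ppm * 1e-6)
            score = float(rng.uniform(200.0, 600.0))
            rt = pep.rt + float(rng.normal(0.0, 0.05)) if cfg.ppm_sd > 0 else pep.rt
            frags = [
                f
                for f in enumerate_fragments(gp)
                if f.slot is not None and f.charge == 1
            ]
            for f in frags:
                intensity = float(
                    1000.0 * _lognormal_factor(rng, 0.5)
                )
                rows.append(
                    {
                        "scan": scan,
                        "peptide": pep.sequence,
                        "mods": "",
                        "glycan": glycan_str,
                        "linkage": pep.linkage or "",
                        "site": pep.site if (pep.site and glycan_str) else "",
                        "protein": prot.accession,
                        "z": z,
                        "observed_mz": f"{observed:.6f}",
                        "score": f"{score:.1f}",
                        "rt_min": f"{rt:.3f}",
                        "frag_series": f.series,
                        "frag_index": f.index,
                        "frag_remainder": str(f.glycan_remainder)
                        if f.series != "Y"
                        else "",
                        "frag_z": f.charge,
                        "frag_intensity": f"{intensity:.2f}",
                    }
                )
            truth_rows.append(
                {
                    "scan": scan,
                    "peptide": pep.sequence,
                    "glycan": glycan_str,
                    "z": z,
                    "theoretical_q1": theo,
                    "ppm_error": ppm,
                    "protein": prot.accession,
                }
            )
            scan += 1
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return report, truth


@dataclass
class PlantedSpectrum:
    """A synthetic spectrum with a record of exactly what was planted."""

    glycopeptide: Glycopeptide
    spectrum: SpectrumPeaks
    planted_oxonium: int  # how many of the required oxonium ions are present
    required_oxonium: int
    planted_y_anchor: bool  # Y0 (O-linked) / Y1 (N-linked)
    planted_b: int
    planted_y: int


def simulate_spectra(
    cfg: SimulationConfig,
    n: int | None = None,
    drop_oxonium_fraction: float = 0.3,
    drop_anchor_fraction: float = 0.3,
) -> list[PlantedSpectrum]:
    """Plant spectra with randomised, fully known fragment evidence.

    Each spectrum carries a random subset of required oxonium ions, the
    Y0/Y1 anchor with the configured drop probability, random numbers of
    b and y backbone ions, and uniform noise peaks kept at least 200 ppm
    away from every theoretical target.  Noise never creates spurious
    matches, but distinct theoretical targets can genuinely share an m/z
    (e.g. the 1+ b1 ion coincides with the 2+ b2 ion when the first two
    residues are identical), so detected counts can exceed the planted
    counts; checkers should recount matched classes rather than assume
    equality.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pool = [
        (gp, pep) for _prot, pep, g, gp, _w in _iter_glycopeptides(cfg) if g
    ]
    out: list[PlantedSpectrum] = []
    count = n if n is not None else len(pool)
    for i in range(count):
        gp, pep = pool[i % len(pool)]
        frags = enumerate_fragments(gp)
        required = [o.mz for o in oxonium_table(gp.glycan, gp.linkage) if o.required]
        anchor_index = 0 if gp.linkage == "O" else 1
        anchor_mz = next(
            f.mz for f in frags if f.series == "Y" and f.index == anchor_index and f.charge == 1
        )
        b_pool = sorted(
            {f.index for f in frags if f.series == "b" and not f.glycan_remainder}
        )
        y_pool = sorted(
            {f.index for f in frags if f.series == "y" and not f.glycan_remainder}
        )

        n_ox = (
            len(required)
            if rng.random() > drop_oxonium_fraction
            else int(rng.integers(0, max(1, len(required))))
        )
        has_anchor = rng.random() > drop_anchor_fraction
        n_b = int(rng.integers(0, len(b_pool) + 1))
        n_y = int(rng.integers(0, len(y_pool) + 1))

        targets: list[float] = list(rng.choice(required, size=n_ox, replace=False))
        if has_anchor:
            targets.append(anchor_mz)
        frag_mz = {
            (f.series, f.index): f.mz
            for f in frags
            if f.charge == 1 and not f.glycan_remainder and f.series != "Y"
        }
        for idx in rng.choice(b_pool, size=n_b, replace=False):
            targets.append(frag_mz[("b", int(idx))])
        for idx in rng.choice(y_pool, size=n_y, replace=False):
            targets.append(frag_mz[("y", int(idx))])

        all_theoretical = (
            [f.mz for f in frags]
            + [o.mz for o in oxonium_table(gp.glycan, gp.linkage)]
        )
        noise = []
        while len(noise) < cfg.noise_peaks:
            mz = float(rng.uniform(150.0, 2000.0))
            if all(abs(mz - t) / t > 200e-6 for t in all_theoretical):
                noise.append(mz)
        mzs = np.array(targets + noise)
        intensities = rng.uniform(50.0, 5000.0, size=mzs.size)
        spectrum = SpectrumPeaks(
            scan=2000 + i,
            rt=pep.rt,
            precursor_mz=precursor_mz(gp.neutral_mass, pep.charges[0]),
            precursor_z=pep.charges[0],
            mz=mzs,
            intensity=intensities,
        )
        out.append(
            PlantedSpectrum(
                glycopeptide=gp,
                spectrum=spectrum,
                planted_oxonium=n_ox,
                required_oxonium=len(required),
                planted_y_anchor=has_anchor,
                planted_b=n_b,
                planted_y=n_y,
            )
        )
    return out


@dataclass
class SimulatedDia:
    """Per-sample transition tables plus independently computed truth."""

    samples: dict[str, pd.DataFrame]
    design: dict[str, list[str]]  # condition -> sample names
    truth_transitions: pd.DataFrame  # per condition, noiseless
    truth_peptides: pd.DataFrame
    truth_proteins: pd.DataFrame
    truth_fractions: pd.DataFrame  # (family, glycoform) x condition


def _effect_fold(cfg: SimulationConfig, stripped: str, glycan: str, condition: str) -> float:
    fold = 1.0
    for e in cfg.effects:
        if (
            e.condition == condition
            and e.stripped_sequence == stripped
            and (e.glycan is None or e.glycan == glycan)
        ):
            fold *= e.fold
    return fold


def simulate_dia(
    cfg: SimulationConfig,
    lib: IonLibrary,
    k: int = 6,
    grouping: dict[str, str] | None = None,
) -> SimulatedDia:
    """Simulate DIA transition intensities for every library record.

    The true intensity of a precursor in a condition is its configured
    base intensity x glycoform weight x charge share x planted fold
    change; a transition receives that intensity multiplied by its share
    of the precursor's library reference intensity.  Replicate values are
    truth x lognormal(CV), with zeros injected at the dropout rate.

    The returned truth tables are computed here by direct summation
    (top-k by library intensity for peptides, accession sums for
    proteins, family renormalisation for glycoform fractions) without
    calling the quantification module, so they are an independent oracle
    for it.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    grouping = grouping or {}

    # Index library transitions per precursor.
    by_precursor: dict[tuple[str, int], list] = {}
    for rec in lib.records:
        by_precursor.setdefault(
            (rec.modified_sequence, rec.precursor_charge), []
        ).append(rec)

    # Planted precursor truth per condition.
    info: dict[tuple[str, int], dict] = {}
    for prot, pep, glycan_str, gp, w in _iter_glycopeptides(cfg):
        mod_seq = gp.modified_sequence()
        for z, share in zip(pep.charges, pep.charge_shares):
            if (mod_seq, z) not in by_precursor:
                continue
            info[(mod_seq, z)] = {
                "stripped": pep.sequence.upper(),
                "glycan": glycan_str or "unmodified",
                "protein": prot.accession,
                "base": pep.base_intensity * w * share,
            }

    sample_names: dict[str, list[str]] = {
        cond: [f"{cond}{r + 1}" for r in range(cfg.n_replicates)]
        for cond in cfg.conditions
    }

    tr_truth_rows = []
    sample_rows: dict[str, list[dict]] = {
        s: [] for names in sample_names.values() for s in names
    }
    pep_truth: dict[tuple[str, int], dict[str, float]] = {}
    for (mod_seq, z), recs in by_precursor.items():
        meta = info.get((mod_seq, z))
        if meta is None:
            continue
        rel = np.array([r.relative_intensity for r in recs], dtype=float)
        shares = rel / rel.sum() if rel.sum() > 0 else np.full(len(recs), 1.0 / len(recs))
        order = np.argsort(-rel, kind="stable")
        top = set(order[:k])
        for cond in cfg.conditions:
            fold = _effect_fold(cfg, meta["stripped"], meta["glycan"], cond)
            precursor_truth = meta["base"] * fold
            tr_values = precursor_truth * shares
            pep_truth.setdefault((mod_seq, z), {})[cond] = float(
                sum(tr_values[i] for i in top)
            )
            for i, rec in enumerate(recs):
                tr_truth_rows.append(
                    {
                        "modified_sequence": mod_seq,
                        "prec_z": z,
                        "slot": rec.slot,
                        "frg_z": rec.fragment_charge,
                        "condition": cond,
                        "intensity": tr_values[i],
                    }
                )
                for s in sample_names[cond]:
                    value = tr_values[i] * float(_lognormal_factor(rng, cfg.cv))
                    if cfg.dropout > 0 and rng.random() < cfg.dropout:
                        value = 0.0
                    sample_rows[s].append(
                        {
                            "modified_sequence": mod_seq,
                            "prec_z": z,
                            "slot": rec.slot,
                            "frg_z": rec.fragment_charge,
                            "intensity": value,
                        }
                    )

    samples = {
        s: pd.DataFrame(
            rows,
            columns=["modified_sequence", "prec_z", "slot", "frg_z", "intensity"],
        )
        for s, rows in sample_rows.items()
    }
    truth_transitions = pd.DataFrame(tr_truth_rows)

    pep_rows = []
    for (mod_seq, z), by_cond in pep_truth.items():
        meta = info[(mod_seq, z)]
        pep_rows.append(
            {
                "modified_sequence": mod_seq,
                "prec_z": z,
                "stripped": meta["stripped"],
                "glycan": meta["glycan"],
                "protein": meta["protein"],
                **by_cond,
            }
        )
    truth_peptides = pd.DataFrame(pep_rows)

    conds = list(cfg.conditions)
    prot_acc = sorted({r["protein"] for r in pep_rows})
    truth_proteins = pd.DataFrame(0.0, index=prot_acc, columns=conds)
    for row in pep_rows:
        for acc in row["protein"].split(";"):
            for cond in conds:
                truth_proteins.loc[acc.strip(), cond] += row[cond]

    fam_rows: dict[tuple[str, str], np.ndarray] = {}
    for row in pep_rows:
        family = grouping.get(row["stripped"], row["stripped"])
        key = (family, row["glycan"])
        vals = np.array([row[c] for c in conds])
        fam_rows[key] = fam_rows.get(key, 0.0) + vals
    index = pd.MultiIndex.from_tuples(fam_rows.keys(), names=["family", "glycoform"])
    fam = pd.DataFrame(np.vstack(list(fam_rows.values())), index=index, columns=conds)
    truth_fractions = fam.copy()
    for family, sub in fam.groupby(level="family", sort=False):
        totals = sub.sum(axis=0)
        truth_fractions.loc[sub.index] = sub.div(totals.where(totals > 0), axis=1)

    return SimulatedDia(
        samples=samples,
        design=sample_names,
        truth_transitions=truth_transitions,
        truth_peptides=truth_peptides,
        truth_proteins=truth_proteins,
        truth_fractions=truth_fractions,
    )


def simulate_null_fractions(
    n_families: int,
    n_glycoforms: int,
    n_reps: int,
    cv: float,
    seed: int,
    conditions: tuple[str, str] = ("A", "B"),
):
    """Null glycoform-fraction data for calibration checks.

    Every family has the same true glycoform profile in both conditions;
    replicate intensities are truth x lognormal(CV) and renormalised per
    family, exactly the noise structure the DIA simulator uses.  Returns
    a :class:`~glycodia.quant.GlycoformProfile`.
    """
    from .quant import GlycoformProfile

    rng = np.random.default_rng(seed)
    samples = [f"{c}{r + 1}" for c in conditions for r in range(n_reps)]
    keys = []
    rows = []
    for f in range(n_families):
        base = rng.lognormal(mean=np.log(1e4), sigma=1.0, size=n_glycoforms)
        intensities = base[:, None] * _lognormal_factor(
            rng, cv, size=(n_glycoforms, len(samples))
        )
        fractions = intensities / intensities.sum(axis=0, keepdims=True)
        for g in range(n_glycoforms):
            keys.append((f"family{f}", f"glycoform{g}"))
            rows.append(fractions[g])
    index = pd.MultiIndex.from_tuples(keys, names=["family", "glycoform"])
    frame = pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    families = {
        f"family{f}": [f"glycoform{g}" for g in range(n_glycoforms)]
        for f in range(n_families)
    }
    return GlycoformProfile(fractions=frame, families=families)
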