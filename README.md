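# glycodia

Glycopeptide SWATH/DIA ion-library construction and site-specific
glycoform quantification.

## The problem

Intact glycopeptides are hard to quantify reproducibly. Data-dependent
acquisition (DDA) identifies them well — search engines match the
peptide backbone and glycan composition from MS/MS spectra — but its
stochastic precursor sampling makes run-to-run quantification noisy.
Data-independent acquisition (DIA/SWATH) fragments *everything* inside
a ladder of fixed isolation windows and quantifies analytes from
extracted ion chromatograms (XICs) of library transitions, but it needs
a transition library, and the standard peptide-centric library formats
have no vocabulary for glycopeptide fragment ions.

`glycodia` implements a complete workflow that bridges the two:

1. **Mass arithmetic** (`glycodia.chem`) — monoisotopic masses for
   peptides (including hydroxyproline, written in-sequence as lowercase
   `p`), glycan composition vectors over Hex/HexNAc/dHex/Pent, precursor
   *m/z* and ppm error, from a single fixed constants table.
2. **Fragment model** (`glycodia.fragments`) — theoretical b/y ions,
   glycopeptide Y ions (Y0 = bare peptide, Y1/Y2 = peptide + 1/2 core
   HexNAc), b/y ions retaining HexNAc₁ or the intact glycan, and
   diagnostic oxonium ions. Glyco-specific ions are repurposed into the
   fixed a/b/c/y slots of a PeakView-style library: Y0/Y1/Y2 → a1/a2/a3,
   b/y+HexNAc₁ at backbone positions ≥ 4 → a*N*, b/y+glycan → c*N*
   (positions 1–3 of the HexNAc class are excluded to keep a1–a3
   unambiguous).
3. **PSM validation** (`glycodia.validation`) — a deterministic rule
   engine encoding manual glycopeptide-acceptance criteria: required
   oxonium ions present (dHex/Pent exempt for N-glycans), the Y0
   (O-linked) or Y1 (N-linked) anchor plus ≥ 3 backbone ions, a
   fallback path when no Y anchor is seen, and a stricter path for
   Lys/Arg–Pro and N-ragged cleavage.
4. **Library builder** (`glycodia.library`) — parses a documented
   tab-separated identification-report dialect, keeps the best-scoring
   PSM per precursor, computes theoretical Q1/Q3, deduplicates
   transitions, merges with a peptide-centric library, and round-trips
   the 14-column PeakView-dialect TSV.
5. **DIA quantification** (`glycodia.quant`) — isolation-window schemes
   (e.g. 34 windows of 26 *m/z* with 1 *m/z* overlap across 400–1250),
   XIC transition quantification (±75 ppm, 6-min RT window), top-6
   transition rollup to peptide precursors and proteins, reference
   (trypsin) and total-abundance normalization, and site-specific
   glycoform relative abundances (each glycoform's share of the summed
   intensity of all forms of its peptide family across charge states).
6. **Statistics** (`glycodia.stats`) — per-analyte two-sided t-tests
   with log2 fold changes for proteins (α = 10⁻⁵, on log2 intensities)
   and glycoforms (α = 0.05, on fractions), and sample-level PCA.
7. **Synthetic data** (`glycodia.simulate`) — a seeded generator that
   emulates a wine-like glycoproteome (yeast O-glycopeptides with
   Hex₁–₉ ladders, grape hydroxyproline O-glycopeptides with Pent₁–₆,
   grape N-glycopeptides, trypsin reference peptides) and emits
   identification reports, planted MS/MS spectra and DIA transition
   tables together with independently computed ground truth.

## Worked example

The three best-characterised glycopeptides in the package's simulated
glycoproteome, at their observed charge states:

```python
from glycodia import (
    Glycopeptide, ModifiedPeptide, parse_glycan, precursor_mz, ppm_error,
)

for seq, glycan, site, z, observed in [
    ("VITGVPWYSSR", "Hex6", 9, 3, 746.3205),   # yeast Pau5, O-linked
    ("VNLVELGVYVSDIR", "Hex2", 11, 2, 950.4798),  # seripauperins, O-linked
    ("VVRPppTpKPpT", "Pent6", 5, 3, 714.6610),  # grape Hyp-rich, O-linked
]:
    gp = Glycopeptide(ModifiedPeptide(seq), parse_glycan(glycan), "O", site=site)
    theo = precursor_mz(gp.neutral_mass, z)
    print(f"{seq}+{glycan} {z}+: theoretical {theo:.5f}, "
          f"observed {observed} -> {ppm_error(observed, theo):+.2f} ppm")
```

prints

```
VITGVPWYSSR+Hex6 3+: theoretical 746.33330, observed 746.3205 -> -17.15 ppm
VNLVELGVYVSDIR+Hex2 2+: theoretical 950.49348, observed 950.4798 -> -14.40 ppm
VVRPppTpKPpT+Pent6 3+: theoretical 714.67013, observed 714.661 -> -12.78 ppm
```

i.e. each observation sits 12–18 ppm below its theoretical precursor
*m/z*, the systematic under-measurement typical of an uncalibrated
TripleTOF acquisition.

The full pipeline, from nothing to differential glycoforms:

```sh
glycodia simulate --seed 3 --out sim/
glycodia build-library --ids sim/id_report.tsv --out library.tsv
glycodia quantify --library library.tsv --samples sim/samples/*.tsv \
    --reference trypsin --out-prefix quant
glycodia contrast --matrix quant.glycoforms.tsv --level glycoform \
    --groups design.tsv --out contrasts.tsv
```

`quant.glycoforms.tsv` holds per-family glycoform fractions that sum to
1 per sample; `contrasts.tsv` adds log2 fold changes, p-values and an
informational Benjamini–Hochberg column.

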