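# Methods

This note documents the models, parameters and design choices behind
`glycodia`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, and
what the synthetic tests do and do not demonstrate.

## Mass model

All masses are monoisotopic and come from one constants table
(`glycodia.chem`, exportable with `glycodia constants`): 20 amino-acid
residue masses to five decimals, hydroxyproline as lowercase `p`
(Pro + 15.99491 Da), water 18.010565 Da, proton 1.0072765 Da, and the
four monosaccharide residue masses Hex 162.05282, HexNAc 203.07937,
dHex 146.05791, Pent 132.04226 Da. Five-decimal precision keeps ppm
calculations stable to the second decimal for precursors up to a few
kDa; the table is deliberately frozen in one module so every Q1/Q3 and
ppm value in the package is reproducible bit-for-bit. Ionisation is
protonation only: m/z = (M + z·1.0072765)/z. Isotope envelopes, average
masses and charge-state deconvolution are out of scope.

Modifications are positional (1-based index, delta, label) triples;
standard deltas are provided for deamidation (+0.98402), oxidation
(+15.99491) and dehydro (−1.00783). Hydroxyproline is the one
modification encoded in-sequence, because it is the attachment residue
of plant O-glycans and reads naturally in the display convention
(`VVRPppTpKPpT`). Ile/Leu are distinct letters with identical mass;
sequences are stored as reported.

The ppm convention is (observed − theoretical)/theoretical × 10⁶, so an
instrument that under-measures gives negative errors.

## Fragment model and slot allocation

For a glycopeptide the enumerator emits, at 1+ and 2+:

- plain b/y ions at every backbone position (glycan fully lost, the
  dominant behaviour of labile O-glycans under CID);
- Y0 (bare peptide) always, plus Y1/Y2 (peptide + HexNAc₁/₂, the
  chitobiose core stubs) for N-linked glycans;
- when the glycosite is localised: site-containing b/y ions retaining
  HexNAc₁ (N-linked) and site-containing b/y ions retaining the intact
  glycan (both linkages).

Partial-loss ladders on backbone fragments are not modelled beyond the
explicit HexNAc₁ class. Fragment charges are restricted to 1+/2+,
typical of QTOF MS2 transitions.

Slot allocation maps each fragment into the fixed a/b/c/y vocabulary of
a PeakView-style transition list: Y0/Y1/Y2 → a1/a2/a3, b/y+HexNAc₁ at
positions ≥ 4 → a*N*, b/y+intact glycan → c*N*; b/y+HexNAc₁ at
positions 1–3 is excluded so the a1–a3 labels stay unambiguous. Because
b*N*+HexNAc₁ and y*N*+HexNAc₁ share the a*N* label, the library builder
resolves collisions by keeping the higher-intensity fragment and
logging the collision. The slot parser inverts every label back to
(kind, index); the backbone series of an a*N* (N ≥ 4) slot is not
recoverable from the label alone, by construction.

Oxonium reference m/z values are residue mass + proton (Hex⁺ 163.06010,
HexNAc⁺ 204.08665, Pent⁺ 133.04954). For N-glycans, dHex and Pent
oxonium ions are flagged exempt from the presence requirement — they
are weak or absent in QTOF spectra of fucosylated/xylosylated N-glycans
— while every monosaccharide of an O-glycan must be confirmed.

## Validation rules

`validate()` is a deterministic decision tree over matched ion classes
(fragment matching at 50 ppm by default, precursors at 20 ppm):

1. every required oxonium ion must be matched, else reject;
2. Lys/Arg–Pro or N-ragged cleavage: Y0 (O) / Y1 (N) anchor AND ≥ 3
   distinct b positions AND ≥ 3 distinct y positions;
3. otherwise with the Y anchor: ≥ 3 distinct backbone positions from
   the union of b and y;
4. without the anchor: ≥ 3 backbone positions with both series
   represented; a `strict_fallback` switch demands ≥ 3 of each series
   instead, for labs that read the fallback more conservatively.

A backbone position counts as matched if either charge state of its ion
is within tolerance. Co-elution of other glycoforms and Y-ion
confirmation of individual monosaccharides are recorded as advisory
notes only — they are not mechanizable as hard rules and never flip a
verdict. Matching consumes each peak at most once per query (nearest
peak wins), which for well-separated target sets is equivalent to
naive any-peak-within-tolerance counting; the test suite verifies the
engine against exactly such a literal recount.

## Library building

The identification report is a documented TSV dialect (one row per
fragment observation, grouped by scan) carrying what a search engine's
debug export contains; columns are listed in `glycodia.library`. The
builder keeps, per (modified sequence, precursor charge), the
highest-scoring PSM (ties to the lowest scan number), computes
theoretical Q1 from the peptide+glycan neutral mass and Q3 from the
fragment model, drops excluded slots, deduplicates on (modified
sequence, precursor charge, slot, fragment charge) keeping the highest
intensity, and emits the 14-column tab-delimited library (floats at
five decimals; the `isotype` column carries the slot label). Reading a
written library reproduces it field-for-field, and building from a
built library is idempotent. Merging a glycopeptide library with a
peptide-centric one takes the union; on key conflicts the glycopeptide
record wins and the conflict is logged. Decoys are emitted as FALSE
throughout — FDR control lives upstream.

## Quantification

Isolation windows are fixed-width and overlapping: window *i* spans
[low + i·(width − overlap), …+ width], with
⌈(high − low − overlap)/(width − overlap)⌉ windows; the default scheme
(400–1250 m/z, 26 wide, 1 overlap) has 34 windows. m/z values in an
overlap region are assigned to the later window so assignment is
unique.

Transition intensity is the summed signal within ±75 ppm of Q3 and
±3 min of the library RT (a 6-min total XIC window), inside the
acquisition window containing Q1; summation rather than peak-shape
integration is used, and RT alignment is not performed. Pre-extracted
transition tables are accepted as an alternative input. Peptide
precursors sum their top-6 transitions ranked by library reference
intensity; proteins sum their peptide precursors, with peptides shared
between accessions (`;`-joined) counted fully for every parent.
Reference normalization divides every protein by a spiked/background
reference (trypsin) per sample and is scale-invariant; total-abundance
normalization divides each sample column by its sum.

Glycoform relative abundance first sums all charge states of a
glycoform, then divides by the summed intensity of all detected forms
— including the unmodified peptide — of the same site-peptide family in
that sample. Families pool cleavage variants of one glycosite via an
explicit grouping table (the rule cannot be inferred from sequence
alone); ungrouped peptides are singleton families. A family with zero
total in a sample yields missing fractions, not zeros. Zeros propagate
through rollup; downstream log transforms drop them (logged) rather
than add a pseudocount.

## Statistics

Both contrast functions are per-analyte two-sided t-tests reported with
log2 fold changes: proteins on log2 intensities with α = 10⁻⁵ (a
deliberately stringent threshold standing in for a full feature-level
mixed model, which is outside this package's scope), glycoforms on
fractions with α = 0.05 (a `log_fractions` switch tests log2 fractions
instead, keeping the fold change on the fraction scale). The default
test pools variances (Student): the design targets technical
triplicates, where group variances are comparable, and at n = 3 the
Welch–Satterthwaite approximation is measurably conservative (empirical
null rejection ≈ 0.035 at nominal 0.05, versus ≈ 0.05 for the pooled
test — both measured by the calibration tests in this repository).
`welch=True` is available when unequal variances are expected. With
zero variance in both groups, p is 1 for equal means and 0 otherwise.
Raw p-values are reported; a Benjamini–Hochberg column is included for
information only. PCA treats samples as observations, drops analyte
rows with missing values (logged), centres, and reports per-sample
scores with explained-variance fractions.

## Synthetic data

The generator's default configuration emulates the glycoproteome
structure this workflow targets: a yeast seripauperin O-glycopeptide
(VITGVPWYSSR, site S9) with a Hex₁–₉ elongation ladder; the shared
seripauperin peptide (VNLVELGVYVSDIR, site S11) with unmodified +
Hex₁–₄ forms; a grape hydroxyproline-rich O-glycopeptide
(VVRPppTpKPpT) with Pent₁–₆; a grape N-glycopeptide (SNATLGR, sequon
N2) with HexNAc₁, HexNAc₂Hex₃dHex₁Pent₁ and HexNAc₃Hex₃dHex₁Pent₁; and
two unglycosylated trypsin peptides as the normalization reference.
Glycoform ladders default to a 1/(1+i) abundance profile (larger forms
progressively rarer), charge states 2+/3+ split 60/40.

Precursor mass errors are drawn from N(−15, 3) ppm, mimicking the
systematic negative bias of an uncalibrated QTOF; fragment reference
intensities are log-normal. DIA replicate intensities are truth ×
log-normal multiplicative noise with configurable CV (default 10 %,
a realistic transition-level figure for technical replicates), with
optional dropout. Planted fold changes are applied per glycoform per
condition. All randomness flows from one integer seed through
`numpy.random.default_rng`.

Ground-truth tables are computed inside the simulator by direct
arithmetic (top-k sums, accession sums, family renormalisation) without
calling the quantification module, so the noiseless end-to-end identity
check compares two independent code paths. Planted spectra keep noise
peaks ≥ 200 ppm from every theoretical target; planted ion-class counts
are exact lower bounds (distinct theoretical targets can genuinely
share an m/z, e.g. b1¹⁺ = b2²⁺ when the first two residues repeat), so
verdict checks recount matched classes literally.

What the simulations do *not* emulate: chromatographic peak shapes and
RT drift, interference from co-isolated analytes inside a DIA window,
isotope envelopes, in-source decay, and search-engine scoring behaviour.
Passing the synthetic tests therefore demonstrates the correctness of
the arithmetic, rule logic, bookkeeping and statistical calibration —
not robustness to real-spectrum interference, which depends on the
upstream search and manual curation this package consumes.

## Problem sizes and numerical choices

The bundled simulations are sized for quick, deterministic runs: the
default glycoproteome yields 48 precursors and ~1,400 transitions;
rule-engine equivalence is checked on 1,000 planted spectra; calibration
uses 1,000 null glycoforms at n = 3 per group; recovery uses a planted
2× shift on a minor glycoform (≈ 4 % of its family), for which the
expected fraction-level log2 shift is ≈ 0.94 after family
renormalisation. Library floats are written at five decimals and
records are rounded accordingly at build time so write/read round-trips
are exact. Matching tie-breaks are nearest-m/z; rollup ranking
tie-breaks on slot label to stay deterministic.

## Known limitations

- The a*N* slot class erases the b/y series of HexNAc-retaining ions;
  downstream tools see the slot label only.
- Quantification assumes centroided input and ignores the acquisition
  window when the input stream does not annotate one.
- The protein-level t-test is a simplification of feature-level
  mixed-model inference; with dropout-heavy data its zeros-dropped log
  transform loses information.
- Site localisation is consumed, never inferred; site-ambiguous
  glycopeptides skip the site-containing fragment classes.
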