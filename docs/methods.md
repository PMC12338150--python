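# Methods

## Chemistry model

All steroid cores are treated as substituted C24 cholanic acid skeletons.
The unsubstituted skeleton is C24H40O2 (both oxygens in the carboxyl);
every hydroxyl at C-3/C-6/C-7/C-12 adds one oxygen and every oxo group adds
one oxygen while removing two hydrogens relative to the hydroxyl form.
Positional and stereochemical isomers (CDCA vs DCA vs UDCA vs HDCA; α- vs
β-OH) therefore share an elemental composition and an exact mass — this is
deliberate, since mass spectrometry cannot distinguish them; they are
separated only by retention time where authentic standards exist.

Amide conjugation of a core with a free amino acid loses one water.  The
default library is the Cartesian product of 15 cores and 16 mass-distinct
amino-acid entries (glycine plus fifteen others, with leucine/isoleucine
collapsed into a single entry flagged ambiguous), 240 species.  Taurine is
excluded by default because taurine conjugates were not part of the
screened repertoire, but the registry accepts user-added residues.

Monoisotopic masses are summed from the NIST atomic mass table (via
pyteomics); the proton mass is 1.00727646688 Da.  Ionisation is negative
mode only: [M−H]⁻ = M − proton.  Average molar masses (for μg/ml ↔ μM
conversion) use standard average atomic weights, not monoisotopic masses.

Each conjugate carries a predicted fragment triad for MS2 confirmation:

* amino-acid anion = free amino acid − proton;
* amino-acid-loss fragment = deprotonated core (equivalently parent −
  residue mass);
* major sterol fragment, by default the dehydrated deprotonated core
  ([core − H − H2O]⁻).

The sterol rule is a plug-in because the true major sterol fragment varies
per compound; the dehydration default reproduces the dominant behaviour of
hydroxylated cores and can be replaced by a per-species callable.

## Identification

MS1 features match library species when |ppm error| is strictly below the
tolerance (default 2 ppm).  Retention time is *not* used to identify
conjugates without standards; it only (i) gates species that do have an
authentic standard (default window ±0.5 min), (ii) associates MS2 scans
with features, and (iii) groups double peaks.  All members of an isobaric
group (identical formula) are reported for a matching feature, with the
group size attached — ambiguity is surfaced, never silently resolved.

MS2 confirmation respects the acquisition geometry: all-ion-fragmentation
windows centered at 370/408/446/484/522 Th, 40 Th wide.  A scan is eligible
for a match when its window covers the precursor m/z and its retention time
is within the RT window of the feature.  Evidence is upgraded when ≥2 of
the 3 triad fragments are found within the fragment tolerance (default
10 ppm, coarser than MS1 because MS2 resolution is lower); a 3-of-3 rule is
available.  Because the windows only span 350–542 Th, conjugates heavier
than 542 Th can never be fragment-confirmed under this geometry — they
remain identifiable at MS1 level only.

Enantiomer double peaks: for each (sample, species) with several matched
features, adjacent features in RT order separated by at least the minimum
separation (default 0.3 min) form one reported pair.

## Quantitation

Calibration is a five-point external standard series (0.01, 0.05, 0.1, 0.5,
1.0 μg/ml) fitted by ordinary least squares with intercept.  Unknowns are
inverted through the line and converted to μM with the species' average
molar mass; an optional dilution factor scales back to culture
concentration.  Negative computed concentrations clamp to 0.  Censoring
flags: below-LOD (<0.05 μM) and below-report (<0.1 μM); values are reported
with their flag, never imputed.  Species without standards (all conjugates
except the glycine conjugates of CA/CDCA/DCA) are carried as raw
intensities and summarized in a per-species Z-score matrix (sample standard
deviation, ddof = 1; zero-variance rows are returned as zero and listed).
Per-strain normalization is available as a config switch since a heat map
can be standardized along either axis.

Activity calls scan a fixed 13-edge substrate→product graph.  A call
requires the product to reach the reporting threshold (0.1 μM) at 24 or
48 h under a condition supplying its substrate; the MIX condition supplies
all three substrates but DCA production is never scored there because DCA
is itself an input.  Product detections in no-substrate controls are
flagged as background; product concentrations exceeding the added substrate
by >5% are flagged as mass-balance violations.  Both are reported, not
dropped.

## Genotype prediction

BLASTP hits are gated at E ≤ 1e−10 (inclusive boundary: "threshold" is read
as pass-at-threshold) with the best hit kept per (query, CDS).  Operon
detection looks for the densest set of distinct bai-gene hits on one contig
whose footprint fits in a <100,000 bp window: each hit in turn anchors a
window starting at its CDS start, every hit fitting that window contributes
its gene, and the best window wins (most distinct genes, ties by smaller
span).  Coordinates are 1-based inclusive, so a single gene spans
end − start.  Strand is ignored — co-localization is by genome region only.
The canonical call requires the seven genes BaiA2/B/CD/E/F/G/H; BaiI is
optional.

HSD cutoffs: candidate thresholds are the observed scores themselves (any
threshold between adjacent scores yields identical confusion counts).  At
threshold t, TP = positives ≥ t, FP = negatives ≥ t, FN = positives < t;
F = 2/(recall⁻¹ + precision⁻¹) with the convention F = 0 when TP = 0
(precision is undefined there, and the convention keeps degenerate scans
total).  The cutoff is the minimal threshold achieving the maximal F, and
classification is inclusive (score ≥ cutoff) because the cutoff is itself
an observed positive score.  Scores may come from hmmsearch `--tblout`
files or from the built-in PSSM scorer (log-odds over match columns with
Laplace pseudocounts against a uniform background, best ungapped placement,
in bits; match columns are alignment columns with ≤50% gaps).  Cutoffs are
only comparable within one scoring backend.

## Concordance

Predicted and observed activities are reduced to (strain, class) records
over the classes {3α-HSD, 7α-HSD, 12α-HSD, 7α-dehydroxylation, conjugation,
other} and compared as sets, per class and per strain.  Transformation
labels map deterministically: the HSD and dehydroxylation labels to
themselves, the CA → 7,12-dioxoLCA double oxidation to both 7α-HSD and
12α-HSD (it chemically requires both), and epimerization/other to "other".
Species-level matching (a prediction confirmed by any strain of the same
species) is available via a strain→species map.

## Synthetic studies and what they establish

The generator emulates the screen's design: 72 strains by default, five
conditions (CA/CDCA/DCA at 100 μM, a 300 μM MIX, and a no-substrate
control), sampling at 24 and 48 h.  Roughly 60% of strains transform at
least one substrate; conditional on being a transformer, per-class
prevalences mirror the observed ordering (7α dehydrogenation most common,
then 3α, 12α, dehydroxylation, and rare other conversions).  48-h product
concentrations are drawn log-uniformly within per-class ranges matching the
observed spreads (up to ~94 μM for 7α, ~29 μM for 12α, ~9 μM for 3α); the
lower bound is set to 0.12 μM, just above the reporting threshold, so that
every planted activity is in principle detectable — class minima straddling
the threshold would otherwise make truth-ledger agreement ill-defined.
24-h concentrations are a random fraction (0.4–0.95) of the 48-h value.

MS1 features carry Gaussian ppm jitter (σ = 0.3 ppm, clipped at 1.5 ppm)
and multiplicative intensity noise (5% default, truncated at ±3σ).  Each
strain receives 500 decoy features placed ≥5 ppm from every library mass,
making false-match counts unambiguous.  Planted conjugates are restricted
to species whose [M−H]⁻ lies inside an MS2 isolation window, since species
outside the acquisition geometry could never be fragment-confirmed;
conjugates of species with authentic standards are planted at the standard
retention time.  Concentration-to-intensity uses the same linear
calibration model that quantitation inverts, with 1% calibration noise, so
zero-noise recovery is exact by construction: the benchmark validates the
pipeline's bookkeeping and thresholds, not chromatography or ionization
physics.  The generator works in measured space — sample-prep dilution is
not modelled (the dilution factor defaults to 1 and flows through if set).

Proteomes are synthetic: ~30 background CDS per strain laid out
sequentially on one contig, with planted operons inserted as a contiguous
block (~10–20 kb, well inside the window) and planted HSD genes scoring in
a high band (380–450 bits) disjoint from the background band (10–90 bits).
Reference score sets are separable by construction (positives 220–370,
negatives 10–90), so cutoff selection recovers F = 1; genotypes are planted
to match phenotypes.  Consequently the end-to-end benchmark shows that the
stages compose correctly and that thresholds behave as specified — it does
not show that real HSD activity is predictable from homology (the screen
this emulates found many active strains with no known homolog), nor that
real spectra are this clean.

All randomness derives from numpy Generators seeded with (seed, stage), so
ledgers and every emission from them are reproducible bit-for-bit; the
truth ledger serializes to JSON losslessly.

## Numerical and design choices

* Strict inequality at the MS1 ppm boundary; inclusive boundaries for the
  E-value gate and the HSD score cutoff (each stated above with its
  rationale).
* OLS curve fits require ≥3 distinct concentrations; slope ≤ 0 marks a
  curve unusable and downstream inversion rejects it.
* The match report sorts by |ppm|; ties elsewhere are broken
  deterministically (operon windows by span, classification support by
  descending score).
* Default problem sizes (72 strains, 500 decoys/strain, 100-seed noise
  replicates at 2 strains each in the test suite) keep a full run in
  seconds while exercising every stage at the study's scale.

## Known limitations

* No peak picking, centroiding, isotope-pattern scoring or chromatogram
  integration: inputs are feature tables.
* Retention-time prediction for conjugates without standards is not
  implemented; identification of those species is by exact mass and
  fragments only, and positional isomers remain grouped.
* The PSSM scorer is ungapped and is not a substitute metric for profile
  HMM scores from external tools; cutoffs are backend-specific.
* The concordance module counts agreements; it does no statistical testing.
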