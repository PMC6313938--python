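# Methods

## Processing model

The package models the canonical secretory-granule peptide-processing
cascade as a sequence-level grammar:

1. **Signal-peptide removal.** The mature chain is residues
   `signal_end + 1 .. L`. Signal calls are consumed from annotation
   tables (SignalP 4.1-style); nothing is predicted de novo.
2. **Endoproteolysis.** Prohormone-convertase sites are modelled as
   `(K/R)Xₙ(K/R)` with the scissile bond after the second basic residue;
   furin sites as `RX(K/R)R` with the bond after the final arginine.
   The intervening `X` residues are unconstrained — they may themselves
   be basic or glycine — so overlapping and nested matches are all
   reported, and deduplication happens only at the cutting step: all
   sites sharing a cleavage point collapse to one cut. Cleavage is
   treated as simultaneous at every predicted site; the pipeline derives
   product inventories, not kinetics, so ordered cleavage would yield
   the same final products.
3. **CPB trimming.** C-terminal Lys/Arg are removed iteratively from
   each product.
4. **PAM amidation.** A trimmed product ending in Gly loses that Gly
   and the new C-terminal residue is recorded as the amide. A product
   must retain ≥ 1 residue after Gly removal (an amide of nothing is
   meaningless), so the minimum amidated-product length is 1. Products
   trimmed away entirely are flagged degenerate.

A second, independent route matches a NeuroPred-style "known motifs"
pattern table (strings over {K, R, X}); matches whose text also fits an
exclusion pattern are removed after matching. The published known-motif
table is not enumerated anywhere we can consume it, so the shipped
default is the mono-/dibasic set (KR, RR, KK, RK) plus the spaced
patterns KXXK, KXXR, RXXK, RXXR, with RK, KXXK and KXXR excluded by
default; both lists are user-replaceable through a YAML `MotifConfig`.
Genome-scale counts computed in known-motifs mode therefore depend on
the table supplied and should be read with that caveat.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `pc_spacings` | {0, 2, 4, 6} | allowed Xₙ spacer lengths in a PC site |
| `amidation_spacings` | {1, 3} | spacer lengths in `(K/R)XₙG(K/R)` |
| `known_motifs` | see above | NeuroPred-style pattern table |
| `excluded_motifs` | {RK, KXXK, KXXR} | patterns removed after matching |
| `max_basic_tail` | 3 | longest `(K/R)ₙ` tail after a terminal Gly |

Two presets differ only in the spacing set: `methods-spacings`
({0, 2, 4, 6}, the default) and `results-spacings` ({0, 2}). Both
conventions circulate for dibasic-site screens; the full set is the
default because it is the superset actually scanned, and the restricted
preset is provided for comparability with the narrower convention.

Counting conventions: motif-presence counts (PC, amidation classes,
furin, terminal Gly) are per protein, evaluated on the mature chain.
Amidated peptides are counted per (precursor, span); identical sequences
arising from different precursors count separately. A furin site is
"amidatable" when its upstream product, after CPB trimming, ends in
glycine.

## Secretome merge

Per-sample spectral counts are scaled Scaffold-style so every sample's
total equals the mean total across samples (switchable off); absence is
encoded by omission and contributes 0 to statistics. A protein is
retained when present in ≥ `min_presence` (default 4) of the samples.
`avg_total` is the mean normalized count over all n samples and `sem`
the (n−1)-denominator standard deviation divided by √n. Ranking is by
descending `avg_total` with lexicographic tie-break on protein id for
determinism; summation order is fixed by sorting values, so the merge is
bitwise permutation-invariant in sample order. The signal-peptide triage
flags proteins whose localization class is SP, or O/NA with a
signal-peptide call; C and M classes are excluded even with a signal
call because organellar transit peptides confound signal predictors.
Because replicate tallies reported for such experiments are sometimes
unions and sometimes per-dataset counts, `dataset_census` reports
per-dataset, union and intersection sizes side by side.

## Topology classification

Two binary facts decide the call: a cleavable signal peptide and the
presence of ≥ 1 TM helix. Signal ∧ no helix → secreted; signal ∧ helix
→ Type I; helix ∧ no signal → Type II; neither → other. Helix position
is deliberately ignored: a protein whose only helix sits near the
C-terminus but which lacks a signal peptide is still Type II under the
signal-anchor reading, and this rule set reproduces all 21 rows of the
packaged S8 subtilisin reference table. The four rules are exhaustive
and mutually exclusive by construction.

## Gel-slice cleavage inference

Each gel slice carries a half-open mass interval `[low, high)`; a mass
on a boundary belongs to the higher slice, and masses outside the union
clamp to the nearest boundary slice (logged). Slices with
`high < (1 − tolerance_fraction) × intact_mass` are *sub-intact*;
`tolerance_fraction` (default 0.2) absorbs the imprecision of gel
migration. A protein is **cleaved** when sub-intact slices carry
≥ `min_counts` (default 2, guarding against single stray PSMs) summed
spectral counts; its fragment regions are the merged unions of peptide
spans in those slices, labelled N-terminal when the union lies in the
first 40% of the chain, C-terminal in the last 40%, else internal (the
40% cutoffs are a stated heuristic, configurable). It is **intact**
when all evidence sits in slices at or above the intact-mass slice, and
**ambiguous** otherwise. Raising the tolerance only shrinks the
sub-intact set, so it can never flip an intact call to cleaved. Intact
masses come from an input table; a sequence-based fallback
(`length × 0.110 kDa`, average residue mass) is provided and labelled
approximate. Domain labels attach to a fragment when the fragment
covers ≥ 50% of the domain's length (configurable).

## Synthetic data

The generators are pure functions of (parameters, seed); all randomness
flows through one `numpy` Generator per call.

* **Precursors** are a planted signal peptide (Met + hydrophobic core)
  followed by alternating 9-residue spacers and motif insertions (`KR`,
  `RQKR`, or `GKR` for an amidatable site). The spacer alphabet
  (ASTVLEDQNPF) excludes K, R and G, so spacers cannot complete any
  motif and the expected false-positive count is exactly zero; the
  9-residue spacing puts every cross-motif basic-residue gap outside
  the PC spacing set, so each planted site yields exactly one cut and
  each `GKR` site exactly one amidated product with a known amide
  residue.
* **Secretome tables** assign each protein a presence level over the six
  samples and draw counts as `1 + NegBin(mean − 1, dispersion)` — the
  shift keeps counts strictly positive (absence is omission, not zero),
  the negative binomial provides spectral-count-like overdispersion.
  Defaults (100 proteins, uniform presence over 1..6, mean 20,
  dispersion 2) give a realistic mix of retained and filtered proteins.
* **Gel evidence** plants intact proteins (~400–520 residues, peptides
  only in their intact slice) and cleaved proteins (terminal quarter
  fragment, peptides confined to the fragment and observed in the
  low-mass slice containing the fragment mass).

These emulate the *shapes* of real data, not its biology: no missed
cleavages, no noise peptides outside planted regions, no shared peptides
between proteins, no mass errors. Passing the planted-truth tests shows
the logic is implemented correctly, not that the grammar's precision on
real proteomes is high — motif grammars of this kind are deliberately
permissive screens.

## Numerical and policy choices

* Positions are 1-based inclusive everywhere; cleavage points are
  "after residue i".
* Proteins missing an annotation row default to not-secreted / no
  helices / NA localization (predictors omit negatives); each default is
  logged rather than raised.
* Exports sort histogram and table keys so reruns are byte-identical.
* Problem sizes in the test suite (300–1000 random sequences per oracle
  comparison, 10,000 sequences for the analytic site-count expectation,
  proteomes of 10–200 synthetic entries) were chosen to make Monte-Carlo
  checks statistically meaningful while keeping the suite quick on a
  laptop.

## Known limitations

* No machine-learned cleavage scoring: matching is purely motif-table
  based, so specificity is what the motif tables give.
* Genome-scale reproduction depends on the exact proteome release and
  predictor versions used for the annotation tables, and in known-motifs
  mode on the exact motif table; the pipeline reports its input sizes so
  discrepancies are traceable rather than silent.
* Gel-slice inference cannot locate the actual cleaved bond; it reports
  fragment regions, not sites, and assumes the slice mass bounds are
  trustworthy.
* Masses from sequence ignore PTMs (glycosylation is heavy in algal
  cell-wall proteins), which is why annotated masses are the primary
  input.
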