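# Methods

## Scope and model

`acpmine` models anticancer-peptide (ACP) discovery as a composition-based
classification problem over short peptides (5–50 residues) harvested from
DNA reads. The working assumptions are those of all composition-feature
peptide classifiers: activity correlates with residue usage (cationic,
hydrophobic, aromatic enrichment) rather than position-specific motifs, so
mono- and dipeptide frequencies are a sufficient feature space, and a linear
decision boundary on those 420 features is interpretable and adequate.

## Reads to peptides

The route from nucleotide reads to peptide stretches is six-frame
translation under the standard genetic code with fragments split at stop
codons; this bridge is this package's design decision — direct protein-FASTA
input bypasses it (`acpmine mine --protein`). Codons containing N terminate
a fragment rather than being translated ambiguously. FASTQ qualities are
parsed for integrity but discarded: read QC is assumed to have happened
upstream, and no stage here uses base qualities. Coordinates are 0-based
half-open on the forward strand; frames are +1..+3 and −1..−3. Records
containing non-canonical protein letters (B, J, O, U, X, Z) are rejected
with a logged count (or raise, under the `error` policy) because composition
features are undefined for them.

## Feature space and selection

Features are the 20 residue frequencies (alphabetical) followed by 400
overlapping-bigram frequencies (lexicographic), normalized by L and L−1
respectively; a length-1 peptide has an all-zero dipeptide block. This
ordering is a frozen contract — model files store feature ids and scoring
verifies them.

Discriminative features are tested per column with a two-sided two-sample
t-test, Welch's variant by default (composition variances differ between
classes by construction; a pooled-variance Student option exists), and
corrected by Bonferroni: `p_adj = min(1, m·p_raw)`, selected iff
`p_adj < α` (default 0.05). The multiplier m counts only testable features —
columns with zero variance in both groups carry no information and would
inflate the correction arbitrarily. Under a complete null this controls the
family-wise error rate at ≤ α; with heavily zero-inflated dipeptide columns
the t-approximation is conservative in practice (measured FWER ≈ 0.002 at
α = 0.05 in the acceptance run), which costs power on the rarest bigrams but
never inflates false selections.

By default only selected features feed the classifier (with a fallback to
all testable features if nothing survives correction, so the selection step
can never empty the design matrix); a config flag trains on all 420.

## Classifier

A soft-margin linear SVM (regularization C = 1.0) on z-standardized
features; standardization statistics are frozen into the model at train
time. Decision values are mapped to [0,1] by a logistic (Platt) fit on the
training decision values — the score is a strictly monotone transform of
the margin, so ranking is calibration-independent. The decision threshold
is 0.5 with a strict inequality (a score exactly at threshold is nonACP).
The training seed is mandatory; identical data, config and seed give
bit-identical model files (JSON with a sha256 integrity checksum and a
major-version gate). Cross-validation is stratified k-fold with feature
selection re-run inside each training fold, so reported metrics carry no
selection leakage.

## Mining

Candidate windows cover every length in [5, 50] at step 1. The minimum of 5
residues is the mining floor used when the source metagenome was scanned;
the maximum of 50 is the customary upper bound of composition classifiers
(the original derivation states only the minimum). Deduplication merges
identical peptides and conserves provenance entries one-for-one. Ranking is
score descending with deterministic tie-breaks (shorter first, then
lexicographic); no ranking rule was given for the original derivation, so
determinism drove the choice. Domain context comes from parsing externally
produced per-domain (`--domtblout`) tables of profile-HMM search tools in
the hmmscan orientation (query = candidate); implementing HMM scoring
itself is out of scope, and the default attachment cutoff is an independent
e-value of 0.01.

## Physicochemical descriptors

* **Elemental formula / mass**: sum of in-chain residue formulas (or
  4-decimal average masses) plus one water, free unmodified termini.
  Monoisotopic masses sit behind a flag. Formula and mass agree through
  IUPAC atomic weights to within 0.05 Da.
* **Integer charge**: (#K + #R) − (#D + #E), histidine and termini
  excluded. This counting mode is what synthesis vendors quote and is the
  mode used in the mining objective; it reproduces the worked example's +5.
* **Henderson–Hasselbalch charge**: graded sum over ionizable groups with
  the bundled EMBOSS pKa set (versioned, immutable); pI is the bisection
  root of that curve on [0, 14] to |charge| < 1e-3. A peptide with no
  ionizable groups (termini-free mode) has no pI and raises. The worked
  example's pI computes to ≈ 10.5 under this set — consistent with a +5
  cationic peptide; published tool-specific values that contradict the sign
  of the charge at pH 7 are not reproduction targets.
* **GRAVY**: mean Kyte–Doolittle hydropathy.
* **Hydrophobic moment**: Eisenberg-consensus vector sum at 100°/residue
  (α-helix; 160° configurable for β). Reported absolute and per residue.
  GRAVY and the moment deliberately use two different bundled scales, both
  swappable by file.

## Propensity scan

Window score = mean residue propensity over a 5-residue window; a residue
is flagged iff some covering window scores strictly above the threshold
(default 0.25), so window-start indices map naturally onto residue
intervals (one above-threshold window starting at residue 1 flags 1–6 when
merged with its successor). Coverage is the flagged fraction of residues,
reported unrounded and rounded. The bundled propensity scale is a
**synthetic stand-in** (hand-built cationic/aromatic preference, labelled as
such in its data file); it reproduces the scanning *behaviour*, not any
specific served tool's per-window probabilities — users supply a real scale
as a TSV to get those.

## Terminal modification

An extension of t residues at the N- (default) or C-terminus is scored by
`w_c·Δcharge + w_g·ΔGRAVY + w_m·Δ(μH/L)` with default weights (1, 1, 1);
the original design presents one hand-chosen 4-mer, so the weights are
exposed configuration, not a fitted quantity. Deltas are recomputed from
scratch on the full modified sequence. Exhaustive search covers lengths
≤ 4 (20⁴ = 160 000 candidates); longer extensions grow greedily per
position, a documented approximation. Note the worked example's AAEK has
Δcharge = 0 under the counting rule (one K cancels one E); the package
reports deltas honestly rather than bending the rule to narrative claims
about increased charge.

## Synthetic data: what it emulates, what it does not

`sample_peptides` draws i.i.d. residues from a class profile, lengths
uniform on 5–50. The default ACP-like profile (K .13, R .11, L .12, F .08,
W .06, D = E = .01, remainder spread over the other residues) against a
uniform background encodes the cationic/hydrophobic enrichment that
separates curated ACP sets from generic peptides; the shift magnitudes were
fixed once as a realistic curated-database contrast and give a Bayes-limited
held-out accuracy around 0.92 under the default training size (200/group).
`plant_feature_shift` raises one residue frequency by δ with proportional
renormalization, or boosts one first-order transition for dipeptide shifts.
`generate_reads` reverse-translates planted peptides with uniform codon
usage, flanks them with stop codons, and embeds them at random strand and
offset in 300-nt random-base reads (long enough for a 30-mer ORF with
flanks), with constant FASTQ qualities.

What this does **not** model: positional motifs or secondary-structure
signal within peptides, codon bias, sequencing error, quality-score
structure, community composition, or homology between training and mined
sequences. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its statistics behave as designed under
composition-only class structure — not that the classifier's accuracy
transfers to real curated ACP sets.

## Problem sizes and numerical choices

The statistical acceptance checks run at the sizes stated with them: 1000
null replicates at 50/group for the family-wise error rate, 100 replicates
at 200/group for planted-feature recovery, 30 planted peptides against 50
background reads for the mining round trip — sizes at which the binomial
error of the measured rates is small relative to the bounds they are
checked against. Bisection tolerance for pI is 1e-6 in pH, asserted to
|charge| < 1e-3; degenerate t-tests (both groups constant and equal) are
defined as t = 0, p = 1; two constant groups with different means raise.
All ranking ties break deterministically. Seeds derive from a single
user-supplied integer everywhere randomness exists.

## Known limitations

* Composition features ignore residue order beyond bigrams; permuted
  peptides with identical bigram content are indistinguishable.
* The bundled propensity scale is a stand-in (see above).
* The greedy long-extension search is not globally optimal.
* The t-test on sparse dipeptide columns is conservative at small n; rare
  bigram effects need larger groups to be detected.
* Classifier scores are calibrated on training decision values only; they
  are comparable within a model, not across models.
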