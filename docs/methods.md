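# Methods

## Problem and model

A protein's disulfide topology is a matching on its cysteines: each
candidate bond is an unordered pair of cysteine positions (1-based), and no
valid topology reuses a cysteine. Several determination methods each emit a
set of candidate bonds with confidences in [0, 1]. `ssfuse` models these as
evidence sources in the Dempster-Shafer sense and fuses them.

**Frame of discernment.** By default the frame is the union of all bonds any
method reported, in first-report order ("union" mode). This mirrors how the
case-study analysis proceeds and keeps the focal-set space small. An
"all-pairs" mode (all n(n-1)/2 cysteine pairs) exists for completeness;
because the power set grows as 2^|theta|, consistent-subset enumeration is
capped at a maximum cardinality (default 4 — four simultaneous bonds is
already a large focal set for the frames this tool sees). Inconsistent
subsets — two bonds sharing a cysteine — carry mass 0 by definition and are
never enumerated.

**Belief assignment.** A method's per-bond scores sigma_i become subset
masses through

    m(j) = max( sum_{i in j} (2 sigma_i + gamma_i - 1) / k , 0 ),   k = |j|

with gamma_i = -S/(2k) when sigma_i = 0 and +S/(4k) when sigma_i > 0
(S = sum of the subset's scores). The design intent is that extreme scores
dominate: a zero score drags a subset's mass down hard, scores near 1 push
it up strongly, and middling scores are only slightly modified (for a
positive singleton the function reduces to 2.25 sigma - 1, so anything below
sigma = 4/9 contributes nothing). Bonds of the frame a method did not report
score sigma = 0, matching how unreported bonds appear as 0.00 in per-method
scoring tables.

The subset-scoring function is defined up to normalisation; the published
description says only that the values "are normalised". The rule adopted
here: if raw masses total more than 1 they are divided by their sum
(environment mass 0); otherwise they are kept and the deficit 1 - total goes
to the environment. This is the unique simple rule that both respects the
unit-total axiom and reproduces the published MS-column values of the
case study (0.33 / 0.34 / 0.33 across the three consistent subsets).

Two case-study quirks are deliberate non-reproductions. The printed CSP
column shows 0.20 per subset from sigma = 0.21, but the assignment function
as defined yields raw mass < 0 for every subset at that score
(2·0.21 + gamma - 1 < 0), so this implementation produces a vacuous CSP mass
function (environment = 1). And the printed MS column pairs 0.34 with the
*lower* sigma (0.80) and 0.33 with the higher (0.81), which contradicts the
function's monotonicity; this implementation keeps the monotone assignment.
Both look like transcription slips in the source table; neither affects the
two-bond subset mass.

## Combination rules

All product-based rules use the n-ary simultaneous form: one focal element
per source (the environment included), mass products accrued to the tuple's
intersection. The environment is the identity of intersection; a tuple whose
bond sets intersect to the empty set is conflict. The n-ary form matters:
pairwise iteration is order-dependent for Yager, and only the simultaneous
form reproduces the published total-suppression behaviour of the case study.
Dempster is associative, and a test asserts pairwise-iterated equals n-ary
for it.

- **Dempster** divides surviving masses by the surviving product total
  (mathematically 1 - conflict; implemented as the actual sum so fused
  masses total exactly 1 in floating point). Total conflict raises
  `TotalConflictError` — never a silent fallback.
- **Yager** adds all conflict mass to the environment.
- **Campos** divides the Dempster orthogonal sum by 1 + log X, where
  X = 1/(1 - conflict) and log is natural (the weight-of-conflict
  convention; the base is not specified in the source, and the natural log
  is the standard choice). The de-rated deficit joins the environment.
- **Shafer** discounts each source by a reliability alpha (masses scaled by
  alpha, remainder to that source's environment) and averages the
  discounted mass functions focal-set by focal-set. The plain arithmetic
  mean is used for any number of sources; the published form is stated for
  two sources and a weighted mean is a possible alternative reading, but
  the plain mean is the only one that needs no extra parameters.

Discounting applies **only** inside the Shafer rule; Dempster, Yager and
Campos consume undiscounted masses.

Per-bond fused belief is the containment sum: the total mass of focal sets
containing the bond, environment excluded. Singleton belief ss({b}) and
plausibility are also available for diagnostics.

## Constituent predictors

**MS scoring.** In-silico digestion (trypsin or chymotrypsin, configurable
missed cleavages, via pyteomics cleavage rules) yields all
cysteine-containing peptide pairs, joined with a -2H disulfide bridge;
intra-peptide bonds are included. Candidates are filtered by precursor mass
agreement (default +/- 1.0 Da). Theoretical fragments cover twelve ion types
(a, a-H2O, a-NH3, b, b-H2O, b-NH3, c, x, y, y-H2O, y-NH3, z), singly charged
monoisotopic; a backbone fragment that retains the bonded cysteine carries
the intact partner peptide. For intra-peptide bonds, fragments containing
exactly one of the two linked cysteines are skipped (a ring-opened species
the model does not describe). Charge states > 1 and internal ions are out of
scope.

Scores: VS is the matched fraction of retained peak intensity x 100, with
peaks below 10% of the maximum intensity ignored (the customary noise
floor; configurable). pp is -log10 of the binomial upper tail of the
confirmed-match count, with per-fragment random-match probability
p2 = 2 m VM_TH / r — m is read as the number of theoretical fragments,
VM_TH the match tolerance (default 0.5 Da) and r the spectral m/z range.
(Reading m as a single ion's mass value, as the source's gloss suggests,
does not yield a probability; the fragment-count reading does.) The tail is
summed in log space so extreme match counts give large finite pp rather
than overflow. pp2 is -log10 of the Gaussian upper tail of the total
matched abundance; its mean and s.d. are estimated from the spectrum's own
retained peak intensities (matched-count x mean, sqrt(count) x s.d.), since
no external abundance model is available. The log base 10 for pp/pp2
matches the magnitude of the published threshold T_pp = 50. For fusion, pp
maps to a belief by min(pp/100, 1) — a convention, exposed in `MSConfig`.

Search-space trimming is the classic subset-sum approximation: a greedy
scan keeps a mass only if it exceeds (1 + epsilon) times the last kept
mass, guaranteeing every removed mass a kept representative within the
relative factor. epsilon defaults to 1e-4 and is a parameter (the source
calls it data-derived without giving a formula).

The global topology is the maximum-weight matching on the cysteine graph
(networkx). Edges are inserted in sorted bond order, making the result
deterministic; co-optimal matchings have equal total weight, which is what
the brute-force oracle test asserts.

**SVM predictor.** Each cysteine pair is encoded as 2 x 13 x 20 + 1 = 521
features: a 13-residue window centred on each cysteine (six on either side
plus the cysteine itself — the window composition is a documented
convention), one-hot over the 20 standard amino acids, zero blocks for
positions off the sequence ends or non-standard residues, plus the raw
residue separation d_ss (unscaled; no normalisation is specified). The
classifier is a pluggable margin scorer (positive margin = bonded, a fixed
sign convention); a reference RBF-SVC trainer is included for synthetic and
fixture data. Margins are calibrated to beliefs with
sigma = 1/(1 + exp(A f + B)); A and B are fitted by regularised maximum
likelihood (Platt's smoothed targets, Newton iterations with backtracking,
tolerance 1e-6, max 100 iterations). The production training corpus (a
filtered SwissProt subset) is external and not reproduced; the filtering
rules are documented in the source.

**CSP predictor.** The separation profile is the vector of consecutive
cysteine-position gaps. All cysteines of the query enter the profile, since
oxidation state is unknown a priori. Profiles of different length are
incomparable rather than padded (the divergence is undefined otherwise).
Divergence is the L1 distance; belief is (1 + log10(1 + D/10))^-2. The
query inherits the minimal-divergence entry's topology by cysteine ordinal
(the profile abstracts positions, so only ordinals are preserved); ties at
minimal divergence resolve to the first entry in database order, and the
tie count feeds the discounting rule. The shipped reference database is a
small synthetic stand-in of 12 annotated entries (the real annotated
database is external); tests and examples exercise the matching logic
against it.

## Discounting

Weights start at 1 and are decremented subtractively ("decreased by" is
read literally, not multiplicatively), clamped to [0, 1]:

- MS: -alpha_mass (default 0.1) if the precursor exceeds T_mass (default
  4000 Da — heavy ions fragment poorly); -alpha_pp (default 0.2) if pp2
  falls below T_pp (default 50 — matched abundance looks random).
- SVM: weight = belief if belief >= 0.9; belief/1.5 if 0.5 < belief < 0.9;
  belief/3 if belief <= 0.5. Boundary conventions (0.9 keeps full weight,
  0.5 takes the /3 branch) are unstated in the source and fixed here; no
  further clamping or renormalisation is applied after the division.
- CSP: -D/100 if the divergence D exceeds 10 (D = 10 incurs nothing);
  -0.1 if fewer than two entries tie at the minimal divergence
  (the "less than two matches" penalty is read as the tie count).

## Evaluation

Confusion counts are taken over a pair universe (all candidate pairs);
metrics are accuracy Q2, sensitivity Qc, specificity Qnc and MCC with the
four-factor denominator. Undefined metrics (zero denominator) are NaN, not
errors. Both pooled (micro) and per-protein-averaged (macro) aggregates are
implemented and labelled: published aggregate tables for this benchmark are
macro averages (the baseline MS sensitivity 0.821 is the mean of
per-protein sensitivities; pooled counting would print 0.824). When a
fixture carries only bond lists (no full cysteine inventory), only the
sensitivity family is computed — the negative-pair universe is unknown.

## Synthetic data

The generator emulates the study conditions: proteins with an even number
of cysteines (4-10) carrying a planted perfect-matching topology; three
methods reporting planted bonds with Beta-distributed beliefs around 0.85,
10% per-method dropout, and with probability 0.2 a conflicting decoy — a
bond sharing a cysteine with a true bond, beliefs around 0.2. The spreads
mirror the range of published per-bond scores (roughly 0.2-0.96 across the
tables). Synthetic spectra contain each planted pair's own theoretical
fragment peaks plus uniform noise peaks above the intensity floor. All
generation is a pure function of (config, seed).

What the generator does *not* emulate: isotope envelopes, charge states,
instrument-specific noise, homologous decoys for the sequence predictors,
or correlated errors between methods. Passing recovery tests therefore
shows the fusion and scoring machinery is correct under idealised evidence,
not that real-data accuracy matches any published figure.

Test problem sizes are chosen for desk-scale runs: Monte-Carlo recovery
uses 100 synthetic proteins for the evidence route and single proteins with
4-6 cysteines for the spectra route; oracle cross-checks cover up to 3
sources x 4 focal sets (combination), 6-bond frames (subset enumeration)
and 8-cysteine graphs (matching), where exhaustive enumeration is exact and
fast.

## Known limitations

- The end-of-pipeline rule values printed in the source's case-study table
  (Dempster 0.47/0.47, Campos 0.15/0.15, Shafer 0.35/0.36) cannot be
  reproduced from the printed intermediate masses: under the stated rules
  the three-method combination is totally conflicting (Dempster/Campos
  undefined) and the Shafer average over the printed masses gives different
  values. The aggregation that produced those numbers is under-specified;
  this package reports what the rules as defined produce.
- MS fragment generation is monoisotopic, singly charged, with no internal
  ions; real spectra of large disulfide-linked pairs will match less
  completely than the synthetic ones.
- The SVM and CSP components ship without the external training corpus and
  reference database; users supply their own for production use.
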