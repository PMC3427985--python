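# Methods

## Scope and model

`plantpts1` predicts whether a plant protein carries a functional
C-terminal type-1 peroxisome targeting signal (PTS1). The model is
deliberately simple and interpretable: a position weight matrix (PWM)
over the last 14 residues, an additive total score, a fixed decision
threshold, and a Gaussian class-conditional mapping from score to
targeting probability. The package reimplements the prediction scheme
of the first plant-specific PTS1 web service; the service's trained
matrix was never published, so this package separates cleanly into

* **published-constants mode** — the service's printed operating
  constants (threshold 0.412; Arabidopsis proteome score extremes
  1.188 / −1.966; highlighting statistics mean −0.069, SD 0.112 for
  the tripeptide region and 0.057 for the upstream region) are shipped
  read-only and drive display and decisions around externally supplied
  scores or matrices; and
* **trained mode** — matrices, calibrations, thresholds and
  highlighting statistics are estimated from user-supplied (or
  synthetic) training windows.

Printed scores of the published model (the ten-protein Arabidopsis
non-canonical benchmark, the At1g18700 worked example) are treated as
fixture inputs everywhere; no code path pretends to reproduce them from
a matrix.

## Sequence handling

Input is FASTA (multi-record, wrapped lines) or header-less plain text
(one record, identifier `query`). Sanitization removes every
non-letter character — digits, whitespace, `*` stop codons, `-` gaps
and the `>` C-terminal marker the field writes after tripeptides — and
uppercases the rest; it is idempotent. The 6 ambiguity letters
X/B/Z/U/O/J survive sanitization and are resolved at scoring time with
a neutral score of 0 plus a report warning, so one unknown residue does
not void a 14-position prediction. Sequences shorter than 14 residues
are rejected rather than padded: the model is defined on exactly 14
positions and any padding semantics would be invented.

## Estimation

The trainer counts residues per position over the positive windows and
scores residue *a* at position *p* as
`log10((c + κ·b_a)/(n + κ)/b_a)` with pseudocount κ (default 1.0) and
background *b* (default uniform 1/20; optionally estimated from a
negative sequence set). Log base 10 is the package default — the
magnitudes of the published per-residue contributions (~0.05–0.3) and
total range (−1.966…1.188) are consistent with small-magnitude
logarithms, and the base only rescales all scores uniformly.
Classification is inclusive: `total ≥ threshold` predicts peroxisomal.

## Calibration

Both calibrations model class-conditional score densities as Gaussians
fitted by maximum likelihood (means; variances with ddof 0), with a
configurable class prior defaulting to 0.5 (the original service's
prior is unknown; it is deliberately not guessed).

* *original*: class-specific variances. The log-odds is quadratic in
  the score, so the posterior need not be monotone far in the tails.
* *balanced*: one pooled (sample-size-weighted) variance. The
  posterior reduces to a logistic `expit(a + b·s)` with
  `b = (μ+ − μ−)/σ²`, used both as a closed-form cross-check and to
  derive the data-driven threshold (posterior-0.5 point) of trained
  models.

Posteriors are evaluated on the log scale
(`expit(logit(π) + log g+ − log g−)`) for tail stability. The
qualitative contrast the two schemes produce — a broad negative class
makes the balanced posterior much larger than the original one for
positives scoring below the bulk of their class — is asserted in tests
because it is the property that makes the balanced scheme useful for
non-canonical, low-abundance PTS1 proteins (with a correspondingly
higher false-positive rate above 50%).

A separate empirical device, `fit_curve_to_pairs`, least-squares-fits a
slope-constrained (strictly increasing) logistic to published
(score, probability) pairs. Fitting is on probabilities rather than
log-odds so exact 0.000 / 0.990 endpoints of printed tables are
usable; two pairs exactly identify the curve (the documented
"at least 2" relaxation of a nominal 3-pair minimum). Initial values
come from a linear fit on clipped log-odds; the slope bound is 1e−9.

## Highlighting

Per-region statistics (mean, population SD over all matrix entries of
the region) define bands [mean − SD, mean + SD]; scores strictly
outside the band are flagged enhancing/inhibiting, the closed interval
itself is neutral. The published constants print a single mean
(−0.069) with two SDs; whether that mean is global or per-region is
ambiguous in the source material, so `compute_region_stats` supports
both readings (`shared_mean` flag): published-constants mode uses the
single printed mean for both regions, trained mode defaults to
per-region means.

## Tripeptide registry

The registry maps a C-terminal tripeptide to its experimental
validation status, canonicality and an evidence note. The bundled file
`pts1_tripeptides.synthetic.tsv` is a *synthetic reconstruction* from
tripeptides individually named as validated in the plant PTS1
literature (canonical set {SKL, SRM, SKI, AKL}; validated
non-canonical SKV, VKL, IKL, QRL and the benchmark tripeptides); the
original service's downloadable list is larger and frequently updated.
Lookup is an exact match on the last three residues; absence means
"not experimentally verified", never "not peroxisomal".

## Synthetic data generator

Real PTS1 training collections are dominated by canonical tripeptides
with near-background upstream composition and occasional upstream
enhancer positions. The generator emulates exactly that structure:
a tripeptide weight table (defaults heavily enriched for SKL-type and
validated non-canonical tripeptides, 90% of windows) mixed with a
background-tripeptide component (10%, giving every residue positive
probability at every position, hence finite analytic log-odds), and
per-position upstream compositions (uniform except moderate enrichment
of R/K/S at −6 and R/K at −11, the upstream positions with the widest
score range in the published model). These defaults are illustrative
of PTS1-like structure, not a reconstruction of the original training
distribution. All randomness flows through one `numpy` generator
seeded per call.

Two sampling modes exist. The default, `balanced`, allocates category
counts by largest-remainder stratification (randomized remainder
assignment, independently shuffled columns): a size-*n* sample then
realizes the nominal composition with discrepancy O(1/n) per category.
This was chosen at design time from a power analysis: the per-entry
standard error of a log10 frequency estimate at p = 0.05, n = 10,000
is ≈ 0.019 under i.i.d. sampling, so the maximum error over 280 matrix
entries typically exceeds 0.05 and entry-wise parameter-recovery
checks at that tolerance would be dominated by binomial noise rather
than estimator correctness. Stratified allocation suppresses that
noise, making recovery tests a sharp check of the estimator itself;
`iid` mode provides plain multinomial sampling for studies of sampling
variability (its frequency tests use 4σ binomial bands to absorb the
280-cell multiplicity). `true_logodds` returns the analytic log-odds
of the generator's per-position marginals and is computed independently
of the trainer.

What passing synthetic tests do **not** show: performance on real
proteomes (real upstream compositions are position-correlated and
species-biased; the generator's positions are independent), and
agreement with the published matrix (unavailable).

## Numerical choices

* Totals are summed in position order with plain float addition and
  checked against a loop oracle for exact equality.
* Closed-form equivalences (balanced ≡ logistic; original ≡ density
  ratio) are asserted to 1e−12 on 1,000-point grids spanning the class
  means ±(several SD); outside such ranges the density-ratio form can
  underflow while the log-scale implementation stays defined.
* Degenerate cases: zero-variance calibration classes, equal class
  means, empty training sets, zero background frequencies and
  registries with duplicate or malformed rows all raise `ValueError`
  with the offending quantity named. All-zero matrices yield SD-0
  bands and all-neutral flags.
* Boundary conventions: the decision threshold is inclusive
  (peroxisomal at equality); highlight bands are closed (neutral at
  equality).

## Problem sizes

Default study sizes are 10,000 windows for parameter-recovery checks
(the size at which the 0.05 log10 tolerance is meaningful under
stratified sampling), 2,000 + 2,000 windows for the worked training
example, and 1,000 matrix/window pairs for additivity checks. The
whole suite runs in a few seconds on one core.

## Known limitations

* The consensus verdict over putative orthologs is a simple majority
  vote (`supported` above the support fraction, `contradicted` below
  its complement, ties ambiguous); the original analyses reasoned
  case-by-case and no quantitative rule was published.
* Only spermatophyte-style PTS1 prediction is covered: no PTS2, no
  residue-interdependence modelling, no homology search or alignment.
* The registry reconstruction is necessarily incomplete (see above).
* Thresholds derived from synthetic calibrations are internally
  consistent but not transferable to real proteomes.
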