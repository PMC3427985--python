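# plantpts1

Prediction of plant peroxisomal proteins carrying a type-1 peroxisome
targeting signal (PTS1), from C-terminal sequence alone.

Most peroxisomal matrix proteins are imported from the cytosol via a
C-terminal PTS1 — a domain of roughly 10–15 residues largely determined
by the final tripeptide (SKL-type motifs). Canonical tripeptides target
strongly on their own; non-canonical tripeptides (the interesting,
low-abundance cases) target only with enhancing residues upstream.
`plantpts1` implements the spermatophyte-calibrated prediction scheme
used by the first plant-specific PTS1 web service: position weight
matrix (PWM) scoring of the C-terminal 14 residues, threshold
classification, dual posterior-probability calibration, per-residue
importance highlighting, and lookup of experimentally validated plant
PTS1 tripeptides. It is aimed at plant cell biologists triaging
candidate peroxisomal proteins and at anyone studying targeting-signal
evolution across the green lineage.

## The model

For a window *w* of the last 14 residues (positions −14…−1) and a PWM
*M*, the total prediction score is additive:

```
S(w) = Σ_{p=-14}^{-1} M[p, w_p]
```

with entries estimated as pseudocount-smoothed log-odds against a
background *b*:

```
M[p, a] = log10( (c_pa + κ·b_a) / (n + κ) / b_a )
```

where `c_pa` counts residue *a* at position *p* among *n* positive
training windows and κ is the pseudocount (default 1). A sequence is
predicted peroxisomal iff `S(w) ≥ θ` (the published operating threshold
is θ = 0.412, inclusive). The score is interpreted probabilistically by
class-conditional Gaussian calibration,

```
P(PTS1 | s) = π·N(s; μ+, σ+²) / [ π·N(s; μ+, σ+²) + (1−π)·N(s; μ−, σ−²) ]
```

in two variants: the *original* scheme keeps class-specific variances;
the *balanced* scheme pools them (σ+ = σ−), which reduces to a logistic
in *s* and assigns markedly higher probabilities to atypical (non-
canonical) positives. Residues are flagged targeting-enhancing or
-inhibiting when their per-position score leaves the band mean ± SD
computed separately for the tripeptide (positions −3…−1) and upstream
(−14…−4) regions.

The trained matrix of the published service was never released, so its
printed scores ship here as benchmark fixtures; fresh matrices are
trained from user data or from the package's synthetic PTS1-like
window generator.

## Worked example

Train on 2,000 synthetic PTS1-like windows plus 2,000 background
windows, then predict a protein ending in the non-canonical tripeptide
QRL:

```python
from plantpts1 import PlantPTS1Model, render_report, synthetic

params = synthetic.default_params(n=2000, seed=1)
positives = synthetic.generate_positive_windows(params)
negatives = synthetic.generate_negative_windows(2000, seed=2)

results = PlantPTS1Model(positives, negatives).fit()
reports = results.predict(">At1g18700.2\nMGIDWSKVTPQILSSVRSMKGFQRL")
print(render_report(reports[0], "text"))
```

```
Prediction report for At1g18700.2

C-terminal 14 aa:       ILSSVRSMKGFQRL

pos  aa  score    flag
-14  I    -0.000  . neutral
-13  L    -0.000  . neutral
-12  S    -0.000  . neutral
-11  S    -0.071  . neutral
-10  V    -0.000  . neutral
 -9  R    -0.000  . neutral
 -8  S    -0.000  . neutral
 -7  M    -0.000  . neutral
 -6  K     0.382  + enhancing
 -5  G    -0.000  . neutral
 -4  F    -0.000  . neutral
 -3  Q    -0.194  . neutral
 -2  R     0.679  + enhancing
 -1  L     1.145  + enhancing

total prediction score: 1.942
decision threshold:     0.050
prediction:             peroxisomal
targeting probability:  99.9% (balanced: 99.0%)
C-terminal tripeptide:  QRL — experimentally verified (non-canonical)
```

Reading the output: the total score 1.942 clears this model's
data-driven threshold (0.050, the balanced-posterior 0.5 point), so the
sequence is predicted peroxisomal; the flags show the prediction is
carried by the C-terminal R/L and the Lys at −6, exactly the kind of
upstream enhancement non-canonical tripeptides depend on; and the
registry confirms QRL has been experimentally validated as a plant PTS1
tripeptide. `results.summary()` prints the fitted matrix and
calibration parameters.

The same pipeline is available from the shell:

```sh
plantpts1 fixtures -o work --n 2000 --seed 1
plantpts1 train work/synthetic_positives.fasta -o work/model.pwm.tsv
plantpts1 calibrate work/synthetic_positives.fasta work/synthetic_negatives.fasta \
    --pwm work/model.pwm.tsv --scheme balanced -o work/balanced.cal
plantpts1 predict query.fasta --pwm work/model.pwm.tsv \
    --calibration-balanced work/balanced.cal --format json
plantpts1 consensus orthologs.fasta --pwm work/model.pwm.tsv
```

`consensus` aggregates predictions over a user-supplied multi-FASTA of
putative orthologs — peroxisome targeting is generally conserved among
orthologs, so a majority of positive predictions strengthens an
ambiguous call.

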