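# Methods

## Evidence model and calling rules

Each cell line carries up to three evidence channels for TP53 integrity:

* **Mutation.** TP53 variant calls with HGVS protein-level notation; the
  parser classifies each change as missense, nonsense, frameshift, in-frame
  indel, splice, silent or other. The classifier is total (any string maps
  to a class; unrecognised forms fall through to `other`) so malformed rows
  degrade to warnings, never crashes. By default every non-silent
  coding/splice class is inactivating. This is deliberately permissive: a
  hotspot-agnostic policy matches how such lines are annotated in public
  panels, and the class set is a parameter for stricter policies
  (e.g. nonsense-only). Read counts are stored and reported as variant
  allele fraction but never gate a call — a 7/1 variant is still a call.
* **mRNA.** One expression value for probe set `201746_at` on the MAS5-150
  scale. Values below 32 are mRNA loss (rule R2). The borderline zone
  [32, 40) is annotation only: 8 units is wide enough to flag a value of 33
  while leaving clearly expressed lines (≥ 40) unflagged, and the flag never
  flips a call — it feeds the borderline-removal scenario instead.
* **Copy number.** Signal-intensity ratio vs normal reference, 1.0 ≈
  diploid. CN < 0.25 is bi-allelic loss and inactivates (R3); CN in
  [0.25, 0.6) is hemizygous ("allelic") loss and is annotation only, since
  one intact allele can suffice for function. No line in the reference
  evidence set is called on CN alone, so R3 is exercised by simulation.

Every cutoff is a strict inequality (expression of exactly 32 is not loss).
Status is `inactivated` iff at least one rule fires; the call object carries
the evidence set, the annotations, and a human-readable trail of every rule
tested, including rules skipped for missing evidence. Missing channels are
never imputed: a line with no channel at all is an error, a line missing
only CN simply skips the CN rules (logged). When a frameshift or nonsense
mutation co-occurs with mRNA loss the call is annotated `nmd_likely` —
nonsense-mediated decay of the mutant transcript is the parsimonious
mechanism, and the two evidence channels are then not independent.

## Normalization

All expression cutoffs are defined on the MAS5-150 scale: each sample
rescaled so its 2% trimmed mean equals 150. `trimmed_mean` drops
`floor(n·f)` order statistics from each tail (the scipy `trim_mean`
convention; ties keep their order-statistic position) and `TrimmedMeanScaler`
multiplies each sample by `target / trimmed_mean(sample)`. The operation is
idempotent, invariant to positive per-sample scaling, and rank-preserving;
the post-condition (trimmed mean equals target to 1e-9 relative) is asserted
in tests. Whether the nominal 2% is per tail or total is ambiguous in common
usage; per-tail is the default and `trim_fraction` admits the other reading.
Probe-set summarization from raw arrays is out of scope — inputs are assumed
already summarized; the module exists so simulated matrices live on the
scale the cutoff of 32 is meaningful in.

## Signature evaluation

Positive class = observed sensitive; test-positive = predicted sensitive.
(This orientation is pinned by the reference confusion table: it is the only
assignment reproducing all five published fractions simultaneously.) Metrics
are reported as exact fractions alongside floats; zero-denominator metrics
are NaN, never exceptions, and `ConfusionMetrics.exact()` exposes rational
values for identity checks. Lines missing a prediction or observation for
the evaluated compound are excluded from that scenario and listed in the
report. The standard ladder is: all lines → caller-filtered likely-WT →
likely-WT minus borderline-annotated lines; arbitrary named removals are
supported. No formal test compares PPV with the response rate — both are
reported and the judgment left to the reader. Wilson score intervals are
available as an explicit extension (`wilson_interval`), off by default.

## Synthetic cohorts

The generator draws the causal structure the evaluation assumes: latent
status ~ Bernoulli(frac_inactivated); each inactivated line gets exactly one
mechanism (mutation : mRNA-loss : CN-loss, default mix 9:2:1 — mutations
dominate in the observed evidence set; the mix is illustrative, not
inferential); mutation templates span all inactivating classes; frameshift
lines additionally lose expression with probability 0.5 (arbitrary,
configurable) to exercise the NMD path. mRNA-intact lines draw log-normal
expression (log-mean log 250 ≈ 5.5, log-sd 0.5 — a plausible spread for a
well-expressed transcript on the MAS5-150 scale), mRNA-loss lines draw
Uniform(0, 20), comfortably below the cutoff. CN is Normal(1, 0.15)
truncated at 0 for non-CN-loss lines and Uniform(0, 0.25) for CN-loss lines.
Observed sensitivity is `insensitive` for every inactivated line (the
mechanistic premise) and Bernoulli(wt_response_rate, default 0.675) for WT
lines; the signature prediction matches latent status with probability
`signature_concordance` (default 0.9) and is flipped otherwise. Defaults
encode the reference study conditions (23% inactivated in a 52-line panel,
WT response rate 0.675).

Randomness: the global seed feeds one `SeedSequence` child per line
(`spawn_key=(i,)`), so line *i*'s draws are independent of cohort size and
insertion order; identical config + seed reproduces the cohort exactly.

What the generator does **not** emulate: the 13 signature genes' expression
values (the signature enters as a binary prediction, as in the evaluation it
supports), realistic copy-number segmentation, lineage structure,
correlation between CN and expression in CN-loss lines, or assay noise in
the mutation channel. Passing tests therefore demonstrate the logic of the
proxy argument and the correctness of the pipeline — not that any particular
real signature behaves this way on data the package has not seen.

Two fixed panels are synthetic reconstructions: the 40-line likely-WT
validation set and the 113-line panel realize the published marginal counts
exactly (tp=24/fn=3/fp=11/tn=2 with DAN-G and HCC-95 as the true negatives;
29/113 inactivated with 43/84 responders) while per-line identities and
evidence values, other than DAN-G's mRNA of 33, are placeholders. Any
statistic that depends only on those marginals (all reported metrics) is
exact; per-line conclusions beyond DAN-G/HCC-95 are not meaningful on them.

## Numerical and design choices

* Trim count per side uses floor; a 17-value constant vector with any trim
  returns the constant.
* Cell-line names are joined after uppercasing and stripping spaces/hyphens
  (public tables disagree on punctuation); the original spelling is kept for
  output.
* Duplicate (cell line, compound) rows in the predictions table are a hard
  error naming the lines — silent last-wins joins hide data problems.
* Reports are byte-stable: fixed float formatting (3 decimals), sorted JSON
  keys, row order preserved from the input; thresholds in force are echoed
  into every output header so a report is interpretable without its config.
* Problem sizes in the test suite: oracle cross-checks use 200 random
  15-line cohorts; the proxy-PPV property uses one 20 000-line cohort
  (binomial SE ≈ 0.004, comfortably inside the ±0.02 band); recovery uses
  10 000 lines at 50% prevalence.

## Known limitations

* The caller is deliberately not a variant-effect predictor: a missense
  passenger counts as inactivating under the default policy. Stricter class
  sets are supported but not validated here.
* CN < 0.25 with normal expression is called inactivated; biologically this
  combination is nearly impossible (no DNA → no mRNA) and is untested by the
  reference evidence set.
* Expression-based rules presuppose correct per-sample scaling; applying the
  cutoff of 32 to a matrix not on the MAS5-150 scale is meaningless, which
  is why the scaler sits in the pipeline ahead of the caller.
* Borderline handling is a reporting device, not an inference: the zone
  width (8 units) has no statistical derivation.
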