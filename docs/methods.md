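# Methods

This note records the models, parameter choices and numerical
conventions behind the package, and what the synthetic-data tests do
and do not establish about real surveys.

## Montage geometry

Tiles are rectangles with square pixels; only the horizontal field of
view is a free parameter, the tile height following from the pixel
aspect ratio.  The coordinate frame is raster-style: origin at the
top-left corner of the top-left tile, x rightward, y downward,
micrometre units, 0-based tile indices.  Tile footprints are treated as
closed intervals, so a point exactly on a shared boundary belongs to
both tiles; the overlap fraction applies identically per axis as a
fraction of the tile extent on that axis.

Two area conventions are exposed deliberately.  The *exact* montage
area is the product of the unrounded axis extents.  The *reported*
area follows the rounding convention of survey summaries: extents
rounded to 0.1 mm, their product converted to cm² and rounded to 3
decimals per montage, and the dataset total summing the pre-rounding
products before rounding to 2 decimals.  With the default acquisition
parameters the two differ in the third decimal (0.2646 vs 0.2655 cm²
per montage; 1.85 vs 1.86 cm² over seven), and the reported convention
is what the headline figures quote.  Downstream densities use the
exact area.

## Consensus decision tree

"Same response" means exact equality on all five questionnaire fields;
count answers are binned at a drop-down cap (default 10+) before
comparison.  Matching on a field subset (e.g. occurrence only) is
available as configuration, since the strict all-fields reading is the
stronger assumption; the disagreement-reason decomposition by field is
what motivates the all-fields default.

Closure is sequential: the image closes at the first response at which
any answer-tuple reaches the quorum.  Dispute detection is order-aware
by default (a fossil report must arrive *before* a no-fossil
validation completes); an order-free mode flags any fossil report in
the stream, which is equivalent under the serving model because no
responses arrive after closure.

A stream that is not closed and shorter than `max_views` is PENDING —
a first-class outcome so the engine can run on truncated exports.
NO_AGREEMENT is declared only once `max_views` responses have arrived,
matching a serving policy in which an undecided image is always shown
to another volunteer while views remain.  The serving policy stops at
closure; how a closed image could still accumulate a fourth view (real
crowds show slightly more interactions per image than this policy
produces) is left as configuration (`max_views`) rather than guessed.

## Synthetic cohort

The generator emulates the study conditions the pipeline assumes:

- **Specimen field**: homogeneous Poisson point process, default
  density 207 specimens/cm² (≈383 specimens over 1.85 cm²), uniform
  positions, log-normal radii (median 15 µm, σ=0.35).  Real specimen
  fields may be clustered by sedimentology; clustering is not the
  default and none of the headline checks depend on spatial
  homogeneity beyond the density itself.
- **Taxon mix**: identifiable taxa at 44/20/9% for the three dominant
  groups with a tail of rarer forms, plus an indeterminable fraction
  of 83/383 ≈ 0.217.
- **Volunteers**: per-specimen detection sensitivity 0.85,
  false-positive rate 0.04 on empty images, count error ±1 with
  probability 0.10, focus-answer error 0.08, naming confusion 0.80
  correct / 0.12 "unknown" / 0.08 spread over other taxa.  The error
  rates are calibrated so the simulated flow fractions sit near the
  reference survey's (disputed ≈ 8–10%, no-agreement ≈ 6–8%, review
  queue ≈ 16–17% of images); they are a plausible operating point, not
  estimates of any real volunteer's skill.
- **Engagement skew**: activity weights are 1 + Pareto(α) with
  α = 1/(1 − ln 0.85/ln 0.10) ≈ 1.076, the closed-form tail index whose
  asymptotic Lorenz curve gives the top decile an 85% share.  At
  realistic pool sizes (~100 volunteers) and with the
  distinct-volunteers-per-image serving constraint, realized shares
  run lower (~60–70%); the qualitative property — a small core doing
  the large majority of the work — is what the tests assert.
- **Serving**: volunteers are drawn per image without replacement with
  probability proportional to activity weight; skips consume the
  volunteer but produce no response and do not count toward the
  quorum.

Passing tests on this cohort show the *decision logic* is correct and
that the pipeline recovers a known field under stated error rates;
they cannot validate taxonomic judgement, image quality effects, or
volunteer learning, none of which are modelled.

## Expert review and census

The simulated expert is an oracle over ground truth with a miss rate
(default 0 — expert review is treated as definitive) and an escalation
rate (default 0.1) routing hard detections to the palynologist.
Review workload is linear: `hours = images × seconds / 3600`, with the
browsing rate always explicit (5 s/image for estimates; observed
review of a real queue runs slower, ~7.7 s/image).

Deduplication is single-linkage within ε = 10 µm in the montage-global
frame — the order of a pollen-grain radius, so duplicate appearances
of one specimen (identical physical position, up to coordinate
round-off) merge while distinct neighbouring specimens almost never
do.  At the default density the probability that two independent
specimens fall within ε of each other is ~10⁻² per montage, a
negligible under-count; ε is configuration.  Cluster taxon is the
majority member label with ties indeterminable.  Census percentages
use identifiable specimens as the base, densities use all unique
specimens over the exact area; exact (unrounded) values are carried
alongside the reported 1-decimal densities and integer percentages so
conservation (Σ counts = identifiable, density × area = count) holds
exactly.

The overlooked-specimen estimate is the linear binomial extrapolation
`missed × total / audited` with its binomial standard error; 7 misses
in a 1000-image audit of a 25 200-image dataset extrapolates to 176 ±
67, which a survey would round to "about 200".

## Problem sizes and determinism

The default simulated survey (seven 60×60 montages, 25 200 images,
~84 000 responses) runs in a few seconds; tests use smaller montages
(10×10 to 30×30) and 5–10 seeds per stochastic check, sizes chosen so
the whole suite stays interactive while Monte-Carlo assertions retain
3-standard-error headroom.  All randomness flows from one master seed
through spawned substreams (specimen field, transcription serving,
expert review); every JSON report records the master seed, and a
repeated run is byte-identical.

## Known limitations

- Volunteers answer all five questions whenever they respond; partial
  or malformed answers occur only at ingestion (quarantined rows).
- No modelling of volunteer learning, fatigue, or image-quality
  covariates; error rates are stationary.
- The DigiVol-style column mapping is a best guess; real exports
  should supply their own schema mapping.
- Taxa are opaque labels throughout — the package counts and
  cross-tabulates but never identifies.
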