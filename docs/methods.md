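# Methods

## Measurement model

The unit of observation is a *shift-point*: one (week, day/night) occasion on
which every rostered person receives a survey listing all colleagues on that
shift. For each of three relations — general problem solving, medication
advice seeking, general socializing — respondent *i* reports how many times
they initiated communication toward colleague *j*, on an integer scale 0..10
where the top category "10+" is stored as 10 (the instrument carries no
information beyond that point). The responses form, per shift-point and
relation, a directed weighted matrix **W** with a structurally absent
diagonal.

**Missing vs. zero.** A person who returned no survey has a *missing*
outgoing row (NaN), which is distinct from an observed row of zeros.
Incoming reports toward a nonrespondent are kept. Dyads with neither
direction observed are excluded from density denominators; excluding rather
than zero-filling avoids mechanically deflating density as nonresponse
rises. Refusal and not-located are tracked separately only in the
response-rate accounting (completed B, refused C, not located D; rate
= 100·B/(B+C+D), one decimal, ties away from zero; the pooled rate uses
summed counts, not the mean of per-shift rates).

## Statistics

* **Dyadic density.** The directed matrix is dichotomized at frequency ≥ 1
  (the minimal reading of "presence") and symmetrized by the *union* rule —
  a dyad is tied if either direction reports communication. Density is the
  percentage of observable dyads tied. The union rule is the one consistent
  with counting ties "on one side of the diagonal" of a symmetrized matrix.
* **Degree centralization** uses Freeman's index on the symmetrized binary
  network, `100·Σ(d_max−d_i)/((n−1)(n−2))`, defined for n ≥ 3. The
  denominator is fixed by the worked example (n = 4 → 6).
* **In-degree centrality** is directed and uses the raw binary arc matrix:
  for member *j*, the count of senders with an observed report ≥ 1 toward
  *j*, divided by *j*'s potential senders (non-missing rows other than *j*).
  A member with no potential sender is flagged undefined (NaN), not scored 0.
  A weighted variant (summed frequencies) exists behind a flag; all printed
  statistics are binary.
* **In-degree centralization** applies the Freeman construction to raw
  in-degree counts with the standard directed denominator `(n−1)²`.
* **Stars and isolates.** Stars are *all* members attaining the maximal
  in-degree (ties are never broken arbitrarily; a network with no arcs has
  no stars). Isolates are members with no tie in the symmetrized network.

## QAP

The association between two relations on the same roster is the Pearson
correlation over jointly observed off-diagonal cells of the weighted
matrices (a binary mode is available by flag; weighted is the default since
dichotomization would discard the frequency information the instrument
collects). Significance comes from the restricted permutation test: a node
relabeling π is applied to rows and columns of one matrix simultaneously,
preserving its internal autocorrelation. Nodes carry their missingness with
them; cells are re-masked after each alignment.

* For n ≤ 7 the full permutation group is enumerated and p is the exact
  proportion of relabelings at least as extreme (the identity guarantees
  p > 0).
* Otherwise B uniform relabelings are sampled (default B = 1000, floor 99)
  and p = (1 + #extreme)/(1 + B), the standard conservative Monte-Carlo
  convention. Two-sided p = min(1, 2·min(p_ge, p_le)); both tails are
  always reported, along with the seed and method, so every result is
  reproducible.
* Degenerate alignments (fewer than 3 joint cells, or zero variance) are
  dropped from the reference set; shift-points whose observed correlation
  is undefined are reported as skipped, never silently omitted.

## Synthetic study generator

The generator emulates the study design: `n_weeks` = 12 weeks × {day,
night}, default 19 people per shift across nine roles (AMD 2, RMD 3, SRN 6,
TRN 1, TRAMRN 1, CRN 1, PCT 3, HUC 1, RC 1), sampled each shift-point from
a fixed per-role pool (`pool_multiplier` = 5× the head-count) so that
repeat-respondent structure arises naturally.

Tie indicators are Bernoulli with log-odds

```
base_logit[r] + s_i + s_j + overlap_lambda[r]·z_ij + night·night_density_offset
```

where `s ~ N(0, sociability_sd²)` is a per-person latent fixed for the whole
study, and `z_ij = z_ji ~ N(0,1)` is a dyad-level factor drawn per
shift-point and *shared across the three relations* — the product
`overlap_lambda[r1]·overlap_lambda[r2]` controls the inter-relation QAP
correlation. Present ties get integer weights `1 + Poisson(weight_mean − 1)`
capped at 10. Each person independently returns no survey with probability
`nonresponse_rate`.

Default values and why:

| parameter | default | rationale |
|---|---|---|
| `base_logit` | −0.7 / −2.5 / −0.2 (problem solving / medication advice / socializing) | places dyadic densities in the ranges reported for emergency-department teams: socializing densest, medication advice far sparser |
| `night_density_offset` | 0.6 | night densities consistently above day, as observed in this setting |
| `sociability_sd` | 0.7 | produces the degree heterogeneity (hence nonzero centralization and identifiable stars) real teams show |
| `overlap_lambda` | 0.8 per relation | moderate inter-relation correlation (QAP r roughly 0.1–0.5) |
| `weight_mean` | 3.0 | reported frequencies cluster at a few contacts per shift |
| `nonresponse_rate` | 0.18 | matches an 82% response-rate regime |

This is the simplest mechanism that *independently* controls density
(base_logit), degree heterogeneity (sociability), inter-relation overlap
(lambda), and the day/night contrast. A calibration utility
(`calibrate_overlap_lambda`) bisects on a Monte-Carlo estimate of the mean
inter-relation correlation (common random numbers across evaluations) to
hit a target r, e.g. 0.4; recovery is checked on an independently seeded
24-shift-point panel.

What the generator does **not** emulate: shift-length or patient-arrival
dynamics, content of communication, role-specific mixing preferences
(e.g. nurses preferentially consulting physicians for medication advice),
or any demographic covariates. The weight distribution is a stand-in: the
instrument defines only the 0–10+ scale, and no distributional facts about
reported frequencies are available, so a truncated shifted Poisson was
chosen as a one-parameter family on 1..10. Passing tests therefore show the
*pipeline* is correct under a plausible data-generating process, not that
real survey data follow this process.

**Independence caveat.** With `overlap_lambda = 0` the relations still share
the per-person sociability term, which is genuine association (and QAP
correctly detects it). The type-I calibration of the QAP test therefore
switches off *both* couplings (`overlap_lambda = 0` and
`sociability_sd = 0`), which is the configuration under which the relations
are actually independent.

## Numerical and reporting conventions

* Percentages print at one decimal, ties rounded away from zero (matching
  survey-table conventions); centralization in the worked example prints at
  two decimals.
* Quartiles in boxplot summaries use inclusive linear interpolation
  (numpy's `linear`, R type 7); the even-count median is the midpoint of
  the central pair. The convention is recorded in output metadata.
* Sociogram node size is the affine map `8 + 40·in_degree` (in-degree
  normalized to [0, 1]); edge width `0.5 + 0.35·frequency`. Both are
  strictly increasing, which is all the visualization claims. Canonical
  sociogram outputs are GraphML and DOT with full attributes; PNG rendering
  is an optional layer. Layouts are seeded; isolates are placed in a
  separate group apart from the connected component.
* All randomness flows through explicit integer seeds; derived seeds come
  from `SeedSequence` keyed by (seed, stage tags) and every stochastic
  output records its seed. Identical configurations reproduce datasets
  bit-for-bit.
* Simulation-backed checks use deliberately moderate problem sizes (e.g.
  500 replicate shift-pairs with 499 permutations for the type-I
  calibration, 48 replicates per calibration evaluation, 10,000
  permutations against exhaustive enumeration on rosters of 4–6); at these
  sizes the Monte-Carlo envelopes quoted in the tests are comfortably
  wider than the residual simulation error.

## Known limitations

* The union dichotomization and ≥ 1 threshold are choices; a stricter
  threshold or intersection rule would lower density. Both are parameters.
* In-degree centralization's `(n−1)²` denominator is the standard directed
  Freeman normalization; other software occasionally normalizes by
  `(n−1)(n−2)` even for directed in-degree, which would scale values by
  `(n−1)/(n−2)`.
* QAP on weighted matrices treats the 0–10+ scale as interval; the binary
  flag is the conservative alternative.
* With heavy nonresponse, pairwise-complete masks shrink and permutation
  reference sets can become noisy for small rosters; the package reports
  effective permutation counts rather than hiding the loss.
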