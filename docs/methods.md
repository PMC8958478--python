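# Methods

## The measurement model

Each primary-care practice team is observed through a sociometric roster:
every responding member marks, separately for type 2 diabetes (DM), coronary
heart disease (CHD) and chronic heart failure (CHF), the colleagues with whom
they exchange patient information at least once a week. This yields three
directed nomination networks per practice whose node set is the full roster —
non-respondents stay in the network and can receive nominations, they just
cannot send any.

The analysis proceeds in three gated phases:

1. **Validation.** Reciprocity — the fraction of directed ties between two
   respondents whose reverse tie also exists — is pooled over all included
   practices and conditions. Ties pointing at a non-respondent are excluded
   from numerator *and* denominator: the reverse nomination is unobservable
   by design, and counting such ties as unreciprocated would bias the gate
   downward in exactly the practices the missing-data rule is meant to
   protect. Undirected analysis proceeds only if pooled reciprocity is
   *strictly above* 0.6; at or below, the pipeline stops with diagnostics
   (CLI exit status 3). An undefined reciprocity (no assessable ties at all)
   is an error, never a silent pass. Pooled reciprocity over *all* practices
   is reported alongside for transparency, but the gate uses the included
   set, since that is the set the undirected reconstruction will be applied
   to.
2. **Reconstruction.** Directed networks are symmetrized with the union
   (weak) rule: an undirected edge exists wherever at least one direction was
   reported. For a practice with a single non-respondent this simultaneously
   reconstructs their edges from incoming nominations, which is why the
   inclusion rule (at least three members, at most one non-respondent)
   and the union rule belong together. An intersection (strong) rule is
   available as a sensitivity option; it necessarily discards every edge
   involving a non-respondent. Practices violating both inclusion rules are
   reported as `too_few_members` — size is the more fundamental defect.
3. **Typology and statistics**, described below.

## Network metrics

For an undirected network on `n` nodes with edge set `E`:

- number of connections `|E|`;
- density `|E| / (n(n-1)/2)`, defined for `n >= 2`;
- Freeman degree centralization `sum_i(d_max - d_i) / ((n-1)(n-2))`, defined
  for `n >= 3`; 0 for any regular network (complete or empty), exactly 1 for
  a star. The degree variant is used because the survey question is about
  being centred on a single person and the analysed networks are undirected;
  betweenness/closeness centralization are out of scope.

Metrics on smaller networks raise an error rather than returning 0, so
excluded practices can never leak into summaries as silent zeros.

## Typology

Density and centralization are banded low (<= 0.33), medium (> 0.33 and
<= 0.67) and high (> 0.67); the thresholds carry an absolute tolerance of
1e-9 so that exact rationals (1/3, 2/3 — ubiquitous degree-sum artefacts in
networks of 3-7 people) are banded by their decimal value, e.g. 2/3 = 0.6667
is medium. Bands are applied to raw metric values, not to rounded ones.
The band pair maps to the four types: A (high density — low hierarchy follows
in the data), B (medium/medium), C (medium/low), D (low density). Band pairs
outside this table — medium density with high centralization, or high
density with medium centralization, both attainable in very small networks —
are reported as `unmapped` rather than forced into a neighbouring type: the
typology is data-driven and forcing would misrepresent it. Networks of
density exactly 1 are flagged `fully_connected`, a special case of type A.

## Cohort statistics

- Per-condition summaries over included practices: mean with sample SD
  (n-1 denominator), median with IQR (25th-75th percentile, linear
  interpolation), and the summed connection count. Undefined reciprocities
  are skipped with the effective n reported.
- **Friedman test** comparing the three conditions measured on the same
  practices: within-row mid-ranks, statistic
  `chi2 = [12/(n k(k+1))] sum_j R_j^2 - 3n(k+1)` divided by the tie
  correction `1 - sum(t^3 - t)/(n k(k^2-1))`, referred to the asymptotic
  chi-square distribution with k-1 df. Tie correction matters here because
  density ties at 1.0 are frequent; without it the statistic is
  systematically deflated. When every row is completely tied the statistic
  is 0 and p = 1. Rows with a missing condition value are dropped with a
  warning. The asymptotic (not exact-permutation) distribution is used and
  documented; at 25 blocks the null rejection rate at alpha = 0.05 is within
  [0.03, 0.07] (checked by simulation in the test suite).
- **Spearman rank correlation** (mid-ranks, t-approximation p-value, via
  scipy) between density and centralization per condition; a constant input
  vector is an explicit error, not rho = 0. Pearson is deliberately not
  offered for this output.
- External-exchange tabulation: per occupational group x condition x stratum
  (overall / physicians / practice assistants), count and percentage of
  *responding individuals* — the denominator is respondents, not practices.
- Cardiologist contacts (CHD, CHF): practice-level mean of member means
  (members with missing counts excluded, practices with no observed count
  excluded), role-stratified individual means, and the raw count range.

Rounding conventions in emitted tables: percentages and means to one or two
decimals, SDs to two — raw values are kept in the in-memory objects.

## The synthetic cohort generator

No roster data are publicly deposited, so the generator emulates the study
conditions and is the substrate for every end-to-end test:

| parameter | default | rationale |
|---|---|---|
| `n_practices` | 40 | cohort size of the study |
| `size_range` | 3-7 | member counts of analysable practices (cohort overall spans 2-15) |
| `two_physician_prob` | 0.3 | mean physician count ~1.3 per practice |
| `tie_prob` | 0.58 | DM nomination probability per ordered pair; union edge probability `1-(1-p)^2 ≈ 0.82`, the observed DM mean density |
| `recip_boost` | 0.30 | probability an unreturned nomination is mirrored; gives pooled reciprocity ≈ 0.70 across the three conditions |
| `retention` | (0.93, 0.93) | per-tie thinning DM→CHD→CHF; expected densities ≈ 0.82/0.80/0.77, reproducing the observed ordering |
| `hub_bias`, `hub_fraction` | 1.5, 0.2 | a physician hub with boosted tie odds in a fifth of practices, matching the minority of medium-centralized networks |
| `nonresponse_prob` | 0.2 | individual response ≈ 74-80%; makes the inclusion filter bite realistically |
| `cardiologist_p_*` | 0.75 / 0.45 | binomial(5, p) counts: physician mean ≈ 3.8, assistant ≈ 2.3 |

Draw order is fixed and documented in the module docstring; each practice
consumes its own PCG64 stream spawned from the master seed, so extending the
cohort never perturbs existing practices and identical configs are
byte-identical on disk.

Nesting (CHF ties ⊆ CHD ⊆ DM) is a modelling choice motivated by diabetes
involving the most team members; it implies the per-practice density ordering
DM >= CHD >= CHF by construction. An `retention="independent"` mode draws the
three conditions independently for sensitivity work.

Closed form used to verify the generator: a pair ends mutual with probability
`P2 = p^2 + 2p(1-p)r` and one-way with `P1 = 2p(1-p)(1-r)`, so the DM edge
probability is `1-(1-p)^2` independent of the reciprocation boost (the boost
only mirrors an existing nomination). Thinning with retention `rho` maps
`P2 -> P2 rho^2`, `P1 -> 2 P2 rho(1-rho) + P1 rho`; the CHD/CHF edge
probabilities apply the map once resp. twice. Monte-Carlo agreement within
three binomial standard errors is asserted in the tests.

### Band calibration

`calibrate_to_bands` returns presets fixed by a pilot Monte Carlo (2,000
practices per candidate, classification on the DM network):

| target | preset | achieved band-pair probability |
|---|---|---|
| A (high/low) | tie_prob 0.95, no hub, sizes 3-7 | ~0.99 |
| D (low/low) | tie_prob 0.025, no hub, sizes 3-7 | ~0.97 |
| B (medium/medium) | tie_prob 0.2, hub bias 3 in every practice, sizes 12-15 | ~0.84 |
| C (medium/low) | tie_prob 0.33, no hub, sizes 12-15 | ~0.83 |

With independently drawn ties, joint band targeting for B and C is
intrinsically noisy: centralization of a random medium-density network only
concentrates as the practice grows, and at sizes 3-7 the achievable rates
are ~0.55 (B) and ~0.24 (C). The B/C presets therefore use the largest
practice sizes observed in the cohort overall; their target type is always
the modal classification, but they do not reach the >= 0.9 recovery that A
and D do. This is a limitation of Bernoulli tie generation, not of the
classifier.

### What the generator does and does not emulate

It reproduces roster structure, non-response mechanics, density/reciprocity/
centralization levels, condition nesting, metadata frequencies and
external-exchange margins. It does **not** model role-assortative
nomination (beyond the hub being a physician), correlation between a
member's answers across conditions' external groups, practice-level random
effects in response propensity, or any association between metadata and
network structure. Passing tests therefore certify the pipeline's
correctness and its behaviour under realistic sampling noise — not that
real practice networks follow an independent-tie model.

## Numerical and degenerate-input choices

- Band thresholds: absolute 1e-9 tolerance, see above.
- Friedman with all rows tied: statistic 0, p 1 (rather than 0/0).
- Reciprocity gate at exactly the threshold: stop (strict inequality).
- Non-respondent with no incoming nominations: kept as an isolated node,
  lowering density — the roster, not the tie list, is the node universe.
- Quantiles: linear interpolation (numpy default), chosen to match the
  convention most statistics packages print.
- Problem sizes in the test suite: the oracle sweep uses 10,000 random
  graphs on up to 6 nodes; calibration recovery uses 200 practices per
  target; Friedman null calibration uses 2,000 simulated 25-practice
  cohorts. These sizes give Monte-Carlo error comfortably inside the
  asserted bounds while keeping the default suite fast.

## Known limitations

- The typology's `unmapped` cell is common in synthetic networks of 3-4
  members (where centralization 1/3 sits just above the 0.33 cut); studies
  applying the cut-offs to 2-decimal rounded values would band these as low.
  The package bands raw values and documents the difference.
- Inclusion is practice-level (member and non-respondent counts do not vary
  by condition); a member who answered only some conditions is not modelled.
- The Friedman p-values are asymptotic; for very small included cohorts an
  exact permutation test would be preferable.
- `summarize_practice_characteristics` bands team meetings at >4 per
  quarter; other descriptive conventions follow the emitted-table rounding
  noted above.
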