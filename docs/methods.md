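# Methods

## The analysis chain

The package operationalises a single-round Delphi survey analysis for a
criterion framework, followed by a multi-criteria performance assessment of
candidate devices. Inputs are (a) a criterion codebook — an ordered
hierarchy of domains and criteria with status and discriminatory flags —
(b) a panellist × criterion table of 5-point Likert ratings with explicit
"Do not know" missingness, and (c) optionally a device × criterion
traffic-light matrix. The stages and the statistics they compute are
described below, together with the choices that were genuinely open and how
they were resolved.

## Consensus (interquartile distance)

For each criterion the first and third quartiles of the non-missing ratings
give Δ = Q3 − Q1, graded as full (Δ = 0), fair (0 < Δ ≤ 1), sufficient
(1 < Δ ≤ 2) and none (Δ > 2). Two boundary decisions are pinned explicitly
because the conventional prose statements of these bands overlap at Δ = 1:
the boundary belongs to the *stronger* class (fair), and Δ > 2 — which the
banding leaves unnamed — is labelled "none". The stopping rule requires no
further survey round exactly when every criterion's label is at least
sufficient.

Quartiles of n ≈ 25 ordinal values depend visibly on the quantile
convention, so it is a parameter rather than a hidden constant:
`linear` (interpolation at positions p·(n − 1), the numpy/R-type-7 default),
`nearest` (closest order statistic) and `spss` (interpolation at (n + 1)·p).
The default is `linear`; the tests exercise cases where the conventions
disagree so the sensitivity is surfaced rather than hidden.

New-criterion inclusion uses a support threshold of 30 % of respondents,
with the denominator supplied explicitly by the caller: open questions are
typically answered by a subset of the panel, and the package does not try
to infer which subset.

## Polychoric correlation and ordinal alpha

Likert ratings are modelled as discretisations of a latent standard
bivariate normal. The polychoric correlation is estimated in two steps:
thresholds from the inverse-normal of each variable's cumulative marginal
proportions, then a bounded 1-D maximisation of the contingency-table
log-likelihood over ρ ∈ (−1, 1) (`scipy.optimize.minimize_scalar`,
tolerance 1e−6). Two-step estimation was chosen over joint ML because it is
the standard fast estimator and is statistically adequate at the sample
sizes involved (n ≈ 25–2000); it is an approximation to joint ML and is
documented as such. Numerical guards: cell probabilities are floored at
1e−12 before the log; ρ is clamped to ±(1 − 1e−6); unobserved categories
are collapsed before thresholding; a constant variable raises a
degenerate-marginal error; fewer than 10 complete pairs attaches a warning
to the estimate. Bivariate rectangle probabilities come from
`scipy.stats.multivariate_normal`.

Domain reliability applies the standardised (correlation-based) Cronbach
form to the polychoric matrix: α = k·r̄ / (1 + (k − 1)·r̄), with r̄ the mean
off-diagonal entry. The form is pinned explicitly because "ordinal alpha"
is sometimes computed from a factor loading instead; the standardised form
is the direct analogue of Cronbach alpha on a correlation matrix and is
monotone in both r̄ and k, properties the tests verify. Interpretation
bands: Excellent [0.9, ∞), Good [0.8, 0.9), Acceptable [0.7, 0.8),
Questionable [0.6, 0.7), Poor (0.5, 0.6), Unacceptable (−∞, 0.5]. The
assignment of α = 0.5 to Unacceptable resolves an overlap in the
conventional banding.

Missing data are deleted listwise within each domain before reliability
computation, so a domain's reply count equals its complete-case panellists
(a single high-missingness criterion therefore depresses its whole domain's
count, the realistic behaviour). Alpha-if-item-dropped recomputes α on each
(k − 1)-item submatrix; an item is flagged when its omission raises α by
more than a margin (default 0.05 — an artifact parameter with no canonical
value; it exists to keep sampling noise from flagging items in healthy
domains). The derived exclusion rule removes a flagged item only in domains
whose full α is below the Acceptable band (0.7).

## Relative Index and subclasses

RI = Σᵢ wᵢfᵢ / N with wᵢ = i/5, frequencies fᵢ over ratings i = 1..5 and
N = Σfᵢ (missing excluded); RI ∈ [0.2, 1] whenever N ≥ 1. Criteria are
sorted by decreasing RI with deterministic id-order tie-breaks. The
Fundamental/Important/Relevant cutpoints have no canonical published
values; the defaults (0.8, 0.7) are exposed as an explicit parameter and
any scientific use should set them deliberately.

## Goodman–Kruskal gamma

γ = (SOP − IOP)/(SOP + IOP) over all C(n, 2) observation pairs; pairs tied
on either variable count in neither term, and SOP + IOP = 0 yields an
explicitly undefined result rather than an exception. Significance uses
the normal approximation z = γ·√((SOP + IOP)/(n·(1 − γ²))), two-sided,
with γ clamped to ±(1 − 1e−9) when |γ| = 1; a permutation p-value
(exhaustive over all n! orderings for n ≤ 8, Monte-Carlo beyond) is
available as the small-sample alternative and serves as the oracle in
tests. A pair is reported "strong" when |γ| > 0.5 *and* p < 0.05. Screening
is within-domain only and uses pairwise-complete observations — a
deliberate asymmetry with the listwise reliability stage, since gamma is a
pairwise statistic and listwise deletion would discard usable pairs. No
multiple-testing correction is applied; the screen is descriptive, and
adding one silently would change the reported flags.

## Framework assembly

Reliability exclusions are applied before importance exclusions (the order
is immaterial when the flags are disjoint but is pinned for determinism).
The importance-discard rule flags a criterion whose consensus median is
exactly 3 — the scale midpoint ("Middle") — with an optional RI floor (off
by default) that can spare high-RI midpoint criteria. A-posteriori criteria
are retained-but-unranked: they carry no survey statistics and no imputed
ones. The discriminatory subset is the retained set minus all cost- and
lifetime-domain criteria. Per-domain RI is reported as the mean RI of the
domain's retained, ranked criteria.

## Device assessment

Missing cells resolve to red (worst case) before any computation; the
resolution is idempotent and the count of resolved cells is reported. A
criterion is selected when green in at least ⌈fraction · n_devices⌉
devices (default fraction 5/8, so the canonical 8-device case needs 5).
"Prevalently coded" is interpreted as the modal colour of a device's row,
with ties resolved to the worse class — consistent with the precautionary
missing-data rule. Both read-outs are monotone under recolouring red →
green, a property the tests check over random matrices. An optional
comparative scorer maps {lower, similar, higher}-than-reference tokens to
colours for cost (lower = green) and lifetime (higher = green) criteria;
it is off by default because those domains are non-discriminatory without
a reference device.

The bundled `who_devices.csv` fixture transcribes only the device names and
the handful of colours the public record states (the pulse oximeter's
yellow "End users' background" and green "Training needs"); every other
cell is missing and resolves to red. Assessment outcomes on this fixture
are therefore dominated by the precautionary rule and are not a
reproduction of the original 8-device analysis, whose full colour matrix
is not public.

## Synthetic panel model

The generator draws latent traits from a multivariate standard normal with
block-diagonal correlation: one exchangeable block per domain (parameter
`within_domain_rho`), with optional per-criterion contamination that sets a
single item's correlation to all its siblings (used to plant a negatively
keyed item). Blocks are validated for positive semi-definiteness and
factored by eigendecomposition (tolerating the PSD-but-singular edge).
Latent values are cut at four strictly increasing per-criterion thresholds
into categories 1–5; "Do not know" cells are MCAR with a scalar or
per-criterion rate. Everything is driven by one `numpy` Generator seeded
with a single integer, so a (spec, seed) pair reproduces a table exactly.

Default study conditions (`study_panel_spec`): 25 panellists over the 25
surveyed criteria in 7 domains; latent ρ = 0.7 within every domain;
criterion 1.2 planted at −0.3 to its domain (the easiness-of-use analogue
that wrecks the user-type scale); a 20 % DNK rate on criterion 4.5 over a
1 % background, so its domain keeps roughly 20 of 25 complete cases.
Default thresholds put approximately 2/6/17/35/40 % of mass on ratings
1–5 (mean rating ≈ 4.05, RI ≈ 0.81), matching the high importance ratings
such expert panels produce.

What the simulator does *not* model — and what passing tests therefore do
not establish about real panels: panellist covariates and rater effects,
round-to-round opinion shift, informative ("I don't know this topic")
missingness, within-panellist response styles (acquiescence, extreme
responding), and open-question participation. Recovery results (polychoric,
alpha, gamma screens) certify the estimators under their own generative
assumptions, not robustness to violations of them.

## Problem sizes in tests and the acceptance script

The test suite runs the polychoric recovery study at its full size
(5 latent correlations × 100 replicates at n = 2000) and the contamination
study at 100 replicates of n = 200. The acceptance script reports the same
two rates at reduced replicate counts (20 and 50 per condition) — sizes
chosen so a complete from-scratch rerun stays in the seconds range while
the binomial noise on the reported percentages stays below a few points.
The recovery rate is reported pooled over the five latent-correlation
conditions: at ρ = 0 the two-step estimator's sampling spread at n = 2000
places ±0.05 almost exactly at its 95 % quantile, so the per-condition
rate hovers at the boundary by construction while the pooled rate sits
near 98 %.

## Known limitations

- Single-round orchestration: the stopping rule is evaluated and reported,
  but multi-round response merging is out of scope.
- No confidence intervals on alpha, no factor-analytic reliability, no
  polyserial correlations.
- The gamma normal-approximation p-value is anticonservative for very
  small n with |γ| near 1; use the permutation option there.
- Numerical equality with any specific published survey's coefficients is
  not claimable without that survey's raw responses; the package's claims
  are structural (arithmetic identities, oracle equivalences) and
  behavioural (parameter recovery under the stated model).
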