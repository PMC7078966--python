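# Methods

## Model

NMA summary output is modelled as μ<sub>i</sub> ~ N(μ̂<sub>i</sub>, s<sub>i</sub>²)
for the effect of each treatment *i* versus a reference, jointly as a
multivariate normal with covariance Σ (reference row/column exactly zero).
Pairwise contrasts inherit d<sub>ij</sub> = μ̂<sub>i</sub> − μ̂<sub>j</sub> and
s<sub>ij</sub>² = Σ<sub>ii</sub> + Σ<sub>jj</sub> − 2Σ<sub>ij</sub>. All metrics are
functionals of this normal approximation; nothing here estimates the NMA
itself (no heterogeneity, inconsistency or arm-level modelling), and the
reference is ranked as an ordinary competitor.

Two input representations are supported. The basic-parameter form carries
(μ̂, Σ) directly. The league-table form carries all pairwise (d<sub>ij</sub>,
s<sub>ij</sub>); its pairwise SEs are authoritative for analytic scoring,
while a full Σ is reconstructed (μ̂<sub>i</sub> = d<sub>iR</sub>,
Σ<sub>ii</sub> = s<sub>iR</sub>², Σ<sub>ij</sub> from the pairwise-variance
identity) because rank simulation needs it. Published tables are rounded,
so reconstruction accepts eigenvalues down to −10⁻⁸ of the largest
(clipped to zero) and rejects anything worse, reporting the smallest
eigenvalue.

## Orientation and effect scales

Internally every outcome is put on a larger-is-better scale exactly once:
`orient` negates μ̂ for lower-is-better outcomes (Σ is invariant under a
global sign flip) and a guard flag makes double orientation an error. CIVs
in configurations are declared on the published scale and re-signed with
the outcome; on the oriented scale the pairwise certainty is always
Φ((d − civ)/s), so a positive civ demands a benefit margin and a negative
civ tolerates a deficit. Log odds-ratios are rescaled to SMD by √3/π — the
logistic/normal standard-deviation ratio — and, the map being linear, the
covariance is rescaled by its square; whether the original analysis
rescaled its covariance the same way is not documented anywhere we know
of, so this is stated as an assumption. Between-outcome correlation
matrices are interpreted on the oriented scale.

## Ranking metrics

- `pairwise_prob(d, s, civ)` = Φ((d − civ)/s).
- `pscores` averages pairwise certainties over competitors with equal
  weights. At civ = 0 each pair's two certainties sum to one, so the mean
  P-score across treatments is exactly ½ — an identity the tests assert on
  every generated instance.
- `simulate_ranks` draws from N(μ̂, Σ) (eigendecomposition factor; zero
  eigenvalues allowed, negatives clipped as rounding noise), ranks each
  draw best-first and tallies an I×I doubly-stochastic matrix. Exact ties
  arise only under degenerate Σ and are broken by an independent uniform
  key, i.e. a uniformly random permutation of the tied set. Default
  100 000 draws (Monte-Carlo SE ≈ 0.0016 on a probability); the seed is a
  required argument of the API and defaults to 42 in the CLI, which logs
  it. Ranks are 1-based, 1 = best.
- `sucra` sums the cumulative rank distribution; it equals
  (I − E[rank])/(I − 1) algebraically and the implementation asserts that
  identity at 10⁻¹². SUCRA here is always computed from a simulated rank
  distribution (the frequentist path); P-scores are its analytic
  equivalent and the suite checks their agreement within
  3·√(0.25/n_samples).

## CIV curves and crossings

Curves are computed analytically (never by simulation) column-by-column
over a strictly increasing CIV grid; monotonicity (non-increasing in the
CIV) is asserted on every run. Crossings of two curves are sign changes of
their difference between adjacent grid points, located by linear
interpolation; a sign change through an exact zero at a grid point is
reported at that point, and touching without a sign change is not a
crossing. The default grid step is 0.05 on the SMD scale — fine enough
that halving it moves interpolated crossings by less than one original
step (tested). A scalar CIV applies uniformly to all comparisons; the API
accepts per-outcome vectors in the joint case but not per-pair matrices.

## Multiple outcomes

The joint certainty that *i* beats *j* on all K outcomes is
Φ<sub>K</sub> evaluated at upper limits (d<sub>ij</sub><sup>k</sup> − civ<sub>k</sub>)/s<sub>ij</sub><sup>k</sup>
with the between-outcome correlation matrix ρ — the same ρ for every
treatment pair, since the formulation admits no pair-specific correlation.
ρ cannot be estimated from outcome-specific NMA fits; `correlation_strategy`
supports the three practical stances (zero / fixed expert-informed matrix /
sensitivity range over a single off-diagonal for K = 2). The label
"between-study correlation" is used in this literature for what is
operationally the correlation of the standardized summary contrasts; we
implement the formula as written and flag the conflation here without
resolving it.

Numerics: K = 1 uses the univariate CDF; K = 2 scipy's deterministic
bivariate algorithm (singular ρ = ±1 handled exactly); K ≥ 3 scipy's
numerical integration with absolute tolerance 10⁻⁶ and a fixed integration
rng so repeated calls agree to that tolerance. K is capped at 6; beyond
that the integration scheme would need rethinking. Benefit–risk curves fix
the benefit CIV, sweep the risk tolerance, and reuse the crossing
machinery on the two-outcome joint scores.

## Synthetic networks and oracles

`generate_network` draws true effects uniformly in ±0.6 SMD with
per-treatment SEs in 0.05–0.3 — the dynamic range typical of drug-class
networks, chosen so CIV curves show realistic curvature — and builds each
Σ as a star geometry (independent basic parameters) plus a shared rank-one
component carrying 30 % of each variance, which is PSD by construction and
mimics the correlation a common comparator induces. The packaged example
network (`data/antipsychotics_like.json`, 16 treatments, 3 outcomes,
seed 2019) is generated this way with an illustrative correlation matrix
(+0.5 between the two benefit-type outcomes, −0.5 of each against the
harm); it is clearly labelled synthetic and stands in for real estimates
in docs and examples.

What the generator does *not* emulate: heterogeneity and inconsistency in
the evidence network, non-normal sampling error, sparse or disconnected
geometries, and correlation structure estimated from data. Passing tests
therefore validate the ranking mathematics on well-specified normal
summaries, not the upstream NMA estimation.

`mc_joint_prob_oracle` is the brute-force cross-check: it samples contrast
vectors X<sub>k</sub> = d<sub>k</sub> + s<sub>k</sub>Z<sub>k</sub>, Z ~ N(0, ρ), and counts
the fraction satisfying all shifted inequalities. Its standard error is
Agresti–Coull (add-two) rather than the plain binomial SE so that
"within 3 SE" stays a meaningful criterion when the empirical fraction
hits 0 or 1 in the tails. The suite compares the analytic orthant
probabilities against this oracle on batches of random configurations at
n = 10⁵–10⁶ with fixed seeds.

## Problem sizes and determinism

The default test run simulates at most 100 000 draws per network and
twenty networks per equivalence check, keeping the whole suite within a
few minutes on one CPU while leaving Monte-Carlo tolerances
(3·√(0.25/n) ≈ 0.0047) well above integration error. Every stochastic
path takes an explicit seed: rank simulation is bit-reproducible per seed,
the K ≥ 3 CDF uses a fixed internal rng, and the acceptance script derives
all randomness from its `--seed` argument.

## Known limitations

- Rankings inherit every bias of the input estimates; no risk-of-bias or
  confidence weighting is applied.
- CIV values are taken as given; eliciting them, and mapping them across
  effect measures, is out of scope.
- The joint P-score summarises "better on all outcomes"; treatments with
  very different benefit/harm profiles can still produce similar scores,
  so per-outcome results should be read alongside it.
- No inference on the ranking metrics themselves (no CIs for SUCRA or
  P-scores).
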