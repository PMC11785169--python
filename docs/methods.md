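# Methods

## The observable and its symmetry

The raw observable is the output of a symmetry-expanded, per-subunit
focused 3D classification of a homotetrameric channel: one hard state
label per subunit particle — resting (R), activated (A), or disordered
(D) when the intracellular domain is too broken to classify — keyed by
parent tetramer and ring position. Because the four chains are
chemically identical and the particle has no marked subunit, two
per-tetramer state vectors related by a rotation of the ring are the
same physical observation. The equivalence group is the cyclic group Cn
only: cryo-EM particles have fixed handedness, so reflections are not
quotiented out. For two states on C4 this gives six classes (the
Burnside count (1/n) Σ_{d|n} φ(d) k^{n/d} with n=4, k=2), with orbit
sizes (1, 4, 4, 2, 4, 1).

Two conventions are fixed once and attached to all downstream output:

* **Canonical form** is the lexicographically minimal rotation under
  the declared alphabet order (A before R), making tie-breaks
  deterministic; ring positions are 0-based and only adjacency matters.
* **ortho / para**: `2R2A_ortho` denotes the two activated subunits
  *adjacent* (90°-related), `2R2A_para` the diagonal placement (180°).
  The reverse reading of "orthogonal" is defensible; any statistic that
  depends on the split (notably the coupling estimate below) carries
  this convention.

## Trace-back and the intactness rule

Subunit records are grouped by tetramer id and ordered by ring
position. A tetramer is *intact* iff all n subunits are present and
none is D; every statistic operates on intact tetramers only, and the
assembled output always conserves counts (intact + excluded = input).
Classification posteriors, when present, are carried through but
ignored by default; an optional threshold demotes low-confidence labels
to D before assembly (default: no thresholding, since hard-assignment
classification pipelines typically publish none).

## Occupancy statistics

For a spectrum with class counts n_c (N = Σ n_c, a_c activated
subunits per class):

* subunit activated fraction p = Σ a_c n_c / (nN);
* occupancy tail P(≥k) = Σ_{a_c ≥ k} n_c / N, non-increasing in k with
  P(≥0) = 1;
* fold changes are plain ratios of either statistic between conditions
  (undefined, by error, when the reference is zero — report a one-sided
  interval bound instead).

Percentages quoted for comparison with published figures are rounded
half-up to integer percent, matching the reporting granularity of such
studies; raw fractions are always retained in machine output.

Uncertainty: the tetramer, not the subunit, is the independent sampling
unit, so the default interval is a percentile bootstrap that resamples
tetramers with replacement (equivalently, a multinomial redraw of the
class counts — exact and O(B·6) regardless of N), B = 2000 with a fixed
default seed (20250124). Goodman's closed-form simultaneous multinomial
intervals (quadratic inversion with a Bonferroni-adjusted χ²(1)
quantile) are offered for the class fractions.

## Equilibrium layer

Treating each subunit as a two-state system, K = p/(1−p) and
ΔG = −RT ln K (R = 8.314 J mol⁻¹ K⁻¹, T(K) = T(°C) + 273.15), with a
two-temperature van't Hoff enthalpy
ΔH = R ln(K₂/K₁)/(1/T₁ − 1/T₂), kJ/mol. These are descriptive
summaries of the conformational-selection picture — stimuli shift a
pre-existing resting ⇌ activated population equilibrium — not claims of
ideal two-state thermodynamics; ΔH in particular assumes a constant
enthalpy over the temperature pair and ignores the inter-subunit
coupling quantified below. Boundary fractions (p ∈ {0,1}) raise rather
than clip.

## Nearest-neighbour coupling model

Arrangement probabilities follow a ring Ising form with s_i ∈ {0,1}
(1 = activated):

    P(s) = exp(h Σ s_i + J Σ s_i s_{i+1 mod n}) / Z.

The {0,1} spin convention puts the field on the activated state, so
p = expit(h) is exactly the activation probability of an uncoupled
subunit and J = 0 reduces the class law to the binomial with rotation
multiplicity m_c p^{a_c}(1−p)^{n−a_c}. Both sufficient statistics are
rotation-invariant, hence constant on classes, and

    P(class c) = m_c · exp(h a_c + J g_c) / Z

with g_c the number of adjacent activated pairs. Only class counts are
observable, so the likelihood is the 6-class multinomial; h is
identified by the activated fraction and J essentially by the
ortho:para split and the heaviness of the 0/4 tails.

Fitting is deterministic: the independence fit is closed-form (p̂ is
the plug-in subunit fraction; boundary estimates are flagged, their
log-likelihood still evaluated with the 0·log 0 = 0 convention); the
coupled fit does a coarse grid search (h ∈ [−4, 4], J ∈ [−3, 3], step
0.25) followed by Nelder–Mead refinement to 1e−8, with standard errors
from the finite-difference observed information. A single occupied
class leaves (h, J) non-identifiable and raises. The cooperativity test
is 2(ℓ̂_coupled − ℓ̂_indep) on χ²(1) asymptotics; negative values
beyond 1e−6 optimizer slack are treated as a failed optimization, and
small-sample calibration is checked by simulation rather than exact
tests (measured type-I error 0.05 ± 0.03 at N = 5,000 tetramers over
500 null replicates).

## Synthetic data generator

The generator emulates the label layer of the classification output,
nothing upstream of it: true arrangements are drawn i.i.d. from the
exact 2^n-state model distribution, then each subunit independently
becomes D with probability δ (unclassifiable density), then each
surviving label flips with probability ε (symmetric by default; an
asymmetric (ε_RA, ε_AR) option exists because classification confusion
need not be symmetric). Disorder precedes mislabeling — a D subunit
cannot also be flipped. One global seeded stream drives a run, so fixed
configs reproduce byte-identical files; a JSON sidecar records the
config and ground truth.

Defaults are chosen as a realistic heat-ramp-like condition: p = 0.4,
J = 0, ε = 0.02, δ = 0.05. ε has no published counterpart (the source
classification reports no error rate), so 2% is an illustrative,
plausible confusion level; δ = 0.05 gives an intact fraction
(1−δ)⁴ ≈ 0.81, i.e. a visible but not dominant exclusion tally. Under
symmetric mislabeling the observed activated fraction is exactly
p(1−ε) + (1−p)ε, which the corruption report asserts against
simulation.

What passing tests on synthetic data do **not** show: robustness to
alignment errors, to confusion correlated with particle quality or
orientation, to non-uniform disorder across conditions, or to
misassigned tetramer identities during trace-back — none of which the
generator models.

## Shipped fixtures and replication

Four published datasets (apo 18 °C, apo 37 °C, CIM0216 18 °C,
primidone 18 °C) are shipped as per-class intact-tetramer counts,
transcribed into small CSVs with condition metadata; totals range from
0.48 M to 2.2 M tetramers. The replication report recomputes every
headline statistic by exact integer arithmetic (< 1 s) and flags two
published figures that disagree with the table-derived values at
integer-percent rounding: the ≥3-activated tail at 37 °C (26.2%
computed vs 27% printed) and the primidone activated-subunit fraction
(29.5% vs 30%). The discrepancy plausibly reflects a different rounding
pipeline or slightly different particle sets upstream of the published
tables; the report surfaces it rather than matching it. Subunit
percentages are computed after intactness filtering (the published
methods compute ratios "within intact tetramers"); whether the printed
figures predate that filter is unknowable from the tables alone.

## Numerical and size choices

* Class probabilities use log-sum-exp normalization; exhaustive
  enumeration is guarded at k^n > 10⁶ arrangements.
* Simulation-based checks use N = 50,000 tetramers × 20 seeds for
  parameter recovery (mean |p̂−p| < 0.01, |Ĵ−J| < 0.1 at the tested
  (p, J) points), N = 20,000 for dropout/goodness-of-fit checks, and
  500 replicates of N = 5,000 for LRT calibration — sizes at which the
  targeted tolerances are a few Monte-Carlo standard errors wide while
  a full suite run stays around a minute.
* The null-calibration simulator draws class counts directly from the
  exact 6-class multinomial, which is distribution-identical to running
  the per-particle generator at ε = δ = 0.

## Known limitations

* The model is an equilibrium (static) mixture; no kinetics, no voltage
  dependence, no link from J to any physical interface is claimed.
* χ²(1) asymptotics for the LRT are used as-is; at the shipped dataset
  sizes (10⁵–10⁶ tetramers) this is comfortable, but for very small N
  or boundary-adjacent p̂ the test is only as good as its simulated
  calibration.
* Goodman intervals cover class fractions only; derived statistics get
  bootstrap intervals.
* Particle counts in the fixtures are treated as i.i.d. tetramer draws;
  any dependence induced upstream (shared micrographs, duplicated
  picks) is outside the model and would shrink the real effective N.
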