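# ringstate

Subunit-level conformational composition analysis for C4-symmetric ion
channels, built for the post-processing stage of cryo-EM **symmetry
expansion**: each tetrameric particle is replicated once per C4 rotation,
every subunit is classified independently into a **resting (R)** or
**activated (A)** conformation (or flagged **disordered, D**), and the
per-subunit labels are traced back to their parent tetramers. `ringstate`
takes it from there:

* enumerate the rotation-equivalence classes of subunit states on a Cn
  ring (six for two states on C4: `4R0A, 3R1A, 2R2A_ortho, 2R2A_para,
  1R3A, 0R4A`, with orbit sizes 1, 4, 4, 2, 4, 1);
* assemble per-subunit tables (TSV or STAR) into tetramers and apply the
  intactness rule — any tetramer with a missing or disordered subunit is
  excluded before statistics;
* compute composition spectra, the subunit activated fraction
  *p* = Σ a<sub>c</sub> n<sub>c</sub> / (4N), occupancy tails
  P(≥k activated), fold changes between conditions, and bootstrap /
  Goodman confidence intervals;
* summarize the resting ⇌ activated equilibrium: K = p/(1−p),
  ΔG = −RT ln K, and a two-temperature van't Hoff enthalpy
  ΔH = R ln(K₂/K₁) / (1/T₁ − 1/T₂);
* fit a nearest-neighbour coupling model on the ring,
  P(s) ∝ exp(h Σᵢ sᵢ + J Σᵢ sᵢ sᵢ₊₁) with sᵢ ∈ {0,1}, by exact
  maximum likelihood over the class multinomial, and test cooperativity
  (J = 0) with a likelihood-ratio test on χ²(1);
* generate seeded synthetic particle tables with known ground truth
  (label noise ε, disordered dropout δ) so every pipeline stage is
  testable without any experimental download.

The package ships the published per-class particle counts of four rat
TRPM3 cryo-EM datasets (apo at 18 °C and 37 °C, the superagonist
CIM0216, the antagonist primidone) and reproduces that study's headline
numbers end to end — the audience is structural biologists quantifying
conformational heterogeneity, and methods developers who need a tested
reference for necklace-class occupancy statistics.

## Worked example

```python
from ringstate import RingCouplingModel, load_fixture

spec = load_fixture("apo_37C")          # apo channel, heat condition
print(f"N intact tetramers: {spec.total}")
print(f"activated subunit fraction: {spec.active_fraction():.4f}")
print(f"P(>=3 activated): {spec.occupancy_at_least(3):.4f}")
print(RingCouplingModel(spec).fit().summary())
```

prints

```
N intact tetramers: 477026
activated subunit fraction: 0.4034
P(>=3 activated): 0.2617
Ring coupling model
==============================================
ring size                     4
tetramers (N)            477026
log-likelihood          -810157.141
converged                  True
----------------------------------------------
param       estimate     std err
h            -1.1493      0.0028
J             0.8975      0.0029
p             0.2406
----------------------------------------------
cooperativity LRT       94336.480  p=0 (chi2, 1 df)
```

At 37 °C, 40.3% of subunits are activated and 26.2% of tetramers carry
at least three activated subunits — far more than the 18.3% an
independent-subunit (binomial) model with the same subunit fraction
would predict. The fitted coupling J ≈ 0.90 (dimensionless; positive
means like neighbours attract) and the enormous likelihood-ratio
statistic quantify that excess: subunit activation on the ring is
strongly cooperative, consistent with channels switching concertedly
rather than one subunit at a time. `h` is the per-subunit activation
field; p = expit(h) is what the activated fraction would be for an
uncoupled subunit.

A CLI mirrors the pipeline (`ringstate simulate | assemble | stats |
compare | fit | replicate | classes`); run `ringstate --help`.

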