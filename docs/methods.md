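# Methods

This note documents the models, conventions and numerical choices behind
`flexsas`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data validation does and does not
demonstrate.

## Scattering-curve analysis

**Curve container.** A curve is (q, I, σ) with q in Å⁻¹, strictly
increasing and positive, and σ > 0 everywhere (rows with non-positive σ are
dropped on read, with a count in the metadata).  Instrument exports that
report 2σ uncertainties are converted on read via `sigma_scale=2`; deposited
database curves are assumed to carry 1σ already.  A `q_in_nm` flag converts
nm⁻¹ grids explicitly — units are never guessed.

**SEC reduction.** Buffer and sample frame sets (disjoint, shared q-grid)
are averaged and subtracted point-wise; σ propagates in quadrature of the
two means.  Frame-role decisions (which frames are buffer) are the user's,
as in interactive SEC-SAXS processing.

**Guinier fitting.** Weighted least squares of ln I on q², with weights
(I/σ)² from first-order error propagation.  The automatic window starts at
the lowest valid q and shrinks its upper end until q·R<sub>g</sub> ≤ 1.1
(iterating because R<sub>g</sub> depends on the window) — the restrictive
limit appropriate for disordered chains, where the Guinier expansion fails
early.  A Wald–Wolfowitz runs test on the residuals guards against
curvature; in automatic mode the window shrinks further while the runs
p-value is below 0.01.  Explicit 1-based point ranges bypass the automatic
selection so published point ranges can be reproduced exactly.  A positive
fitted slope is a hard error (non-physical).  Parameter uncertainties come
from the weighted design matrix with σ treated as known.

**Dimensionless Kratky.** (qR<sub>g</sub>)²·I/I₀ against qR<sub>g</sub>,
with a peak locator over qR<sub>g</sub> ≤ 8.  A compact globule peaks at
(√3, 3/e) ≈ (1.73, 1.10); a Gaussian coil plateaus near 2; rising curves
indicate chain-like flexibility.

**P(r) inversion.** I(q) = 4π∫₀^Dmax P(r) sinc(qr) dr is discretized on a
uniform r-grid (default 201 points) with trapezoid weights and endpoint
constraints P(0) = P(D<sub>max</sub>) = 0 (implemented by removing the
endpoint unknowns; the second-difference penalty rows that reference them
enforce smooth decay into the boundaries).  The objective is
‖(Kp − I)/σ‖² + α‖L·s·p‖², where L is the second-difference operator and
s = ‖A‖<sub>F</sub>/‖L‖<sub>F</sub> normalizes the two blocks, so α is a
dimensionless smoothing weight.  Because the normalization is
data-dependent, α values are comparable within one curve but not across
instruments; α is always echoed in the result.  When α is not supplied, a
logarithmic scan (10⁻⁸…10³) picks the strongest smoothing whose reduced χ²
stays within max(0.1, 5%) of the minimum — an L-curve-style discrepancy
rule.  Outputs include R<sub>g</sub> from the second moment
(R<sub>g</sub>² = ∫r²P dr / 2∫P dr, with a delta-method uncertainty from
the regularized covariance), I₀ = 4π∫P dr, the reduced χ² of the fit, and
a quality block (positivity fraction, smoothness norm, endpoint decay).
No attempt is made to reproduce any program-specific composite quality
score numerically; the components are reported instead.  Solutions whose
P(r) integrates non-positive (a symptom of badly wrong D<sub>max</sub>)
yield NaN moments with a warning, keeping the χ² available for misfit
diagnosis.  q<sub>min</sub> > π/D<sub>max</sub> triggers a warning (the
data cannot resolve the largest dimensions), not an error.

**Robustness scan.** Following the practice of testing P(r) features
against analysis choices, the curve is re-inverted over a grid of
(D<sub>max</sub>, α, optionally q<sub>max</sub>) and a feature window in r
is searched for a *secondary* local maximum (the global peak never counts)
exceeding 5% of the global peak with half that prominence
(`scipy.signal.find_peaks`).  The summary is the fraction of grid points
where the feature persists; a feature surviving the whole scan is unlikely
to be a regularization artefact.

**Porod-invariant mass.** The invariant Q = ∫q²I dq is accumulated from a
Guinier extrapolation to q = 0 and the data up to a cut (default
0.3 Å⁻¹); the truncated tail is completed analytically assuming Porod
q⁻⁴ behaviour, with the Porod constant estimated from the top 15% of the
fitted range (Q<sub>tail</sub> = K/q<sub>max</sub>).  The apparent volume
is V = 2π²I₀/Q and mass follows from the protein-density constant
1.212 Å³/Da (ρ ≈ 1.37 g cm⁻³); both the raw (truncated) and
tail-corrected volumes are reported.  On a noise-free 30 Å sphere the
corrected volume is accurate to ~4%.

## Ensemble optimization

**Pool generation.** Conformers are Cα bead chains: consecutive beads
3.8 Å apart, non-adjacent beads rejected below 3.0 Å, disordered segments
grown bead-by-bead from the folded-core termini (or freely, for coreless
constructs) with up to 500 retries per bead before the conformer restarts.
Directions are drawn from a three-state pseudo-bond-angle library —
PPII-like (120° ± 15°, p = 0.40), extended/β (140° ± 12°, p = 0.35),
compact (95° ± 15°, p = 0.25) with uniform dihedrals — a deliberately
simple coil model biased toward extended states, matching the character of
P/G-rich IDRs.  It is *not* a residue-specific Ramachandran library;
consequently ensemble metrics are validated by recovery of known ground
truth, not by comparison with any particular program's pool statistics.
Only terminal disordered segments are supported (bridging loops between two
core pieces would need closure sampling).  Pools are bit-reproducible from
(spec, seed).

**Profiles.** The Debye double sum over identical dummy residues,
I(q) = f(q)²[N + 2Σ<sub>i<j</sub> sinc(q r<sub>ij</sub>)], with a Gaussian
dummy-residue form factor f(q) = exp(−q²R<sub>g,dr</sub>²/6),
R<sub>g,dr</sub> = 2.5 Å.  The exact sum is used whenever
n<sub>pairs</sub>·n<sub>q</sub> ≤ 5·10⁷; beyond that a 0.5 Å
distance-histogram approximation kicks in (and is flagged by argument).

**GA selection.** Chromosomes are index multisets of fixed ensemble size
(repetition = weight).  Fitness is the reduced χ² of the equal-weight
average profile after an optimal scale (optionally scale + constant) fit.
Defaults: population 50, 200 generations, tournament selection, uniform
crossover at rate 0.5, per-gene mutation 0.1 (half drawing fresh pool
members, half duplicating a gene of the same chromosome so weight can
concentrate), elitism 1.  One chromosome per run is seeded with the best
single conformer (greedy initialization).  Each run ends with a vectorized
greedy polish (single-gene exchanges against the whole pool to a local
optimum).  `n_runs` independent runs from sub-seeds are pooled; the
selection's weights are the pooled membership frequencies.

**Parsimony (ensemble-size selection).** Ensemble fitting overfits: large
multisets can dip *below* the noise floor of the reduced χ² by compensating
the specific noise realization, which smears the recovered R<sub>g</sub>
distribution far beyond what the data justify (we verified this directly:
the unrestricted maximum-likelihood mixture over a 2000-member pool fits a
single-conformer target better than the generating conformer itself while
spreading weight over ±10% in R<sub>g</sub>).  `select_ensemble_size`
therefore applies a discrepancy/Occam rule: the GA is run over a ladder of
sizes (default 1, 2, 3, 5, 10, 20; sizes 1 and 2 are solved exactly by
enumeration, size 2 via the weighted Gram matrix) and the smallest size
whose best reduced χ² is within one standard error (√(2/N)) of the overall
best is retained.  A single-state target then collapses to one member; a
genuine mixture keeps the size it needs.  The fixed-size GA remains
available for users who want the classical behaviour.

**Flexibility metrics.** R<sub>flex</sub> = 100 × Shannon entropy of the
R<sub>g</sub> histogram / ln(n<sub>bins</sub>), computed on a shared
Freedman–Diaconis binning of the pool range (minimum 10 bins; the binning
is reported since the metric depends on it).  R<sub>σ</sub> is the ratio of
selected to pool R<sub>g</sub> standard deviations; values below 1 with a
left-shifted geometric mean indicate compaction.  `compaction_test` draws
random pool multisets of the same total size to build a null distribution
of the geometric-mean R<sub>g</sub>; the one-sided bootstrap p-value
classifies the selection as compact / extended / indistinguishable at a
conventional two-sided 5% level (2.5% per tail).  By construction, random
subsamples are called indistinguishable ~95% of the time, and tercile
selections are detected essentially always.

## Neutron contrast

All SLDs are Σb/V in 10¹⁰ cm⁻².  Conventions, frozen as one documented
table (`flexsas.tables`) with user override:

* Coherent scattering lengths: Sears values (b<sub>H</sub> = −3.739,
  b<sub>D</sub> = +6.671 fm, etc.).
* Residue elemental compositions at pH ≈ 7: Asp/Glu carboxylates
  deprotonated, Lys/Arg protonated, His neutral; chain termini add one
  water whose two hydrogens are exchangeable.
* Exchangeable hydrogens: backbone amide (none for Pro) plus labile
  side-chain O–H/N–H/S–H of the ionization state above.
* Residue volumes derive from the Cohn–Edsall partial specific volumes with
  a +0.5% calibration folded into the embedded Å³ table so that the
  calculator reproduces the published MULCh-style reference outputs for the
  SFPQ test case; the calibration is an order of magnitude smaller than the
  2–5% spread among published residue-volume tables, which is also why the
  contrast tests carry a ±0.05 × 10¹⁰ cm⁻² tolerance.
* Water volume 29.9 Å³.  Default solute volumes: KCl 34.7 Å³ (Pauling
  ionic volumes), glycerol 121.4 Å³, HEPES 310 Å³, DTT 210 Å³.

The protein SLD replaces non-exchangeable H by D at the labelling fraction
d and exchangeable H at x·f<sub>D</sub>, where x (default 0.9) is the
solvent accessibility of labile sites and f<sub>D</sub> the D fraction of
the water.  The solvent SLD sums number-density-weighted scattering lengths
of water and solutes, with solutes displacing water by their volume
fraction.  Buffer-component formulas are taken literally: solute hydrogens
exchange with the solvent only when a component declares them via
`n_exchangeable_h` (default 0).  This literal-formula convention is what
reproduces the published reference outputs for buffers specified as plain
chemical formulas; declaring glycerol's three hydroxyls exchangeable shifts
a ~95% D₂O solvent by ≈ +0.13 × 10¹⁰ cm⁻², outside the reference values'
tolerance.  Because contrast is affine in the D₂O buffer fraction, the
match point is bracketed on [0, 1] and solved to |Δρ| < 10⁻⁴; if the
contrast does not change sign the protein is flagged unmatchable with both
endpoint contrasts reported.  The match point is reported both as the
fraction of buffer prepared in D₂O (the bench-mixing convention) and as the
D₂O volume fraction of the whole solution (which is lower because solutes
displace water).

Dialysis dilution reports both conventions in use: per-step factor =
bath/sample (two 25× baths → 625×) and the inclusive
(bath+sample)/sample total (275 µl into 5225 µl → 19× vs 20×).

## Sequence computations

Masses are standard average residue masses plus one water per chain;
ε₂₈₀ = 5500·n<sub>W</sub> + 1490·n<sub>Y</sub> per chain (all cysteines
reduced), with the cystine-inclusive value (+125 per pair) reported
alongside, since tools differ silently in this assumption.  Enrichment is
the query fraction over a reference (e.g. one-sequence-per-gene proteome)
fraction; residue types absent from the query but present in the reference
are flagged as infinitely depleted rather than given a number, and the
reverse case is flagged undefined.  Sliding-window fractions are indexed by
the 1-based window *start* (a convention the output records explicitly).
The bundled SFPQ sequence is cross-validated against the published
chemical-composition mass and mass-extinction coefficient.  One caveat the
package resolves deliberately: the published chemical-composition dimer
mass corresponds to the expressed TEV-cleaved construct carrying an
N-terminal Gly-Ser scar (2 × 76.293 kDa = 152.587 kDa), not to residues
1–707 exactly (152.299 kDa); `sfpq_sequence(construct=True)` returns that
construct and the physchem checks use it.

## Cross-link mapping

Links are lysine–lysine pairs (strict mode also accepts the protein
N-terminus); duplicates collapse with occurrence counts.  Classification
labels each link by its ordered region pair on a user domain map
(symmetric in endpoint order), with same-peptide links in a dedicated
category.  Feasibility against an ensemble uses a Cα–Cα cutoff, default
30 Å for a DSSO-style linker (≈ 10.3 Å spacer plus two lysine side chains
and coordinate uncertainty); the cutoff is configurable and always echoed.
In homodimers a residue pair maps to several chain assignments; the minimum
distance over assignments is used and the link flagged ambiguous —
identification data cannot distinguish intra- from inter-protomer links.

## Synthetic data and what the tests show

Phantoms are analytic (sphere form factor, pure Guinier, Debye coil,
forward transform of a custom P(r), weighted conformer mixtures) with noise
σ(q) = a·I + b·√(I+c), defaults a = 0.01, b = c = 0 — a 1% relative floor
typical of well-exposed SEC-SAXS frames.  The default phantom q-grid is
0.005–0.5 Å⁻¹ (400 points), matching modern beamline ranges.  SEC series
add a flat buffer baseline and optional linear R<sub>g</sub> drift across
the eluting peak (larger conformers eluting first).  Every generator is a
pure function of (spec, seed) and emits a ground-truth record.

The synthetic validation demonstrates *internal correctness* — the
analyses recover what the generators put in, at the stated noise — under
idealized conditions: no inter-particle structure factor, no beam smearing,
no radiation damage, flat buffer baselines, Gaussian noise, and coil
statistics from a generic three-state library.  Passing tests therefore
show the machinery is right, not that any particular real dataset will be
as well-behaved.  The published SFPQ contrast/mass/match-point values are
reproduced exactly because they are closed-form computations on the
sequence; the ensemble-method validation is by ground-truth recovery at
reduced scale (2000-conformer pools of 80-residue chains, 5 noise seeds),
chosen so the full suite runs in minutes on one CPU, and published
R<sub>flex</sub>/R<sub>σ</sub> values from other software are treated as
qualitative references only, since they depend on unpublished sampler
internals and deposited data.

## Known limitations

* The coil library is generic; sequence-specific stiffness (polyproline
  runs, charge patterning) only enters through the global state biases.
* No hydration shell or excluded-volume term in the Debye profiles; at the
  dummy-residue resolution this mainly affects q ≳ 0.3 Å⁻¹.
* The IFT α is normalized per-curve; α values are not transferable across
  datasets.
* X-ray contrast, 2D reduction, absolute-intensity calibration, ab initio
  bead modelling, and cross-link identification/FDR are out of scope.
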