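# Methods

`eprnano` reconstructs the lateral nanodomain composition of a cell
plasma membrane from a single X-band EPR spectrum of a lipophilic
nitroxide spin probe. This note records the model, its assumptions, the
numerical choices and the limits of what the synthetic benchmarks show.

## Spectral model

A membrane probed by a fatty-acid nitroxide such as MeFASL(10,3) is
treated as a small set of K nanodomain types. All probe molecules in one
domain type share a motional mode described by

| parameter | meaning | units | default bounds |
|-----------|---------|-------|----------------|
| S         | order parameter of the acyl-chain long axis | – | 0 … 1 |
| τc        | rotational correlation time | ns | 0.05 … 5 |
| pA        | hyperfine-tensor polarity correction | – | 0.85 … 1.15 |
| pg        | g-tensor polarity correction | – | 0.999 … 1.001 |
| W         | residual Lorentzian half-width | mT | 0 … 0.5 |
| d         | fraction of probes in the domain type | – | 0 … 1, Σd = 1 |

The motion is assumed *fast but restricted* on the EPR timescale
(wobble in a cone). Fast motion partially averages the rigid-limit
tensors to axial effective values

    A∥ = pA (a_iso + ⅔ S ΔA),  A⊥ = pA (a_iso − ⅓ S ΔA),
    a_iso = (A_xx + A_yy + A_zz)/3,  ΔA = A_zz − (A_xx + A_yy)/2,

and analogously for g with pg. The trace is conserved for every S. The
rigid tensor defaults (A = 0.63/0.58/3.36 mT, g =
2.0088/2.0061/2.0027) are standard doxyl-nitroxide literature values
and are configuration inputs, not fitted constants.

The cone half-angle follows from S through the wobble-in-cone relation
S = ½ cosθ₀ (1 + cosθ₀), monotone from θ₀ = 0 (S = 1) to 90° (S = 0).

For a director at angle θ to the field, line m_I ∈ {−1, 0, +1} resonates
at B = hν/(g_eff μ_B) − m_I·A_eff with the usual axial angular
dependences. Its Lorentzian half-width is

    ΔB(θ, m_I) = W + κ τc Var_cone[B_res(m_I)],

where the variance of the instantaneous (rigid-tensor) resonance field
is taken over the accessible cone, uniformly in solid angle. κ defaults
to the electron gyromagnetic ratio expressed in ns⁻¹ mT⁻¹ (0.1761), the
natural scale of motional broadening; it is configurable. This term
vanishes at S = 1 and is exactly linear in τc. The model covers the
motional-narrowing regime only; slow-motion (stochastic-Liouville)
lineshapes, saturation and other nuclei are out of scope.

A spectrum is the d-weighted superposition of components, each powder
averaged over director orientations (Gauss–Legendre in cosθ, 64 nodes
for generation; fitting uses 32 nodes, which reproduces the 64-node
spectra to ~10⁻⁹ of peak). Each component's absorption is
baseline-corrected with the straight line through its sweep-edge values,
normalized to unit integral, and differentiated analytically. Field
modulation (0.2 mT) is carried as metadata; because it is small relative
to the linewidths the default rendering is the analytic derivative, with
numerical pseudo-modulation available as an opt-in flag.

Default acquisition grid: 9.59 GHz, centre 341.5 mT, 10 mT sweep,
1024 points, 20 °C — matching a Bruker X-band configuration for this
probe.

## Fitting (HEO: genetic algorithm + downhill simplex)

The objective is the noise-weighted SSR between the unit-amplitude
normalized measured spectrum and the model, with the noise sd estimated
from the outer 5% of field points (floor 10⁻⁴ of peak, so noise-free
synthetic fits stay finite).

Three structural choices dominate the optimizer's reliability; all were
adopted after the naive formulation proved unable to resolve three
components at realistic noise:

1. **Variable projection for d.** The spectrum is linear in the
   proportions, so at every evaluation the optimal non-negative weights
   are solved by NNLS and renormalized to Σd = 1. The evolutionary
   search runs over the K×(S, τc, pA, pg, W) shape parameters only.
2. **Canonical component ordering.** Every genome keeps its components
   sorted by descending S. This removes the K! relabelling symmetry
   that otherwise makes crossover combine unrelated components.
3. **Restart ("split"/"nudge") moves.** After the simplex refinement,
   the fit re-starts the simplex from candidates in which (a) the
   largest-d component is split into two S-shifted copies and (b) the
   lowest-S component is kicked away from the S = 0 bound with a
   compensating τc rescale. These target the two recurrent local
   minima of multi-component lineshape fits — merged components, and a
   disordered component collapsed to the isotropic bound — and are
   accepted only on improvement.

The GA is real-coded (population 36, 60 generations, tournament 3,
blend/row-swap crossover 0.9, per-gene Gaussian mutation with sd 5% of
the bound width, elitism 2, 25% random immigrants every 10
generations). The global phase evaluates the objective on a 4×
decimated field grid (information loss is negligible: linewidths span
many grid steps); the Nelder–Mead refinement runs at stride 2 and then
at full resolution, where the reported χ² is always computed. Each run
is seeded and bit-reproducible; a multi-run uses seeds base,
base+1, ….

## GHOST condensation

Each spectrum is fitted by many independent runs (200 at full scale).
The solution cloud is condensed as follows: keep the best half of runs
by χ²; explode each kept run into one point per component; normalize
(S, τc, W, pA) to the fit bounds; drop points with fewer than 5
neighbors within 0.05 (Euclidean, normalized space); slice the S axis
into overlapping windows (width 0.05, step 0.025); link points that
share a slice and lie within 0.05 in the (τc, W, pA) subspace; merge
linked clusters across slices. Connected components become domain
groups, labelled 1, 2, 3 … by descending mean S. Group parameters are
member means; their standard errors come from the member covariance
matrix (sd/√n, the between-run spread — a pragmatic stand-in for a
per-fit covariance analysis); group proportions are the mean fitted d,
renormalized to 100% across groups. The thresholds are unpublished in
the method's sources and are package defaults, configurable and echoed
in the output metadata. The density threshold should be scaled with the
cloud: 5 neighbors suits ≥50-run clouds (~75+ retained points); the test
suite uses 4 for its 18-run clouds.

Grouping consumes no randomness, is invariant to point order, and is
verified in the tests against a brute-force all-pairs neighborhood-graph
oracle.

## Condition comparison

Replicates are independent spectra (synthetic: independent noise seeds),
each fitted and condensed separately. Domains are matched across
conditions by descending-S rank. Each parameter (S, τc, pA, d) is
summarized as the relative change of replicate means
(cond − ctrl)/ctrl with first-order error propagation, and tested with
a two-sided two-sample Student's t-test at α = 0.05 (Welch and
Bonferroni variants available as flags, off by default to mirror common
reporting practice). With fewer than two replicates per side the table
is still produced with tests flagged not computable.

## Synthetic data

Presets emulate the plasma membranes of five cell lines/conditions as
three-domain compositions. Only the intermediate-domain order
parameters of the two receptor-expressing presets (0.37 for "aT3",
0.41 for "HEK-HAGnRHR") are published values; every other number is a
package-chosen plausible default: an ordered raft-like domain
(S ≈ 0.62–0.65, τc ≈ 2.5 ns), a fluid domain (S ≈ 0.12–0.14,
τc ≈ 0.5 ns), W between 0.08 and 0.12 mT, and proportions decreasing
from the ordered to the fluid domain. Differences between an expressing
preset and its control follow the reported directions of change; the
"+mbCD" (cholesterol-depletion) preset lowers all three S values.

Noise is additive white Gaussian on the derivative signal, sd =
peak/snr, default snr 50 (visually matching clean measured cell
spectra); an optional linear baseline drift exists for robustness tests.
The generator does not emulate probe reduction kinetics, cell-to-cell
variability or instrument drift, so passing recovery tests demonstrates
identifiability under ideal noise, not robustness to systematic
artefacts of real measurements.

## Problem sizes used by the shipped benchmarks

The packaged test suite and `scripts/acceptance.py` run the pipeline at
desk scale: 50 HEO runs per cloud for the domain-count and acceptance
computations (the method's full scale is 200; 50 keeps ≥25 retained
runs, amply enough for the density filter at the default thresholds),
and for replicate statistics 5 seeded replicates per preset with 18-run
clouds, a reduced-effort GA profile (population 24, 40 generations) and
min_neighbors 4. At these sizes a full pipeline takes minutes per
spectrum on one core; results at 200 runs are statistically
indistinguishable for the synthetic presets, the cloud is simply denser.

## Known limitations

* The linewidth model (κ·τc·cone variance) is one member of the
  restricted-fast-motion family; absolute τc values are therefore
  calibration-dependent even though recovery of *planted* values is
  exact by construction.
* pg is fittable but bounded to ±10⁻³; at X-band the data barely
  constrain it.
* K is fixed by the user (default 3). The package reports χ² per run
  but does not select K automatically.
* Group standard errors measure between-run spread of retained
  solutions, which under-represents uncertainty when the cloud is
  strongly filtered.
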