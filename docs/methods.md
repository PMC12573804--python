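# Methods

This note records the models implemented in `zwitterphase`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions taken where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Units and constants

Distances are nm; energies are kJ/mol at rest and converted to thermal
units only at computation boundaries, with k_BT = RT = 2.494 kJ/mol at the
fixed analysis temperature of 300 K. Harmonic force constants are
kJ mol⁻¹ nm⁻² (0.6 J mol⁻¹ pm⁻² = 600 kJ mol⁻¹ nm⁻²;
25 J mol⁻¹ pm⁻² = 25 000 kJ mol⁻¹ nm⁻²).

## Synthetic ground truth

The synthetic layer replaces the molecular-dynamics stage with closed-form
models so that every estimator can be checked against known truth.

**Analytic PMFs.** `flat` (identically zero), `gaussian_well` (inverted
Gaussian: depth in k_BT, centre and SD width in nm) and `double_well`
(two inverted Gaussians). The production stand-in for a
coacervate-forming monomer pair is a 3.0-k_BT well at 0.55 nm with width
0.12 nm on the domain [0, 3.5] nm. For *null* (flat-truth) experiments the
domain is set to the profiled interval itself: an unbounded flat support
puts accidental single counts into bins where the unbiasing factor
exp(+V/k_BT) is enormous, a catastrophic-noise artifact of the synthetic
null rather than a property of the estimators.

**Biased sampling.** Each umbrella window is sampled by single-variable
Metropolis Monte Carlo from the density ∝ exp(−[PMF(z)+½k_z(z−z₀)²]/k_BT)
(Gaussian proposals, default step 0.05 nm; fidelity of dynamics is
irrelevant because only the stationary density feeds the estimators).
Perpendicular displacements r are drawn i.i.d. from the restraint's own
harmonic density so V_r is non-trivial downstream. The production protocol
draws 12,500 raw samples per window and discards the first 20% as
equilibration, mirroring a 250-ns window with 50 ns of equilibration.
All generators are pure functions of (parameters, seed).

**Conformer frames.** A dimer frame carries six labelled atoms (carbonyl
carbon, nitrogen, sulfur of each molecule). The two-state model places the
sulfur at a backbone–sulfur distance of 0.5 nm ("closed") or 0.9 nm
("open"), with the open state offset by a designed ΔF in k_BT; conformers
are drawn with their Boltzmann probabilities, all atoms jittered by
isotropic Gaussian noise (default 0.02 nm), and the second molecule placed
so the COM separation follows the window's *biased equilibrium*
exp(−[PMF+V_z]/k_BT) (inverse-CDF sampling on a dense grid). Drawing z
from the actual underlying PMF matters: with a flat implied z-density the
reweighted distribution forms a flat ridge in PC space whose spurious
shallow minima are an artifact no real system would show. Ground-truth
labels are retained for recovery testing. Dense-quadrature alignment
constants F_i = −ln ∫ p₀(z) e^(−V_i/k_BT) dz provide a sampling-free
oracle for reweighting synthetic frames.

What the synthetic data do **not** emulate: force-field physics, solvent
and ion effects, orientational degrees of freedom beyond the six labelled
atoms, autocorrelation structure of real MD (the Metropolis chain has its
own, different, correlation time), and any coupling between conformer
state and COM separation. Passing tests therefore certify the estimators
and the pipeline plumbing, not the fidelity of any molecular model.

## WHAM

Shared histogram edges are multiples of the bin width (default 0.01 nm)
spanning the pooled samples padded by one bin. The self-consistent
equations are iterated directly (vectorised over a precomputed
exp(−V_i(z_b)/k_BT) matrix) until max_i|ΔF_i| < tol, defaults
tol = 10⁻⁶ k_BT and max_iter = 10⁵; bin width and tolerance are chosen so
discretisation error is far below the 0.15-k_BT recovery target at
production scale. Zero-count bins are masked, never interpolated. The
profile is shifted so its mean over the dissociated reference window
(1.75–2.25 nm) is zero; profiles that do not reach the reference window
are shifted to min 0 instead. WHAM is gauge invariant: adding a constant
to every window bias leaves F(z) unchanged (tested).

**Bayesian bootstrap.** Whole window trajectories are the exchangeable
units: each of B replicates (default 50; 20–25 in the shipped analyses)
re-solves WHAM with window histograms scaled by flat-Dirichlet weights
(times the window count so the expected weight is one), warm-started from
the central solution; the per-bin SE is the ensemble SD. Frame-level
resampling would understate autocorrelated error. Known limitation: with
one trajectory per window, the resampler cannot see *within*-window drift
of a too-short chain; calibration (SE within a factor ~2 of the
repeat-experiment SD of ΔG; measured ratios ≈ 0.9–1.0) holds at
production sampling depth (10,000 retained samples/window for the
well-stiffness ladder) and degrades at much shorter chains.

The production well experiment needs the production restraint stiffness:
with weak springs (k_z ≲ 300 kJ mol⁻¹ nm⁻² at 0.1–0.2-nm spacing) windows
near a 3-k_BT well collapse into it, the repulsive rise is under-sampled
and alignment noise inflates — the textbook umbrella-sampling failure
mode, not an estimator defect.

## Interaction free energy

ΔG = mean(F over reference-window bins) − min(F over bins with
0.4 nm ≤ z ≤ search_max), computed on raw bin values (no smoothing or
interpolation, which would introduce a bandwidth parameter the statistic
does not need); positive values are attractive well depths. search_max
defaults to 2.8 nm, the top of the profiled interval: the histogram
padding beyond the last restraint centre contains bins covered only by
window tails, where a single accidental count is amplified by
exp(+V/k_BT) into a multi-k_BT spurious dip. The SE applies the identical
functional to every bootstrap member.

**Null-truth bias.** Because ΔG is an extremum functional, its expectation
under an exactly flat truth is *positive*: the minimum over B populated
bins of i.i.d. noise of scale σ sits ≈ σ√(2 ln B) below the mean. A
spread-based error bar (any bootstrap flavour) measures dispersion, not
this bias, so on flat-truth experiments |ΔG| typically exceeds 2×SE
(measured median |ΔG|/SE ≈ 3 across window layouts and bin widths). The
statistic is therefore a well-*depth* estimator, reliable when a genuine
well dominates the noise floor, and conservative claims near ΔG ≈ 0 should
use the repeat-experiment scatter, not the single-experiment error bar.
This is documented deliberately: one end-to-end null-calibration test
asserts 2×SE coverage and fails for exactly this reason.

## Conformational free-energy surface

Unbiasing weights w_j ∝ exp[(V_z(z_j)+V_r(r_j)−F_i)/k_BT] with frames
excluded when V_z+V_r > 4 k_BT (comparison performed with ≤ on the k_BT
scale, exactly). The sign convention is fixed by the no-bias limit, where
the weights must reduce to uniform. PCA is computed on unweighted,
mean-centred features — all 15 pairwise distances among the six labelled
atoms, sharing nm units, hence no standardisation — and weights enter only
the density stage; component signs are fixed so the largest-magnitude
loading is positive. The surface is a weighted Gaussian KDE (Scott's rule
by default) evaluated on a 200×200 grid padded by three bandwidths,
Boltzmann-inverted (G = −k_BT ln ρ, grid minimum shifted to 0), with
cells below 10⁻⁶ of the peak density masked.

Minima: steepest descent on the 8-connected grid from every unmasked cell;
distinct endpoints are candidates, merged when within the 0.1 cutoff
(interpreted in raw (PC1, PC2) units, since the projection is not
standardised) of a lower candidate; merged basins holding less than 1% of
the total probability mass are discarded, because kernel bumps around
isolated outlier frames otherwise masquerade as minima. Each minimum's
free energy is the average of G over unmasked cells within the cutoff, and
representative frames are the highest-weight retained frames projected
within the cutoff.

## Phase-behaviour layer

Regime thresholds default to 0.8 and 2.0 k_BT, separating the observed
groups (no phase separation ≤ 0.62 k_BT, coacervates ≈ 1 k_BT, gel at
2.77 k_BT); the true boundaries also depend on polymer and salt
concentration, so the thresholds are configuration, never hard-coded.
Classification is half-open (t_low ≤ ΔG < t_high → liquid–liquid). Both
empirical laws are plain OLS without measurement-error weighting (no
per-record uncertainties are recorded); the √C_s,max transform is part of
the salt law and is inverted, with clamping at zero and extrapolation
flags, for design predictions. The relation between ΔG and C_s,max is
summarised only by a Spearman rank correlation — no functional form is
imposed.

## Problem sizes in the shipped analyses

Production umbrella experiment: 28 windows × 10,000 retained samples;
toy cross-check experiments: 5 windows × 2,000 samples (proposal step
0.15 nm for fast mixing at that size); conformational stage: 6 windows ×
5,000 frames = 30,000; bootstrap: 20–25 replicates; law fits: 10-point
series. These sizes make the full test suite and the acceptance script
run in minutes on a single CPU while keeping every recovery target
comfortably inside its tolerance at production scale.

## Known limitations

- No autocorrelation correction or effective-sample-size estimate; the
  bootstrap treats each window as one exchangeable unit (see above).
- 1-D WHAM only; the perpendicular restraint V_r enters the frame weights
  but not the PMF, which is defined along the COM separation alone.
- The FES stage assumes two informative principal components; systems
  whose conformational variance needs more dimensions will fold distinct
  states together.
- The regime thresholds are calibrated to one polymer/salt condition and
  are not transferable without re-calibration.
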