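# zwitterphase

Umbrella-sampling post-processing for the rational design of
phase-separating zwitterionic polymers.

Zwitterionic betaine monomers (sulfate-, sulfonate-, carboxylate- or
phosphate-bearing, e.g. ZB/SB/CB/MPC chemistries) encode dramatically
different phase behaviours in the polymers built from them: some polymers
stay dissolved, some form liquid coacervate droplets (liquid–liquid phase
separation), and strongly interacting monomers drive liquid–gel
transitions. The pairwise monomer–monomer interaction free energy,
computed from biased molecular simulations, predicts which regime a
homopolymer falls into and how copolymer composition tunes it. This
package implements the complete post-simulation analysis chain for that
workflow, together with a ground-truth-known synthetic data layer so every
stage is testable without running molecular dynamics.

## What it computes

**PMF by WHAM.** Harmonically restrained umbrella windows along the
centre-of-mass separation z (production layout: 28 windows, centres
0.1–2.8 nm, k_z = 600 kJ mol⁻¹ nm⁻², 25 000 kJ mol⁻¹ nm⁻² perpendicular)
are histogrammed and combined self-consistently:

    p(z_b) = Σ_i n_i(z_b) / Σ_i N_i exp[(F_i − V_i(z_b))/k_BT]
    F_i    = −k_BT ln Σ_b p(z_b) exp[−V_i(z_b)/k_BT]

with V_i(z) = ½k_z(z−z_i)². The potential of mean force is
F(z) = −k_BT ln p(z), zeroed on the dissociated 1.75–2.25 nm reference
window. Errors come from a Bayesian bootstrap over window trajectories
(flat Dirichlet weights, one ensemble member per WHAM re-solve).

**Interaction free energy.** ΔG = mean F over the reference window minus
the PMF minimum in the bound region (0.4 nm ≤ z ≤ 2.8 nm), in k_BT;
its SE applies the same functional to every bootstrap member. ΔG maps to
phase regimes through configurable thresholds (defaults 0.8 and 2.0 k_BT:
below → no phase separation, between → liquid–liquid, above → liquid–gel).

**Conformational analysis.** Frames from the windows spanning the PMF main
well are restored to equilibrium with Zwanzig unbiasing weights
w_j ∝ exp[(V_z(z_j)+V_r(r_j)−F_i)/k_BT], excluding frames whose bias
exceeds 4 k_BT. PCA over all 15 pairwise distances among the six labelled
atoms (carbonyl C, N, S of each molecule) gives a 2-D projection; a
weighted kernel-density estimate, Boltzmann-inverted, gives the free-energy
surface, whose minima are located by grid descent and valued by local
averaging within a 0.1 cutoff in (PC1, PC2).

**Copolymer laws.** For sticker–spacer copolymer series the package fits
√C_s,max = a·f_sticker + b (maximum salt concentration still showing phase
separation vs sticker fraction) and T_cp = c·C_s,max + d (cloud point vs
salt resistance) by ordinary least squares, and inverts the first law for
design predictions.

## Worked example

The numbered drivers under `analysis/` run the full chain on synthetic
experiments with known ground truth (later stages read the outputs of
earlier ones; run them in order):

```bash
python analysis/01_simulate_umbrella.py   # biased window series -> scratch/
python analysis/02_wham_pmf.py            # WHAM + bootstrap -> results/pmf.tsv
python analysis/03_interaction_energy.py  # monomer panel -> interaction_energies.csv
python analysis/04_conformational_fes.py  # FES + minima -> fes_minima.csv
python analysis/05_phase_behavior.py      # copolymer laws -> phase_fits.json
```

Stage 02 recovers a 3-k_BT gaussian-well ground truth from 28 windows of
10,000 retained samples:

```
WHAM converged in 1584 iterations (final max|dF_i| = 1.0e-06 kBT)
PMF recovery: 0.136 kBT RMS vs the analytic ground truth (0.4-2.8 nm)
median per-bin bootstrap SE: 0.098 kBT
```

Stage 03 screens a three-monomer panel spanning the regimes (true depths
0.4, 1.0, 2.8 k_BT); recovered ΔG carries its bootstrap SE and the regime
assignment:

```
weak         true 0.40 kBT -> recovered 0.14 +/- 0.14 kBT -> no_phase_separation
coacervate   true 1.00 kBT -> recovered 0.87 +/- 0.16 kBT -> liquid_liquid
gel          true 2.80 kBT -> recovered 2.93 +/- 0.16 kBT -> liquid_gel
```

Stage 04 builds the conformational surface of a two-state dimer with a
designed 1.0-k_BT closed/open gap:

```
2 free-energy minima:
  minimum 0: G = 0.17 kBT at PC=(-0.59, -0.01); representatives are 100% 'closed'
  minimum 1: G = 1.20 kBT at PC=(0.08, 0.68); representatives are 100% 'open'
free-energy gap between minima: 1.03 kBT (designed: 1.00)
```

Stage 05 recovers the copolymer laws (true slopes 2.0 and 10.0):

```
sqrt(Cs,max) vs f_sticker: slope 1.962 (95% CI 1.851-2.072, true 2.0), R^2 0.9953
Tcp vs Cs,max: slope 10.253 (true 10.0), R^2 0.9913
design example: f_sticker = 0.5 -> predicted Cs,max 1.16 M (true 1.21 M)
```

A `zwitterphase` console command exposes the same stages
(`simulate`, `wham`, `dg`, `fes`, `phase`) over `.xvg` window series,
extended-XYZ frame files and CSV copolymer tables, configured by a YAML
file; stochastic stages refuse to run without an explicit seed.

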