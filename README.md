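# cetpdyn

Trajectory-analysis pipeline for lipid transit through the tunnel of
cholesteryl ester transfer protein (CETP) and related BPI/LBP-family
transfer proteins.

CETP is an elongated plasma protein whose two β-barrels flank a central
neck, forming a continuous hydrophobic tunnel through which neutral lipids
(triglycerides, cholesteryl esters) pass between lipoproteins.  Two
phospholipid "plugs" occlude the central pores of the tunnel, and the
mechanistic questions around them — do they synchronize the barrel
domains, widen the tunnel, reroute the transiting lipid, accelerate it by
a gliding contact with their acyl tails? — are answered from molecular
dynamics trajectories.  `cetpdyn` implements the analyses those questions
require, for anyone post-processing MD or steered-MD trajectories of
tunnel-type lipid transfer proteins:

* **Domain dynamics** — inter-barrel angle series θ(t) (principal-axis
  angle of each barrel against the neck), analytic-signal (Hilbert)
  instantaneous phase and phase rate, normalized cross-correlation
  r(τ) between the barrels, in-/out-of-phase frame fractions, and
  anisotropic-network normal modes of the Cα network.
* **Tunnel profiling** — a polyline tunnel axis through the domain
  centers, per-axial-bin probe-excluded cavity volume and lining
  hydrophobicity (Kyte–Doolittle by default), and a per-bin Mann–Whitney
  U comparison between two profile ensembles.
* **Lipid path analysis** — center-of-mass tracing s(t), r(t) along the
  axis, the sustained-contact residue filter (min heavy-atom distance
  ≤ 0.6 nm for > 1 ns cumulative), across-replicate path averaging,
  traversal/fallout/incomplete fate classification, and hydrophobic
  contact-patch clustering.
* **Gating and gliding** — χ2 side-chain dihedral series with ring-symmetry
  normalization and 20-ps moving average, flap-opening event detection
  (≥ 40° excursions) with lipid-coincidence flags, instantaneous lipid
  velocity and spike ("gliding") detection, acyl-tail plane angles
  (parallel at ≤ 50°), and salt-bridge occupancy around plug headgroups.
* **Free energy** — weighted-histogram (WHAM) estimation of the potential
  of mean force F(ξ) from umbrella-sampling windows, with periodic
  reaction coordinates, moving-block bootstrap errors and time-block
  convergence checks.

A first-class synthetic-data module generates ground-truth-labelled inputs
for every stage (hinged-oscillator pseudo-protein, transit traces with
injected velocity spikes, telegraph rotamer series, Boltzmann samples from
analytic PMFs, hollow-cylinder tunnel clouds), so the whole pipeline is
testable end-to-end without an MD engine.

## The statistics at the core

For an angle series x(t), the analytic signal x̂(t) = x(t) + i·H[x](t)
gives the instantaneous phase φ(t) = arg x̂(t); two barrels are *in phase*
in a frame when their wrapped phase difference satisfies |φ_N − φ_C| ≤ π/2,
and the in-phase fraction is the fraction of such frames.

WHAM solves self-consistently, for windows i with bias u_i(ξ) = ½k(ξ−ξ_i)²
and histogram counts n_ib:

    p_b ∝ Σ_i n_ib / Σ_i N_i exp[(f_i − u_ib)/k_BT],
    f_i = −k_BT ln Σ_b p_b exp(−u_ib/k_BT),

iterated until max|Δf_i| < 10⁻⁸, with F(ξ_b) = −k_BT ln p_b shifted to
min 0.  On a periodic reaction coordinate the first and last bins are
neighbours (minimum-image bias distances).

## Worked example

```python
import numpy as np
from cetpdyn import synthetic, dynamics, wham

# 1. a plug-bound-like trajectory: barrels coupled in phase
spec = synthetic.OscillatorSpec(n_frames=4096, seed=42)
ens, truth = synthetic.gen_domain_trajectory(spec, coupling="in_phase")
n_angles, c_angles = dynamics.barrel_angle_series(ens, synthetic.PSEUDO_DOMAINS)
report = dynamics.cross_correlation(n_angles, c_angles, max_lag=50).combine(
    dynamics.synchrony_classify(dynamics.hilbert_phase(n_angles),
                                dynamics.hilbert_phase(c_angles)))
print(f"lag-0 cross-correlation: {report.lag0:.3f}")
print(f"in-phase frame fraction: {report.in_phase_fraction:.3f}")

# 2. PMF from umbrella windows drawn off a known periodic curve
pmf_spec = synthetic.AnalyticPMFSpec(form="periodic-cosine",
                                     amplitude_kcal=2.0, period_nm=2.0)
centers = np.round(np.arange(-1.0, 1.0, 0.1), 10)
windows = synthetic.gen_umbrella_samples(pmf_spec, centers,
                                         force_constant_kj_mol_nm2=500.0,
                                         n_samples_per_window=5000, seed=42)
profile = wham.estimate_pmf(windows, -1.0, 1.0, periodic=True, n_boot=20, seed=42)
truth_f = pmf_spec.f(profile.bin_centers); truth_f -= truth_f.min()
print(f"PMF max |error|: {np.nanmax(np.abs(profile.free_energy - truth_f)):.3f} kcal/mol")
print(f"median bootstrap sd: {np.nanmedian(profile.sd):.3f} kcal/mol")
```

Output:

```
lag-0 cross-correlation: 0.952
in-phase frame fraction: 1.000
PMF max |error|: 0.157 kcal/mol
median bootstrap sd: 0.041 kcal/mol
```

The N-barrel of this synthetic replicate oscillates over 33.5–41.5° and
the C-barrel over 45.5–58.2°; because the two are driven with a common
phase, their lag-0 correlation is near 1 and every frame is classified
in-phase.  The recovered free-energy curve tracks the 2 kcal/mol analytic
cosine to within 0.16 kcal/mol, with bootstrap errors of ~0.04 kcal/mol.

## Command-line pipeline

Each stage runs as a subcommand over a YAML config and writes artifacts
plus a manifest (parameters, seed, config hash) under `<out>/<stage>/`:

```sh
cetpdyn fixtures  --seed 1 --out run1
cetpdyn synchrony --seed 1 --out run1
cetpdyn tunnel    --seed 1 --out run1
cetpdyn pmf       --seed 1 --out run1
cetpdyn report    --seed 1 --out run1   # aggregates stage manifests
```

Reruns with the same config and seed are byte-identical; `report` refuses
to mix artifacts produced under different config hashes.

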