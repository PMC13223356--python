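# Methods

This note records the models, estimators and numerical choices behind
`cetpdyn`, what the synthetic generators do and do not emulate, and the
known limits of each method.

## Units and conventions

Lengths are nm internally (PDB Å are converted on load), times ps,
energies kcal/mol (force constants are accepted in kJ/mol/nm² as pull
codes print them, divided by 4.184 on use).  k_B = 1.9872041×10⁻³
kcal/mol/K; the default temperature is 300 K.  Residues are referred to by
their as-authored sequence numbers everywhere a user sees them; internal
indices are 0-based.  Coordinates are assumed whole-molecule: no
periodic-boundary unwrapping is performed, which is correct for the
synthetic fixtures and for post-processed (recentred) MD trajectories but
not for raw wrapped ones.

## Trajectory model

PDB/GRO topologies and XTC/DCD trajectories are read through MDAnalysis
into a minimal in-memory model (atoms, residues, per-frame nm
coordinates).  XTC round-trips coordinates to its storage precision of
0.001 nm.  DCD carries only a nominal step, not wall-clock times; when a
`dt` is supplied, frame times are synthesized as `index·dt` and the
substitution is logged.  The selection mini-language is deliberately
small — `resid A-B[,C-D] [and name N1 N2 ...]` — and an empty selection is
always an error rather than a silent empty result.

## Inter-domain angles

The angle of a barrel against the neck is the angle between two oriented
principal axes: each domain's first principal axis of Cα coordinates,
with the barrel axis oriented from its neck-proximal end to its distal
end, and the neck axis oriented away from the barrel under consideration.
The neck axis is anchored at the barrel's proximal (hinge-side) end
rather than the barrel's centroid — a barrel folded back parallel to the
neck would otherwise flip the neck orientation and report 180° instead of
0°.  The construction is exactly invariant under global rigid transforms
and exact for collinear pseudo-domains, which is what makes the
synthetic-oscillator recovery test an identity to ~1e-9 degrees.

## Instantaneous phase and synchrony

The angle series is linearly detrended (removing mean and slow drift),
its outer edges are Tukey-tapered (α = 0.1), and the analytic signal is
taken by FFT.  The taper removes the periodic-extension discontinuity
whose spectral leakage otherwise contaminates the interior phase.  Because
the Hilbert kernel decays only as 1/t, edge effects die off algebraically:
the first and last 10% of frames are excluded from phase-rate statistics,
and interior phase rates recover a pure tone's angular frequency to within
1% provided the tone completes at least ~80 cycles in the window.  Slower
oscillations need proportionally longer series; the estimator does not
diagnose this itself, so the calibration test documents the domain.

Synchrony is classified per frame from the wrapped phase difference:
in-phase when |φ_a − φ_b| ≤ π/2 (threshold configurable and recorded in
the report).  This maps "in phase" to positive instantaneous co-variation
with a single parameter.  Cross-correlation is mean-removed and
energy-normalized over the full series, so the lag-0 value is the Pearson
coefficient and |r| ≤ 1 at every lag by Cauchy–Schwarz.

## Elastic network modes

The anisotropic network model places uniform springs (γ = 1 by default)
between all Cα pairs within 1.3 nm, assembles the 3N×3N Hessian and
diagonalizes it densely.  Rigid-body modes are identified by
|λ| < 10⁻⁸·λ_max and excluded from the reported set; a disconnected
contact graph is an error that lists the component sizes.  Eigenvalues
scale linearly in γ and the two-atom system has the closed-form single
mode λ = 2γ along the bond, both used as oracles.

## Tunnel axis and profiles

The axis is a polyline through the Cα centers of mass of C-barrel, neck
and N-barrel (arc length measured from the C-barrel end, matching the
pull direction), resampled every 0.2 nm and re-centred laterally on the
Cα centroid within a 0.8 nm slab.  Volume profiling lays a Cartesian
voxel grid (default 0.05 nm) over the axis neighbourhood; a voxel is
tunnel interior when it lies within the radial envelope (default 1.2 nm)
of the axis, projects onto the axis proper (voxels whose nearest axis
point is a clamped endpoint are outside — without this the open tunnel
ends accrete spurious volume), and is farther than (element vdW radius +
1.4 Å probe) from every atom.  Per-element radii: C 1.7, N 1.55, O 1.52,
S 1.8, P 1.8, H 1.2 Å.  Per-bin volume is voxel count × voxel volume;
the per-frame stack is retained for distributional comparison.  Binning
conserves volume exactly (bins partition the axis span), and the profile
is invariant under joint rigid transforms up to voxel re-alignment (< 3%
in tests).

Hydrophobicity profiles average the scale value (Kyte–Doolittle shipped;
any residue→value map accepted) over residues with ≥ 1 heavy atom within
the lining cutoff (default 0.6 nm) of a bin's axis segment; bins with no
lining residues are NaN and excluded from comparisons.

The synthetic cylinder oracle: wall-atom centers are placed at
nominal radius + (atom radius + probe radius), so the probe-accessible
cavity radius equals the nominal radius and the analytic volume πr²L is
exact.  For this geometry the radial envelope must be set inside the
wall's excluded band (0.8 nm for the r = 0.5 nm cylinder); the 1.2 nm
default suits protein-sized inputs where the envelope bounds the tunnel
against unrelated voids.

## Rank-sum comparison

`mann_whitney_u` computes U by pairwise comparison with midrank ties
(equivalent to rank sums).  The two-sided p is exact via the classic
counting recursion (the Gaussian-binomial coefficients) for tie-free
samples with n₁·n₂ ≤ 400; tied samples are enumerated exhaustively when
C(n₁+n₂, n₁) ≤ 20,000; everything else uses the normal approximation with
tie and continuity correction.  Exhaustive permutation of large tied
samples is combinatorially impossible (C(40,20) ≈ 1.4×10¹¹), which is why
the exact path is split this way; the method used is recorded in the
result.  Profile comparisons test each bin's per-frame distributions at
α = 0.05 with no multiplicity correction by default (per-position testing,
as is common for profile figures); Benjamini–Hochberg is available by
flag.

## Lipid path

The lipid trace projects the reference-group COM onto the axis: s(t) is
the arc length of the nearest axis point, r(t) the lateral distance.
Contacts use heavy atoms only (robust to united-atom inputs): a residue is
in contact when its minimum heavy-atom distance to any lipid heavy atom is
≤ 0.6 nm (inclusive), with the ≤ 0.3 nm subset marked "tight"; the > 1 ns
duration rule sums cumulative (possibly non-consecutive) frame time, each
frame weighted by its local spacing.  Path averaging resamples each trace
at equal fractions of its own axial span; because backsliding makes s(t)
non-monotone, the position at a level is taken at the first interpolated
crossing of that level.  Fate classification: traversal when s reaches the
exit threshold before any fallout; fallout when r exceeds the lateral
bound while s lies in the interface window (default: middle third of the
axis, the barrel–neck interface where the first plug sits); first
qualifying event wins; otherwise incomplete.  Hydrophobic patches are
single-linkage clusters (connected components at the 0.8 nm link cutoff)
of contact residues, size ≥ 3.

## Gating and gliding

χ2 = dihedral(CA, CB, CG, CD1), computed through MDAnalysis and reported
in the common atan2 (IUPAC) sign convention; the aromatic ring's two-fold
symmetry reduces it to (−90°, 90°], and a centered 20-ps moving average
(partial windows at the edges, so constants are preserved) gives the
smoothed series.  Gate events are contiguous spans where the smoothed
series deviates from the circular median baseline by ≥ 40° (set below the
~50° excursions it must catch, so noise does not split events) for ≥ 10 ps;
an event is lipid-coincident when the lipid COM comes within 1 nm of the
residue during it.  Directionality is probed by running the detector on
time-reversed traces rather than by a separate reverse-pull pipeline.

Instantaneous velocity is the central finite difference of s(t) (axial
projection; the 3-D speed is available by flag) smoothed by a centered
moving average — exact for affine s(t) at every frame, any window.  Glide
events are spans above mean + 2σ for ≥ 3 frames, with the baseline
mean/σ computed in two passes (candidate spikes from the first pass are
excluded before the second) so that spikes do not inflate their own
threshold.  Tail-plane angles take each acyl tail's vector from the first
to last atom of its terminal segment (terminal 3 carbons by default, the
exact atoms being a user choice); the plane is "parallel" at ≤ 50°.
Salt bridges use formal-charge heavy atoms (Arg NH1/NH2/NE, Lys NZ, Asp
OD1/OD2, Glu OE1/OE2) against the supplied headgroup atoms at a 0.4 nm
cutoff — the conventional definition.

## WHAM

Binning discards each window's equilibration segment, histograms the
production samples on a common grid (default bin width 0.02 nm, five bins
per 0.1 nm window spacing — fine enough to resolve the bias curvature
without starving counts), and evaluates the bias ½k·Δξ² at bin centers
with minimum-image Δξ when the coordinate is periodic.  An overlap
diagnostic flags adjacent windows sharing no occupied bin.  The solver
iterates the standard two equations (gauge f₁ = 0) until max|Δf| < 10⁻⁸,
using log-sum-exp for the window free energies; convergence failure at
10⁵ iterations is an error carrying the residual.  Adding a constant to
all biases provably cancels, and a single unbiased window reduces to
direct Boltzmann inversion — both are asserted as oracles.  Errors come
from a moving-block bootstrap (blocks preserve autocorrelation; no
statistical-inefficiency reweighting is applied, the blocks carry that
burden), each replicate re-shifted to min 0 before the per-bin sd.
Convergence is assessed by re-solving on progressively longer time blocks;
profiles agreeing within 0.2 kcal/mol per bin are called converged.
Averaging PMFs across paths, where used, is the pointwise mean of
per-profile min-shifted curves.

## Synthetic generators: what they emulate, and what not

All generators take a mandatory seed and are bit-reproducible; truth
labels align one-to-one with generated frames/bins.

* **Oscillator** — three rigid collinear Cα domains (20 atoms at 3.8 Å)
  hinged on a neck; θ_i(t) = mean + A·sin(2πft + φ) + noise with the
  defaults matching the observed regimes (N-barrel 37.5 ± 2.5°, C-barrel
  52 ± 5°, Gaussian noise 0.5°; f = 0.002/ps with 10-ps frames, i.e. ~82
  cycles per 4096-frame replicate, inside the phase estimator's validity
  domain).  The biological angle fluctuations have no published force
  constant or noise level, so these are testability choices, not fitted
  ones.  Couplings: common phase (in), π offset (anti), or independent
  random-walk phases with 0.4 rad/frame steps (uncoupled) — the step is
  large enough that the wrapped phase difference mixes many times per
  replicate, keeping single-run in-phase fractions near 1/2.
* **Transit trace** — s(t) integrates a velocity with Gaussian spike
  bumps (default pull speed 1 nm/ns); fallout ramps the lateral offset
  past the tunnel radius from the given frame.  It emulates kinematics
  only: no protein, no forces.
* **Rotamer telegraph** — baseline ↔ baseline+δ over given intervals plus
  Gaussian noise; truth stores the interval mask.
* **Umbrella samples** — Metropolis on F(ξ) + bias (step 0.02 nm, burn-in
  1000, thinning 10, recorded in metadata), pooled from 32 independent
  walkers per window so sampling stays fast on one CPU.  Closed-form
  checks: flat PMF + harmonic bias gives N(ξ_c, k_BT/k); harmonic PMF
  ½aξ² biased at ξ_c gives mean k·ξ_c/(a+k).
* **Tunnel cloud** — rings of pseudo-atoms, one residue per ring, wall
  offset as described above.

Passing on these generators shows the estimators are correct on data
satisfying their assumptions (rigid domains, stationary noise,
equilibrated windows, whole molecules).  It does not show robustness to
force-field artifacts, partial occupancy, wrapped coordinates or
non-stationary drift; the convergence-block and overlap diagnostics exist
precisely because real windows violate stationarity.

## Problem sizes

The shipped tests and the acceptance script run on deliberately modest
sizes chosen as the smallest that make each check sharp: 4096-frame
oscillator replicates, 20 umbrella windows with 8,000 samples each for
curve recovery (50,000 for the flat-control RMS, where the bound is
tighter), a 2,601-atom cylinder on a 0.05/0.025 nm grid, 30 fate traces,
20 null seeds for the gate detector.  The full suite runs in about half a
minute on one CPU.

## Known limitations

* The tunnel-volume method is grid-based with conventional radii; absolute
  volumes from other cavity tools (surface-mesh or sphere-packing) will
  differ systematically, so cross-tool comparisons should be of
  differences, not absolute values.
* The phase estimator's validity domain (≥ ~80 cycles) excludes very slow
  domain motions; for those, longer trajectories are the only remedy.
* The contact filter's cumulative-duration reading of "> 1 ns in contact"
  is switchable to longest-consecutive, but the default treats
  intermittent rebinding as one residency.
* No MBAR, no 2-D PMFs, no autocorrelation-based inefficiency weighting;
  single-temperature WHAM only.
* mmCIF, velocities and box vectors are out of scope for the trajectory
  model.
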