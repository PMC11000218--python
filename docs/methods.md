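# Methods

`unbindkit` implements the analysis layer of a volume-restrained
well-tempered metadynamics study of ligand/product release: the
collective-variable machinery, the bias engine, the reweighting and
standard-state thermodynamics, and unbinding-rate estimation from
biased escape times.  The atomistic simulations such a study rests on
are replaced by overdamped Langevin model systems with known ground
truth, so every stage of the analysis can be validated end to end.

## Model systems and dynamics

Two analytic landscapes stand in for the protein--ligand energy
surface:

* **1D double well** — U(x) = h((x/x0)² − 1)², minima at ±x0 (U = 0),
  barrier h at x = 0.  Default h = 5 kT, x0 = 1.
* **2D radial binding landscape** — Cartesian (x, y) dynamics on a
  radially symmetric profile: a Gaussian bound well (depth 6 kT below
  the plateau at ρ = 1) plus a Gaussian barrier bump (2 kT above the
  plateau at ρ = 2), constant to < 1e-9 beyond ρ = 4.5.  The effective
  well→top barrier of the default profile is ≈ 7.9 kT; `scaled()`
  multiplies all energies to hit a target barrier exactly.  A synthetic
  coordination number C_N(ρ) = 190/(1 + (ρ/1.26)¹²) mimics a
  heavy-atom contact count: ≈ 180 at the well minimum, < 0.01 beyond
  ρ ≈ 2.86, which is the unbinding-commitment radius for the
  threshold C_N < 0.01.

Dynamics are overdamped (position) Langevin integrated with
Euler–Maruyama: x ← x − (Δt/γ_f)∇U + √(2kTΔt/γ_f)·ξ.  Reduced units
throughout (kT = 1, friction 1); physical units (kcal/mol, Å, K) enter
only at the thermodynamics/reporting boundary.  Everything is
seed-deterministic; identical seed and configuration give bit-identical
trajectories (noise is pre-drawn from one `numpy` Generator stream, so
the chunked metadynamics path and the plain integrator consume the same
stream).

Euler–Maruyama carries an O(Δt) sampling bias that grows with the local
curvature; at Δt = 0.005 it distorts the steep double-well flanks by a
few tenths of kT.  The equilibrium-sampling checks therefore run at
Δt = 0.001–0.0025, where the bias is well below the statistical error.

## Well-tempered metadynamics

Hills are Gaussians deposited at the current CV value every
`stride_time`, with heights tempered as
w = w₀ exp(−V(s,t)/((γ_wt−1)kT)), so the bias converges to
−(1 − 1/γ_wt)F(s).  Defaults on the toys: w₀ = 0.8 kT, σ = 0.15,
stride 1.25 time units, γ_wt = 10 (equilibrium runs); w₀ = 0.5 kT,
σ = 0.25, stride 2.5, γ_wt = 15 (infrequent-metadynamics runs, i.e.
deposition slow relative to basin relaxation).  These mirror, at toy
scale, deposition parameters of the protein-scale protocol
(1.2 kJ/mol / 1 ps / γ = 20 for the volume-based runs and
1.5 kJ/mol / 100 ps / γ = 15 for the rate runs).  The bias is evaluated
by direct summation over hills — exact, and affordable at desk-scale
hill counts (10³–10⁴); no grid caching of the bias during dynamics.
The inner integration loops are numba-compiled per deposition chunk.

The one-sided wall V = k(ρ − ρ_s)² (no ½ prefactor — the upper-wall
convention of the PLUMED ecosystem; the protein-scale values are
k = 200 kJ/mol/Å², ρ_s = 28 Å) confines the unbound state.  Angular CVs
are treated as non-periodic: the toy CVs never wrap, and no geodesic
Gaussian distance is implemented — a documented limitation relative to
biasing true spherical angles.

## Reweighting and thermodynamics

Sample weights use the time-independent estimator: after each hill the
offset

c(t) = kT·ln[ Σ_s e^{βγ/(γ−1)V(s,t)} / Σ_s e^{β/(γ−1)V(s,t)} ]

is evaluated on the FES grid (cell-volume weighted, log-sum-exp
stabilized), and each sample carries w ∝ exp(β(V(s_t, t) − c(t))), with
c(t) piecewise constant between depositions.  The FES is
F = −kT ln(weighted histogram density), min-shifted; unvisited cells
are +∞ and excluded from region integrals (with a warning when more
than 10% of a region is unvisited).  Each cell also records a Kish
effective sample count (Σw)²/Σw²; comparisons against analytic
references use cells with ≥ 100 effective samples.  The first 10% of a
run is discarded as the filling transient.

The bound/unbound difference is
ΔG_MetaD = −kT·ln(Σ_bound e^{−βF}dA / Σ_unbound e^{−βF}dA), a
piecewise-constant (midpoint) rule; against adaptive quadrature on an
analytic two-basin surface it agrees to ~3×10⁻⁸ kT at a 2200² grid.
The standard-state correction is TΔS = RT·ln(((4/3)πρ_s³ − V_prot)/V⁰)
with R = 1.9872×10⁻³ kcal/mol/K, V⁰ = 1660 ų (the inverse of 1 M,
asserted consistent to 0.1%); ΔG_b° = ΔG_MetaD − TΔS and
K_d = C⁰·exp(ΔG_b°/RT).  Sign conventions are fixed so that a deeper
bound basin gives ΔG_MetaD < 0, TΔS > 0 for an accessible volume above
V⁰, and more negative ΔG_b° gives smaller K_d.

Statistical errors use block analysis: weighted block means over a
scanned set of block sizes, with the reported error the plateau
(maximum over the scan); for ΔG itself, contiguous-segment estimates
feed the same rule.  Convergence is monitored by recomputing ΔG_MetaD
from data up to a series of checkpoints.

## Rate estimation from biased escape times

Escape under a growing bias is modeled as an inhomogeneous Poisson
process with hazard k₀·e^{γβV_MB(t)}: S(t) = exp(−k₀∫₀ᵗe^{γβV_MB}dt').
V_MB(t) is the survivor-averaged running-maximum instantaneous bias:
at each t only runs still in the initial basin contribute, which keeps
the series monotone (an instantaneous-bias variant is switchable; the
running maximum is the default because the a·log(1 + bt) model assumes
monotone growth).  The model V_MB = a·log(1 + bt) up to a cutoff t_c
(constant beyond) makes the integrated hazard closed-form, including
the logarithmic special case c = γβa = −1 (unreachable for physical
parameters but guarded).  (k₀, γ) are estimated by maximizing the
censoring-aware likelihood (events contribute ln[h·S], censored runs
ln S) with a deterministic coarse log-grid plus Nelder–Mead refinement;
a degenerate a = 0 model makes γ unidentifiable, which is flagged and
k₀ returned as the exact exponential MLE M/Σt.  The cutoff t_c is
scanned over the deciles of the observed V_MB span, keeping the cutoff
that maximizes the KS p-value (ties: smaller D).  The KS test compares
event times (censored runs excluded) with 1 − S(t) using the asymptotic
Kolmogorov p-value, without a parameter-estimation correction — a known
approximation that makes the test conservative (p-values cluster high
under the true model).  Bootstrap intervals resample runs with
replacement, refit (k₀, γ) with the V_MB model held fixed (the survivor
average is an ensemble-level quantity), keep samples passing KS at
p > 0.05, and report the 30th/70th percentiles of k₀.  The
hyperdynamics estimator (t* = ∫e^{βV}dt per run, exponential fit to
rescaled times, KS reported) is provided for comparison and reports its
own KS failure when the CVs are poor.

### Synthetic ground truths

The escape-time generator inverts the survival law analytically (root
bracketing on its own closed-form integrated hazard, written
independently of the fitting module) and attaches the deterministic
V_MB curve as each run's bias trace.  Two regimes are used:

* **study-scale truth** (calibration and bootstrap experiments):
  k₀ = 2×10⁻³, γ = 0.7, a = 3 kT, b = 1, t_c = 10, horizon 200, 41
  runs — slow unbiased rate, plateau ≈ 7 kT reached *within* the
  observed escape window, mirroring a V_MB curve that visibly flattens
  before the last escape.
* **recovery truth** (parameter-recovery oracle): identical except
  k₀ = 1 — the unbiased timescale is comparable to the bias growth, so
  escapes sample the low-bias regime and (k₀, γ) are jointly
  identifiable.  With k₀ ≪ 1 every observed escape is bias-accelerated
  and estimating the unbiased rate is an exponential extrapolation
  along the k₀–γ likelihood ridge; the median error is then ~30% even
  when fitting with the exact V_MB model, irrespective of optimizer
  quality.  A recovery oracle has to probe the identifiable regime;
  the hard regime is exercised separately by the calibration and
  coverage experiments.

### What the bootstrap interval does and does not cover

The 30th–70th percentile band is nominally a 40% interval.  Measured
coverage at the 41-run study scale is ≈ 22–36%: a consistent bootstrap
cannot exceed its nominal level, and the cutoff-scan variability
between replicate ensembles is not mirrored inside the fixed-model
bootstrap.  The interval is a useful indication of multiplicative
spread, not a confidence interval at any comfortable level — a point
worth keeping in mind when reading small-ensemble unbinding rates.

## Full-stack toy infrequent metadynamics

41 independent biased runs start from the bound minimum of the 8 kT
radial landscape (wall k = 50 kT/len² at ρ_s = 3.5) with distinct
seeds; escape is committed when C_N < 0.01.  The reference rate comes
from direct unbiased first-passage runs on a 4 kT copy of the same
landscape, rescaled to 8 kT with the 1D Kramers ratio
√(U''_min|U''_max|)/(2πγ_f)·e^{−βΔU} (curvature and entropic factors
cancel in the ratio up to the energy scale).  The KTR estimate lands
within a factor ~2 of the reference (one-order-of-magnitude check),
with γ near 1, as expected for an ideal CV; independent seeds replace
the source protocol's diversified starting frames, the nearest
equivalent for a memoryless toy.

## Problem sizes and numerical choices

Experiment sizes were chosen so the whole validation suite runs on a
single CPU at desk scale: equilibrium reweighting uses one 5×10⁶-step
run (5000 time units, ~4000 hills); recovery uses 20 replicates of 500
escape draws; calibration 200 replicates and coverage 50 replicates at
41 runs; the toy iMetaD stage uses 41 biased plus 60 unbiased runs.
Log-sum-exp is used for every Boltzmann-weighted sum; the removable
singularity of the switching function at r = r₀ is evaluated
analytically (limit m/n with a first-order series in a 10⁻⁷
neighborhood); the Gaussian-tail flatness of the radial landscape is a
construction constraint (widths chosen so tails are < 10⁻⁹ beyond the
flat radius).

## Limitations

* The model systems are memoryless, low-dimensional and isotropic; they
  validate the *analysis* (reweighting, integration, likelihood,
  calibration), not force fields, solvation or CV design.  Passing
  tests say nothing about whether a particular protein-scale CV set is
  adequate — indeed the γ diagnostic exists precisely because real CVs
  are imperfect.
* Gaussians are non-periodic; angular CVs with wrap-around are not
  supported.
* The KS p-value ignores parameter estimation (conservative), matching
  the procedure it reproduces.
* Protein volume V_prot is an input, never computed (no volumetric
  grid probe).
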