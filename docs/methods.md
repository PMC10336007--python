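# Methods

## Model and units

The fine-grained chain is a bead-spring polymer of N beads, each representing
one nucleosome plus linker DNA (~200 bp).  All computation runs in reduced
units — bead diameter σ = 1, thermal energy k_BT = 1, bead mass 1 — and is
converted at reporting time through a single `UnitSystem` (defaults σ = 21 nm,
200 bp/bead, k_BT = 4.1 pN·nm).  The 21 nm default sits between the two
geometric bounds computed by `estimate_nl_bead_geometry`: neighbouring
nucleosome centres joined by a straight rigid 50 bp linker are at most
11 + 50 × 0.34 = 28 nm apart, while unconnected nucleosomes can approach to
one core diameter (~11 nm).

The force field has three terms:

* harmonic chain bonds, default k = 100 k_BT/σ², r₀ = 1 σ — stiff enough to
  fix the bond scale, soft enough for dt = 0.005;
* harmonic constraint springs encoding contacts, default k = 50 k_BT/σ²,
  r₀ = 1 σ — strong enough to bring a pair into contact range without
  freezing it;
* one non-bonded pair term acting on *all* bead pairs: WCA (purely repulsive,
  the self-avoiding default), truncated-shifted Lennard-Jones (ε = 1 k_BT,
  r_cut = 2.5 σ for the collapsed-globule control), or a tabulated potential
  (natural cubic spline; the force is the spline's analytic derivative; zero
  beyond the cutoff, linear force continuation below the first grid point).

## Langevin integration

Dynamics uses the BAOAB splitting of underdamped Langevin dynamics (friction
γ = 1/τ, dt = 0.005 τ by default), jit-compiled over batches of independent
chains.  The contract is distributional — Boltzmann sampling at the stated
temperature — not trajectory equivalence with any particular MD package.
Velocity initialization is Maxwell–Boltzmann; a run is deterministic given
its seed.

Two robustness mechanisms are always active:

* pair forces at separations below 1e-9 σ are replaced by a capped force of
  10³ along a fixed axis (coincident beads carry no direction);
* per-bead speeds are clamped at 10 σ/τ, ~6× the thermal speed, so the clamp
  is statistically invisible at equilibrium (clipping probability ~e^-50) but
  bounds per-step displacement during the violent transient right after
  long-range constraint springs are inserted, when springs stretched across
  ~100 σ would otherwise drive beads through WCA cores and overflow the
  integrator.

A dt warning fires when dt·√(k_max) > 0.1 (one tenth of the stiffest
harmonic period scale).  Equilibration is detected on the sampled
radius-of-gyration series: the burn-in index is the first point where
consecutive window means agree within 2%; a run with no such plateau is
flagged.  Chain integrity (no bond beyond 3 r₀) is enforced over the
equilibrated portion of a run — the insertion transient is allowed to
stretch bonds temporarily.  Initial conformations are self-avoiding random
placements (unit steps, 0.8 σ exclusion, helical fallback).

## Two-step constrained ensemble

Step 1 bonds each *prominent contact* — an entry `P_ij` at least one
population standard deviation above the mean of its `|i−j|` stratum, for
separations ≥ 2 — independently with probability `P_ij` per configuration
(draws consumed configurations-outer, pairs sorted by (i, j) inner).  A
zero-variance stratum yields no prominent contacts: all its entries are
equal, so none stands out.  After equilibration, step 2 ranks the
configurations by the current distance r_ij of every pair with
`P_ij ≥ 1/n_configs` and bonds the `round_half_even(P_ij·n_configs)` closest,
counting configurations already bonded in step 1 toward the quota; exact
distance ties break toward the lower configuration index.  Quotas come from
a single distance snapshot, so pair order is immaterial and the assignment
reproducible.  Step-1 bonds are retained throughout.  The second
equilibration runs twice as many steps as the first because step 2 inserts
roughly an order of magnitude more springs and the resulting collapse
relaxes more slowly.  The reconstructed map counts a contact when
r_ij < 2 σ — the cutoff must exceed the constraint rest length so bonded
pairs register.

## Coarse-grained observables

Per-genomic-position profiles (R_g, l_cg, θ_cg, overlap) use sliding windows
of n_b beads; distributions and CG polymer quantities (bond lengths, angles,
dihedrals, K_cg, O) use the blocked disjoint partition, since a CG polymer is
made of consecutive disjoint beads.  Bond angles are θ_cg = π − α with α the
angle between successive bond vectors (collinear = 180°); dihedrals use the
right-handed atan2 convention with planar cis = 0° and trans = 180°.  Angle
histograms default to 36 bins of 5°; the sin-measure correction
P̃ = P/sin θ is evaluated at bin centres with the outermost bins masked
(sin → 0).  Effective potentials are V = −ln(density) on occupied bins only
(no extrapolation), minimum shifted to zero.  The two-Gaussian deconvolution
is a bounded least-squares fit to P(θ) (not P̃) over five fixed starts; a fit
whose relative RMS residual exceeds 10% of the mean density is flagged poor.
K_cg uses the population variance (the definition is a distribution moment,
not a sample estimate).  Degenerate geometry (zero-length CG bonds,
collinear triples) is excluded with a logged count rather than raised,
because overlapping soft beads can legitimately produce it.

An exact identity ties the scales together: for any conformation and any
blocked n_b, Rg²(chain) = Rg²(CG trace) + mean within-block Rg².  It is
tested to 1e-10 and explains why the CG trace is always slightly more compact
than the chain it summarizes.

## Iterative Boltzmann inversion

IBI starts from V = 0 and applies
`V_{i+1}(r) = V_i(r) + α(r) ln(P_i(r)/P_target(r))` with
`α(r) = 0.2 e^{−r²/2}` and r in CG bond-length units (the damping form is
dimensionless only in reduced units; the unit choice is exposed in config).
P_i(r) pools distances of all pairs ≥ 2 CG bonds apart over the second half
of sampled frames from a batch of replicas.  Bins with fewer than 10 events
or density below 1e-8 are skipped rather than extrapolated; the table is
re-anchored to zero at its cutoff each update.  Optional stabilization
smooths the *increment* with a 3-point average — smoothing the accumulated
potential instead would blur it further every iteration.  Convergence is
monitored as KL(P_target ‖ P_i) (penalizing missing mass where the target
has support), default tolerance 0.01, and the best-KL iterate is returned.

Two properties of the procedure are worth knowing.  First, KL converges long
before the potential does: the chain's local density screens pair-potential
changes (a 0.3 k_BT change in V moves ln P by only ~0.1), so pointwise
recovery of a known potential to 0.2 k_BT needs ~60 iterations for a mildly
repulsive truth (V₀ ≈ 1.5 k_BT) and proportionally more for stiffer ones.
Second, because α(r) decays rapidly, the update cannot correct the potential
at large r; the cutoff anchor, not the data, fixes the additive constant
there.

The parametric soft form is

    V_soft(r) = V0 [1 − (r/r_m)^η1]^η2 − ε     r < r_m
              = (ε/2)[cos(μ r² + ν) − 1]        r_m ≤ r < r_c
              = 0                               r ≥ r_c

with μ = π/(r_c² − r_m²) and ν = π − μ r_m² solved analytically so the
attractive branch takes value −ε with zero slope at r_m and 0 with zero
slope at r_c; η2 ≥ 1 is enforced in fitting so the repulsive branch also
meets the minimum with zero slope.  Fits take r_m from the tabulated argmin,
ε from the depth, r_c from the first zero crossing beyond r_m (linear
interpolation), and V0, η1, η2 by bounded least squares on the repulsive
branch.  A purely repulsive table degenerates to ε = 0 with an empty
attractive branch.  Softness is 1/F_max, the inverse of the maximum
repulsive force −dV/dr.

## Validation

SCC follows the HiCRep construction: optional 2D mean-filter smoothing
(half-width h, default 1), Pearson correlation per diagonal stratum
s ∈ [2, max_stratum] (default min(50, n/3)), combined with weights
N_s·sd_A·sd_B; zero-variance strata are skipped.  The smoothing parameters
are reported alongside every SCC value.  KL divergence regularizes both
distributions additively (ε = 1e-10) and renormalizes.  Distance histograms
use 0.1 σ bins, auto-truncated at the last occupied bin.  Fine-vs-CG R_g
comparisons measure the fine-grained ensemble on its blocked CG trace so
both sides measure the same object.

## Synthetic data: what it does and does not emulate

`generate_synthetic_map` produces
`P_ij = clip(A s^(−γ) B_ij η_ij, 0, 1)`: power-law decay with genomic
separation (the dominant feature of real contact maps), block-enriched
TAD-like domains (B_ij = boost within a block), and multiplicative
log-normal noise with unit median (preserving positivity and symmetry).
It does not emulate compartment checkerboards, loop anchors/corner peaks,
coverage biases, or balancing artefacts — passing tests demonstrate the
machinery is correct on maps with realistic stratified structure, not that
any biological conclusion transfers to a particular locus.  The ideal-chain
ensemble is sampled exactly (isotropic Gaussian steps with ⟨step²⟩ = b²),
removing integrator error from the control baselines; its bond-length and
angle references are validated against closed-form Gaussian-chain laws and
the P(θ) = ½ sin θ measure.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
statistical targets are comfortably resolved on one CPU: SAW control of
20 × 300 beads, 40 000 steps (window-Rg scaling exponent resolved to ±0.02);
globule control of 12 × 200 beads, 50 000 steps; map reconstruction on a
200-bin synthetic TAD map with 200 configurations (6 000 + 12 000 steps);
IBI recovery on a 50-bead CG chain, 16–24 replicas per iteration, 60
iterations.  Larger maps (to the 5 000-bin dense-storage limit) and longer
runs only improve statistics.

## Known limitations

* Dense map storage; no sparse or cooler-backed input (an extension point).
* No entanglement control: soft potentials permit chain crossing, so dynamic
  (as opposed to ensemble) observables are not meaningful.
* The Langevin engine is O(N²) per step; it targets desk-scale chains
  (≲ a few thousand beads), not chromosome-scale systems.
* Step-2 bonding measures distances on a single end-of-equilibration
  snapshot; time-averaged per-configuration distances are a possible
  refinement.
* Prominent contacts are computed in a single pass, without recomputation
  after excluding selected pairs.
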