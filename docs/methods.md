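# Methods

This note documents the models, algorithms and numerical choices behind
`redelim`, in the spirit of the methods documentation of simulation packages:
what is computed, under which assumptions, and what the synthetic stand-ins
do and do not show about real ab initio data.

## The problem

Alkyl–alkyl reductive elimination from a gold(III) complex,
P(CH₃)₃(CH₃)₂Au⁺, is accelerated by orders of magnitude when the cation is
encapsulated in the anionic supramolecular cage Ga₄L₆¹²⁻ in water.  The
computational route to explaining this combines:

1. **well-tempered metadynamics** in a 2-D collective-variable (CV) space —
   the methyl–methyl carbon distance (Å) and a smooth Au–C coordination
   number — to reconstruct the free-energy surface (FES);
2. the **zero-temperature string method** on that FES to obtain the
   minimum-energy path (MEP), transition state (TS) and activation free
   energy ΔG‡;
3. **committor analysis** to validate that the CV-identified TS ensemble
   commits to reactant and product with near-equal probability;
4. a **transition-state-theory** rate ratio exp(ΔΔG‡/RT) between catalyzed
   and uncatalyzed pathways; and
5. an **electrostatic decomposition**: electric fields from each source
   group (bulk water, the single complexed water, the cage) projected on
   the two reactive Au–C bonds, combined with bond dipoles as
   ΔG_elec = Σᵢ −C (μ_TS·E_TS − μ_RS·E_RS), C ≈ 0.048 kcal/mol per
   Debye·(MV/cm).

Producing the underlying trajectories requires periodic DFT ab initio MD,
which is far outside desk scale.  The package therefore pairs each analysis
stage with a synthetic generator of known ground truth (model potentials,
overdamped Langevin dynamics, grouped point-charge environments), so every
stage is exercised end to end and verified against analytic oracles.  The
electrostatic stage additionally ships a packaged reference snapshot table
of per-group projected fields and bond dipoles for the catalyzed and
uncatalyzed reaction, on which the decomposition is computed exactly.

## Collective variables (`cv`)

The coordination number uses the rational switching function
CN = ½ Σᵢ [1−(rᵢ/R₀)⁸]/[1−(rᵢ/R₀)¹⁴] over the two leaving-methyl carbons.
Exponents 8/14 are used exactly as defined for this system (not the more
common 6/12).  The removable singularity at r = R₀ is evaluated as the
analytic limit p/q = 8/14 inside a relative guard band of 1e−9.  R₀ defaults
to 2.1 Å, a typical Au(III)–C equilibrium bond length, and is configurable
for other metal–ligand systems.  CN is
strictly decreasing in each rᵢ and confined to (0, 1] for finite positive
distances; both properties are tested.

## Synthetic dynamics (`synthetic_data`)

**Surfaces.** The workhorse is the double well
V = h[(x/a)² − 1]² + ½k y² (+ tilt·x/a), with exact minima (±a, 0) at V = 0
and saddle (0, 0) at V = h for tilt = 0.  Defaults h = 6 kcal/mol, a = 1,
k = 2 give a barrier an order of magnitude above k_BT — qualitatively the
regime of the reaction barriers — while remaining crossable by a biased
walker in tens of picoseconds.  The domain is [−3a, 3a] × [−3, 3].

**Dynamics.** Overdamped (first-order) Langevin,
x ← x − μ∇V·dt + √(2μk_BT·dt)·ξ, with mobility μ = 1/friction.  Only
basin-commitment behavior and Boltzmann sampling matter for the analyses
here, so inertia is deliberately omitted.  The Euler–Maruyama step is stable
and accurate when μ·dt·V″ ≪ 1; with the 0.5 fs timestep of the reference
schedule and double-well curvature 8h/a² = 48 kcal/mol/unit², the
metadynamics pipeline uses friction 100 fs⁻¹ (μ·dt·V″ ≈ 0.24).  The generic
default friction is 1 fs⁻¹, intended for small timesteps (the equipartition
test uses dt = 0.02 fs).  Identical seeds give bitwise-identical
trajectories; sampling a harmonic well reproduces var(x) = k_BT/k, the
package's Boltzmann check.

**Metadynamics.** One Gaussian per `pace` steps (fixed-pace reading of an
"at least every 30 steps" schedule), nominal height 0.005 Ha ≈ 3.1375
kcal/mol, widths default (0.1, 0.25) — roughly the equilibrium fluctuation
widths of the default double well at 298 K, following the usual rule of
sizing hills to basin fluctuations.  Well-tempered damping multiplies the
height by exp(−V_B/(k_B ΔT)) with ΔT = (γ−1)T; the reference schedule does
not fix the bias factor, so γ = 15 (a typical well-tempered choice) is the
declared default, always recorded in the hill metadata.  Harmonic
restraining walls (100 kcal/mol/unit², starting 15% of the domain extent
inside each edge) keep the biased walker inside the declared CV domain, the
standard practice for bounded CV spaces; an actual domain exit still raises
an error carrying the last valid frame.  A run-until protocol extends the
trajectory in whole-pace chunks until the CV1 series has committed across
the dividing surface at least three times (hysteresis rule below) *and* a
minimum step count has elapsed; the packaged pipeline uses 100 000 steps
(50 ps) as that minimum.

**Point-charge environments.** Three groups emulate the catalyzed scene:
a shell of randomly oriented three-point (TIP3P-charge) waters at 8–14 Å,
one complexed water ~3.2 Å from the substrate, and twelve −1 e charges on a
7 Å shell for the cage.  The substrate carries two probe bonds (Au at the
origin, carbons 2.1 Å away, ~90° apart).  Ground-truth per-group fields are
computed by an explicit-loop Coulomb sum at each bond midpoint and stored
beside the environment; the vectorized `efield.group_fields` is tested
against them and against exact superposition.

## FES reconstruction (`fes`)

Direct summation of deposited Gaussians gives the bias V_B; the unbiased
estimate is F = −(γ/(γ−1))·V_B for finite γ and F = −V_B for standard
metadynamics, normalized to min F = 0.  Hills are truncated beyond 6.5σ by
default: the neglected tail of a ~3 kcal/mol hill is then ~2e−9 kcal/mol, so
hundreds of hills stay far below a 1e−6 kcal/mol error budget, which the
brute-force (untruncated) oracle test enforces.  A 5σ cutoff would leave
~1e−5 kcal/mol per hill and was therefore rejected.  The default grid is
200×200 over the hill-center range padded by 3σ.

Barrier crossings are counted with a two-threshold hysteresis rule
(default width 0.2 Å on the distance-like CV): a transition is committed
only when the series passes from beyond one threshold to beyond the other,
suppressing recrossing noise; "crossed" is otherwise undefined for a noisy
trajectory.

Single-run well-tempered estimates carry a ripple of the order of the
late-time hill height (here ~1–2 kcal/mol after 50 ps), so barrier estimates
from independent seeds scatter accordingly; the 15% recovery band used in
the end-to-end test reflects that scale, not the truncation or
interpolation error, which are orders of magnitude smaller.

## String method (`string_method`)

The gridded FES is viewed through a bicubic spline (values and analytic
first derivatives continuous across cell boundaries; descent on bilinear
gradients stalls at cell edges).  The string alternates (i) steepest-descent
displacement of every image by −∇F·step and (ii) reparameterization to equal
arc length by piecewise-linear interpolation, iterated to a spacing
uniformity of ~1e−9 relative at the end.  Endpoints are not pinned — they
descend by the full gradient into the basin minima, since the physical RS/PS
are wells, not fixed points.  Defaults are 30 images and 3000 iterations.

The default step is set just under the stability limit of explicit descent,
0.9/κ_max, with κ_max the largest |∂²F/∂x²| + |∂²F/∂y²| over the surface,
and individual image moves are clipped to half a grid spacing.  A fixed
step scaled only to the grid spacing was rejected: on surfaces whose wall
curvature exceeds the transverse well stiffness by two orders of magnitude
it either destabilizes the stiff modes or leaves the soft transverse modes
unrelaxed within 3000 iterations.  Images whose trial move would leave the
grid have that move halved (up to 60 times) before a non-convergence error.

ΔG‡ is the maximum image energy minus the *reactant-side* minimum (not the
global minimum, so an exergonic product well does not inflate the barrier),
with the TS refined by a parabola through the three highest images in arc
length.  A flat or monotone profile raises a "no barrier" error.

## Committor (`committor`)

Candidate TS frames are selected from a CV series by the windows
±0.05 Å (distance) and ±0.005 (CN) around the string's TS.  Commitment is
estimated by shooting momentum-free overdamped Langevin trajectories with
sub-seeds spawned from the run seed; each shot ends on first entry into a
rectangular basin window or at a step cap (timeouts are reported separately,
excluded from p, and warned about above 10%).  Basin windows are centered on
the string's RS/PS minima with half-widths 0.3 × the well separation — a
declared reading of "falls into the equilibrium well", since no geometry is
specified for it.  The 95% interval is Wilson (via statsmodels).  A point is
accepted as a transition state when its CI intersects the band [0.40, 0.60];
CI-overlap semantics (rather than a hard band on the point estimate) are
used deliberately so that small, early-commitment ensembles — e.g. 38% of
50 shots — are still recognized, mirroring how such ensembles are accepted
in practice.

## Electrostatics (`efield`) and kinetics (`kinetics`)

Bond dipoles use the symmetric two-point model about the bond midpoint,
μ = ((q_C − q_Au)/2)·d·4.8032 D/(e·Å), signed along Au→C; fields are
evaluated at the bond midpoint and projected on the Au→C unit vector
(positive = stabilizing orientation, opposite the electron flow of the
elimination).  Both the probe location and the dipole convention are
declared choices — alternatives can be swapped by supplying fields/dipoles
directly.  The conversion constant C is computed from CODATA constants at
import (0.048011 kcal/mol per Debye·MV/cm) and asserted to round to the
conventional 0.048 rather than hard-coded.  The decomposition is linear in
the fields, so per-group contributions add exactly to the total — tested as
group additivity.

The packaged reference table (`redelim/data/reference_fields.csv`) carries
the per-group projected fields and bond dipoles of the catalyzed and
uncatalyzed reaction.  Its partial-charge and bond-length columns are
synthetic placeholders, back-computed to be self-consistent with the stored
dipoles (q_Au fixed at +0.30 e; d = 2.05 Å in RS, 2.60 Å in TS), because the
original per-atom values live in supplementary material that is not
redistributed; they exist so the raw-data consistency check has something to
verify, and they are labelled synthetic in the file header.

TST accelerations use exp(ΔΔG‡/RT) with R = 1.98720e−3 kcal/mol/K and
T = 298.15 K by default.  Note that exp(9/RT) ≈ 3.9e6: an acceleration
quoted for rounded barriers can differ noticeably from the factor implied
by the unrounded ones, and the package makes no attempt to force agreement.

## What the synthetic data does not show

The Langevin/double-well stand-in has no molecular detail: no solvent
degrees of freedom, no inertia, no multidimensional recrossing, and a
barrier (6 kcal/mol) an order of magnitude below the real ~24–37 kcal/mol
(chosen so unbiased commitment and biased crossing are observable in
desk-scale runs).  Passing tests therefore demonstrate the correctness of
the *analysis chain* — hill bookkeeping, unbiasing algebra, string
convergence, committor statistics, field projection and the Eq.-style
decomposition — not the accuracy of ab initio free energies.  Likewise the
point-charge environments validate Coulomb bookkeeping and group
superposition, not DFT-derived field magnitudes.

## Problem sizes

Default desk-scale runs: 50 ps of 0.5 fs steps (≈3300 hills) for the
metadynamics stage, a 200×200 FES grid, 30-image/3000-step strings, and
400-shot committor estimates; the CLI `demo` runs the same chain.
All stochastic stages are reproducible bit for bit from their seeds.
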