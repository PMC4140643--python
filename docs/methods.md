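# Methods

`bindscape` quantifies flexible biomolecular recognition through the
*intrinsic* energy landscape — the micro-canonical density of states
n(E, Q) — of coarse-grained homodimers.  This note records the model, the
estimators, the numerical choices, and what the synthetic test systems can
and cannot show.

## Coarse-grained structure-based model

Each residue is one bead at the C-alpha position (coordinates in nm); all
other quantities are in reduced units (kB = 1, bead mass 1, native-pair
well depth epsilon = 1).  The potential is the standard C-alpha
structure-based (Go-type) form:

| term | form | default |
|---|---|---|
| bond | k_b (r − r0)² | k_b = 100 |
| angle | k_a (θ − θ0)² | k_a = 20 |
| dihedral | k1[1 − cos(φ−φ0)] + k3[1 − cos 3(φ−φ0)] | k1 = 1, k3 = 0.5 |
| native pair | ε[5(r0/r)¹² − 6(r0/r)¹⁰] | ε = 1 (min −ε at r0) |
| excluded volume | ε_rep(σ/r)¹², truncated + force-shifted | σ = 0.4 nm |
| COM confinement | ½k(d − r0)² for d > r0 only | r0 = 6 nm, k = 1000 nm⁻² |

Native contacts are C-alpha pairs within 0.8 nm (same-chain pairs
additionally require |i−j| ≥ 4) and are classified *inter*-chain
(binding, defining Qb) or *intra*-chain (folding, defining Qf).  A contact
counts as formed when r ≤ 1.2 r0.  The excluded volume of each non-native
pair is truncated and force-shifted at min(0.8 nm, 0.95 × its native
separation), which makes the native structure an exact stationary point of
the total potential; the shift is the only deviation from the plain r⁻¹²
form and is negligible (< 10⁻³ ε) everywhere it acts.

The one-sided COM confinement bounds the two chains inside an effective
concentration of ~3.7 mM (two molecules in a 6-nm sphere,
`reference.effective_concentration`); it is flat inside r0 and therefore
does not bias bound states.

**Rigid binding** freezes each monomer: chains become rigid bodies
(translation + rotation, quaternion orientation, principal-axis inertia
from unit bead masses), all bonded and intra-chain terms are removed
exactly, and the inter-chain native and excluded-volume interactions are
bit-identical to the flexible system.  This realizes "binding between
frozen monomers" without stiff-restraint artifacts.

**Interfacial flexibility** rho is the fraction of residues carrying both
an inter-chain and an intra-chain native contact; it measures how strongly
binding and folding are coupled at the interface.

## Dynamics

Flexible chains use the BAOAB splitting of Langevin dynamics
(dt = 5·10⁻⁴, friction γ = 1 by default); with γ = 0 it reduces to
velocity Verlet and conserves energy to < 10⁻³ ε per 10⁴ steps at
dt = 10⁻⁴ (a shipped test).  Rigid bodies follow the same B-A-O-A-B
pattern: the A step advances the quaternion by the body-frame angular
velocity with a midpoint torque-free Euler correction for precession, and
the O step thermostats each principal-axis angular momentum with variance
T·I_k.  The free-rotor substep is approximate (error O(dt²) in the
precession), which is immaterial at the time steps used; rigid-chain
internal distances are preserved to < 10⁻⁹ nm by construction because
coordinates are regenerated from the reference geometry every step.

Replica exchange runs 48 geometric temperatures spanning 0.2–2.2 with
exchange attempts every 20 000 steps by default (toy analyses use shorter
ladders focused on their transitions and denser exchanges); sweeps
alternate even/odd neighbour pairs, the Metropolis criterion is
accept iff u < min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)]) on the full
potential energy of the states actually swapped, and velocities scale by
√(T_new/T_old) on acceptance.  Every replica segment has its own derived
seed, so ensembles are bit-reproducible.

## Density of states and landscape topography

Samples of (E, Q) from all temperatures are histogrammed (default 200
energy bins pooled-range for generic use; the toy analyses use 40, with Q
on its natural contact-count grid) and combined by log-domain WHAM
(damping 0.5, tolerance 10⁻⁷ on the per-temperature free-energy shifts).
Heat capacity, free-energy profiles F(Q;T) and transition temperatures
(Cv-peak argmax with 3-point parabolic refinement, half-height width,
lowest-T tie-break, 1 % twin-peak ambiguity flag) all derive from the DoS
and are invariant under its additive gauge.

Topography of a landscape partitions the DoS into a native macrostate and
the non-native remainder and computes, with count-weighted statistics,

* gap δE = ⟨E⟩_nn − E_native,
* roughness ΔE = std(E)_nn,
* entropy S = ln(Ω_nn / Ω_native),
* glass temperature Tg = ΔE/√(2S) (random-energy-model statistics),
* intrinsic specificity Λ = δE/(ΔE·√(2S)).

The entropy gauge is fixed so the native macrostate holds exactly one
state (Ω_native = 1), making S a pure landscape-shape quantity on the
scale of tens and letting state counts multiply when landscapes are
composed.  The closed forms for Tg and Λ were validated against all 20
published reference columns (five homodimers × rigid/flexible binding and
isolated/dimeric folding): recomputing Λ, Tg and Tf/Tg from the published
gap/roughness/entropy reproduces every published value within the ±0.02
printed-input rounding (a shipped test and `analysis/01`).

### Estimator choices at desk scale

Three choices keep the topography statistics well conditioned for the
small systems sampled here; all are defaults of
`pipeline.landscape_from_ensemble` and are configurable:

1. **Landscape energy = contact energy.**  The folding landscape uses the
   intra-chain native + excluded-volume energy with the bonded terms
   removed, and the global landscape the sum of contact energies.  Bonded
   terms contribute an extensive, temperature-dependent harmonic
   background (~N·T per chain) that blurs n(E) without carrying
   landscape information.  The interfacial (binding) energy never
   contained bonded terms.
2. **Native basin and contact floor.**  The native macrostate is the
   basin Q ≥ 0.85 rather than the single maximal-Q grid point (which is
   sampled too rarely for a stable count), and the non-native ensemble
   excludes the zero-contact stratum: states with no native contact
   belong to the dissociated/denatured continuum, whose statistical
   weight reflects the confinement volume rather than landscape
   topography.
3. **Energy-domain cap.**  Count-weighted non-native moments are
   dominated by the highest-energy occupied bins, because ln n rises
   steeply with E; the highest *sampled* bin is an extreme-value
   statistic and seed-noise dominates it.  The DoS domain is therefore
   truncated at the median energy of the hottest replica, which makes
   the dominant bins well sampled by construction.  The reported S and
   ΔE are thus "up to T_max" quantities; comparisons are made at equal
   T_max (and, for composed landscapes, with the component caps summed).

## Combined vs global binding-folding landscapes

Under weak binding-folding coupling the whole dimer landscape factorizes
into one interfacial-binding and two identical monomeric-folding
landscapes.  On count arrays this is a double discrete convolution over
energy (state counts multiply), and in the native gauge the topography of
the combination follows in closed form:

    δE_comb = δE_b + 2 δE_f
    ΔE_comb = sqrt(ΔE_b² + 2 ΔE_f²)
    S_comb  = S_b + 2 S_f
    Λ_comb  = δE_comb / (ΔE_comb √(2 S_comb))

These forms are exactly the moments of the convolution of the three
*non-native* components (a shipped oracle test).  The directly sampled
global landscape is compared on the same composition strata: its native
macrostate requires binding and both chains' folding in their native
basins simultaneously, and its non-native ensemble is the product region
where all three are partial.  With this stratification the weak-coupling
limit is exact — if binding and folding were independent the stratified
global topography would equal the combination — so the relative
difference (Λ_glob − Λ_comb)/Λ_glob isolates the coupling itself.

## Binding kinetics

Association is measured by ensembles of constant-temperature trajectories
(200 by default) started from randomized dissociated configurations: COM
separation drawn near the confinement radius, independent random
orientations, clash-rejected, and — for flexible chains — internal
coordinates randomized by a short high-temperature burst.  The
first-passage time is the first step at which Qb reaches the stop
threshold and holds for a debounce window (default Qb ≥ 0.8 held for 100
consecutive samples; the toy analyses use an association-type rule,
Qb ≥ 0.25 held briefly, because reaching the fully bound ladder of a toy
interface is orientation-search limited and impractically slow at desk
scale).  Trajectories that never bind are censored at max_steps and
excluded from the mean, with the censored fraction reported.  The MFPT is
the binding time; MFPT_rigid/MFPT_flexible with propagated standard
errors measures the kinetic effect of flexibility.  The kinetic
temperature defaults to 0.9 × the flexible binding transition temperature
and is always logged.

## Synthetic test systems

`make_toy_homodimer` builds two identical chains on a perturbed cubic
lattice (lattice constant 0.5 nm, out-of-plane zigzag 0.15 nm so that no
three consecutive beads are colinear and dihedral geometry is everywhere
regular, Gaussian jitter sigma = 0.01 nm).  The binding interface is a
ladder of one-to-one residue rungs along the fold's edge row; the second
chain is a proper 180° rotation of the first about the interface axis
(C2 symmetry, rung separation ~0.45/0.75 nm by bead parity).  All rungs
share the same geometry; interfacial flexibility is dialed purely in the
contact map, by deleting the intra-chain contacts of the "inter-only"
rungs — as at real interfaces, where residues that bind without folding
contacts still belong to the ordered surface.  The requested rho is
therefore hit *exactly* (rho = coupled rungs / residues), a rho series
varies only the binding-folding coupling at fixed geometry, and
infeasible requests fail with the feasible range.  The native pose is
the exact potential minimum, and native distances never fall below the
excluded-volume radius.

Toy *conditions*: the interfacial well depth defaults to 2 epsilon in the
toy studies (``ForceField.epsilon_inter``), which places the binding
transition in the same temperature range as monomer folding
(Tb_rigid ≈ 1.0, Tb_flexible ≈ 0.7, Tf ≈ 0.9 for the standard trends
toy) — the regime of the real 3-state homodimers, where the published
rigid/flexible binding temperatures bracket the folding temperature.
With equal well depths a small ladder interface binds far below the
folding transition and flexibility has no landscape left to act on.  The
combined-vs-global rho series keeps equal well depths: its stratified
global estimator is unstable when the native binding basin is very deep,
and the coupling effect it measures does not require the 3-state regime.

`make_discrete_dos` inverts the topography measures exactly (native state
at E = 0; e^S non-native states split over δE ± ΔE), providing the oracle
for WHAM-recovery and moment round-trip tests, and `sample_energies`
draws canonical samples from any DoS.

What the toys do *not* emulate: real secondary structure, heterogeneous
contact energies, many-body interface packing, solvent or electrostatic
effects, and the ~10³-contact scale of real homodimers.  Passing toy
tests therefore validates the estimators and the qualitative flexibility
trends (entropy up, roughness down, gap conserved, Λ up; binding
transition temperature down), not the absolute published landscape values
— those enter only through the closed-form table-consistency checks.
Toy analyses run 10-replica ladders for ~3·10⁵ steps per replica; these
sizes were chosen as the smallest at which the topography measures are
stable across replica-exchange seeds (drifts ≪ the rigid-vs-flexible
differences being tested).

## Known limitations

* WHAM error bars are not computed (no bootstrap); stability was assessed
  by independent-seed repeats during design.
* The rigid-body thermostat samples the canonical distribution only to
  O(dt²) in the precession substep.
* Table-scale absolute energies depend on the contact-map definition
  (0.8-nm cutoff, |i−j| ≥ 4); published absolute values are matched in
  trend, not magnitude, by the toys.
* Trajectory output is TSV/JSON text only.
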