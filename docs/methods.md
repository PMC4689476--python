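# Model and numerical methods

## The physical model

The package simulates passive protein patterning in the immunological
synapse: the narrow fluid-filled cleft between an immune-cell membrane and a
ligand-coated surface.  Three coupled fields live on the two-dimensional
contact zone: the gap height `h(x, y, t)`, and the bound densities
`C1` (TCR-pMHC, natural bond length `l1 ~ 15 nm`) and `C2` (LFA-ICAM,
`l2 ~ 45 nm`).

**Mechanics.**  Bound receptors act as Hookean springs spanning the gap, with
stiffness inversely proportional to bond length (`kappa_1 = kappa`,
`kappa_2 = kappa/3`).  Together with membrane bending (modulus
`Bm = E b^3 / 12(1 - nu^2)`) and optionally tension `gamma`, they set the
membrane pressure

    p = Bm lap^2 h - gamma lap h + kappa C1 (h - l1) + (l1/l2) kappa C2 (h - l2).

**Hydrodynamics.**  Because the cleft is thin (`l2/L ~ 5e-3`), viscous flow
obeys lubrication theory, giving a single height-evolution equation

    dh/dt = div( h^3/(12 mu) grad p ).

This is the only time scale in the problem that is slow: squeezing fluid out
of the cleft across the cell scale `L` takes
`tau_L = 12 (L/l2)^2 tau_mu ~ 40 min`, with `tau_mu = mu/(C0 kappa l2)`
the local drainage time.

**Kinetics.**  Binding is gated by the local gap height: a bond of length
`l_i` forms at rate `(1/tau_k) exp(-((l_i - h)/(sigma_on l_i))^2)` and breaks
three times more slowly with the broader width `sigma_off` (`sigma_off = inf`
gives the constant-off-rate variant).  Bound receptors are advected by the
cleft flow, diffuse in the membrane, and drift down height gradients with an
Einstein-relation mobility.  The free receptor pool is well mixed; only bound
densities are fields.

Everything is integrated in dimensionless form (lengths in `L` horizontally
and `l2` vertically, pressure in `p0 = C0 kappa l2`, time in `tau_mu`,
densities in `C0`).  Two groups control the phase diagram: the
bending-to-spring ratio `B = Bm/(kappa C0 L^4)` and the
hydrodynamic-to-kinetic ratio `tau = tau_mu/tau_k`.  The advection/diffusion
ratio `Pe ~ 5e4`, the sliding/diffusion ratio `M ~ 2` and the aspect ratio
`eps = l2/L` enter quantitatively only.  The dimensionless evolution
equations used internally are

    dh/dt = (eps^2/12) div(h^3 grad p),
    p     = B lap^2 h - Gamma eps^2 lap h + C1 (h - lam1) + lam1 C2 (h - 1),
    dC/dt = -div(C u) + (lam1/lam)(1/Pe) lap C
            + (eps^2/M)(lam1/lam)^2 div(C (h - lam) grad h)
            + (ctot - C) K_on(h) - C K_off(h),        u = -eps^2 lam h grad p,

with `lam = l_i/l2`.  The `eps^2/12` prefactor and the `Gamma eps^2` tension
scaling follow from the stated scales; the sliding coefficient is the
Einstein-relation drift `J = -(D_i kappa_i / k_B T) C_i (h - l_i) grad h`
nondimensionalised, which is the reading under which the group `M` enters
the equations at all (the raw printed prefactor of that term is not
dimensionally consistent).  The advective term is implemented in conservative
flux form `-div(C u)` rather than the characteristic form `-u . grad C`:
the two differ by the compressibility term `C div u`, and only the flux form
conserves receptor number under a sealed rim, which we use as a solver
invariant.  Both discretisations are available in `operators.advect`.

## Default parameters

The packaged defaults (`smacsim/data/default_params.toml`) are the reference
literature values: `mu = 0.04 Pa s`, `kappa = 1.2e-6 N/m`, `C0 = 2e14 m^-2`
(LFA total density twice that), `l1/l2 = 15/45 nm`, `D = 5e-13 m^2/s`,
`L = 10 um`, `kBT = 4.34e-21 J`, `sigma_on/off = 0.2/0.6`.  Two defaults are
derived rather than copied:

* `E = 7.91e4 Pa` places the bending modulus at the lower literature endpoint
  `Bm = 4.5e-21 J`, i.e. `B ~ 2e-9`, the baseline of the simulated phase
  diagram (`Bm ~ kBT`).
* `tau_k = tau_mu/15 ~ 2.5e-4 s` (inside the literature range
  `1.1e-5..1.1e-1 s`) makes the default `tau = 15`, the baseline of the
  simulated dynamics.  `tau_k` is always a direct input; it is never derived
  from association constants.

The drainage-time prefactor is 12 (`tau_c = 12 (l_c/l2)^2 tau_mu`,
`tau_L = 12 (L/l2)^2 tau_mu`), which reproduces the dimensional reference
values `tau_c ~ 0.1-1 s` and `tau_L ~ 40 min`.

## Discretisation

Collocated second-order finite differences on a uniform grid over the unit
square (side = one contact diameter `L`); the circular contact zone is the
masked inscribed disk.  All flux operators are assembled from one signed
face-incidence matrix, so every flux divergence telescopes: under no-flux
boundaries the discrete domain sum vanishes to round-off and cleft volume is
conserved exactly.  Face mobilities `h^3` use arithmetic means (the springs
keep `h` well away from 0, so harmonic-mean upwinding buys nothing).
Receptor advection and sliding use first-order upwind face values for
monotonicity; diffusion is centred.

Boundary variants:

* `open_pinned` (default): rim pinned at `h = 0.5 l2`, torque free
  (`lap h = 0` closes the biharmonic stencil), `p = 0` (fluid drains through
  the rim), densities held at their far-field value `0.01 C0`.
* `closed_free`: reflected ghosts; no fluid flux, no bending moment or
  force, no receptor flux.  Conserves volume and arrests the late pattern.

## Time integration

One step advances, in order:

1. **Height (implicit).**  A theta scheme (backward Euler by default) on the
   full nonlinear drainage operator, solved by quasi-Newton iteration.  The
   Jacobian uses lagged mobility `h^3` and frozen densities; its sparse LU
   factorisation is reused across steps (and across nearby step sizes) as a
   preconditioner, and the residual always uses the current right-hand side,
   so the accepted update solves the theta equations to `newton_tol`
   regardless of Jacobian staleness.  Because the Jacobian and residual are
   both in flux form, every Newton iterate conserves volume exactly.
2. **Receptor transport (explicit).**  Upwind advection + sliding, CFL
   limited (`cfl_safety = 0.5`).
3. **Receptor diffusion (implicit).**  Constant-coefficient backward Euler;
   factorisations cached per step size.
4. **Kinetics (exact).**  The binding source is linear in `C` pointwise, so
   it is relaxed exactly toward the local fixed point
   `ctot K_on/(K_on + K_off)`; this is unconditionally stable and keeps
   `C` in `[0, ctot]` with no kinetic step-size restriction.

Step sizes live on a geometric ladder (`dt_init * 1.2^k`): grown one rung
after 5 consecutive accepts, cut four rungs (~halved) on rejection
(positivity loss, bound violation, Newton failure, or per-step height change
above `max_dh = 0.02 l2`), and clipped to the CFL limit and the next
snapshot time.  Ladder quantisation makes factorisation caches effective.
A step-size underflow below 1e-12 raises a stiffness error carrying a
diagnostic snapshot.  The height is guarded by a floor `h_min = 1e-3 l2`;
reaching it signals under-resolution, not physics, and rejects the step.

Snapshot times are deterministic synchronisation points: all caches are
dropped there, so restarting from any archived snapshot reproduces the
uninterrupted trajectory bit for bit (the archive stores the step size and
accept-streak alongside each snapshot).

## Initial conditions

The standard initial state is a flat film at `h = 0.5 l2` decorated with six
Gaussian bumps of width ~`0.1 L` (standard deviation `width/2`, widths
jittered by +-20%) and amplitudes drawn uniformly from `(0.075, 0.1) l2`,
with both bound densities uniform at `0.01 C0`.  Bump centres default to a
fixed hexagon at radius `0.3 L` (the arrangement is not specified by the
underlying model; a seeded uniform-random placement is available).  All
randomness flows through one integer seed; identical seeds give
bit-identical states.

This generator emulates the modelled experiment (a cell landing on a
uniformly ligand-coated supported bilayer) but not features of real synapses
such as pre-clustered ligands, membrane roughness/fluctuations, or active
cytoskeletal forcing — conclusions from passing tests therefore concern the
passive model, not cell-to-cell variability.

## Resolution and problem sizes

The bending-spring balance sets the cluster scale
`l_c = (Bm/(C0 kappa))^(1/4) ~ 70-200 nm`, i.e. `0.007-0.02 L`: fully
resolving it at the baseline `B = 2e-9` would need grids far beyond what this
package targets.  The shipped analyses use desk-scale grids chosen so that
the Nyquist mode is bending-damped (`B (pi n)^4` above the spring stiffness):
64x64 for baseline runs and phase-diagram cells, 32x32 or smaller for unit
tests.  At 32x32 and `B = 2e-9` the pattern collapses to grid-scale
checkerboards (under-resolved interfaces); at 64x64 structures are resolved
but coarse.  Consequences worth stating plainly:

* Bound-receptor time series are qualitatively robust (sharp TCR rise, an
  interior maximum, monotone LFA growth, late decay toward a single-species
  flat state under the open rim).  The time of the TCR maximum is converged
  from 64x64 on (2.89 min at 64x64 vs 2.93 min at 128x128 for the default
  seed, and 2.9-3.0 min across seeds), while 32x32 is qualitatively off
  (~10 min): peak-time statements in this package always refer to grids of
  at least 64x64.  The peak *magnitude* still drifts ~15% between 64x64 and
  128x128 and is treated as order-of-magnitude only.
* Phase-diagram regime *ordering* (no pattern at small `tau`; dispersed
  clusters / bulls-eye at large `tau`) is reproduced at desk scale; the
  precise `tau` boundaries are resolution dependent and only the ordering is
  tested.

## Pattern metrics

Clusters are 8-connected components of `C > 0.3 ctot` with at least 4
pixels.  Regimes: `no_pattern` if `max C1 < 0.2 ctot1`; `bullseye` if a TCR
cluster covers the domain centre and LFA occupies >= 60% of angular bins at
larger radius; `kinetic_clusters` if >= 3 disjoint TCR clusters without a
bulls-eye; else `intermediate`.  None of these labels has a standard
quantitative definition; the thresholds are fixed documented constants in
`AnalysisConfig`, calibrated on constructed fixtures (concentric disk+ring,
scattered blobs), and the defaults are used everywhere.

## Known limitations

* No Darcy-regime flow law, membrane permeation, thermal fluctuations or
  active cytoskeletal stresses (deliberately out of scope of the passive
  model).
* First-order upwinding smears receptor fronts by a few cells; cluster
  diameters at desk resolution carry O(dx) uncertainty.
* The conservative advection form can transiently compress `C` toward
  `ctot`; values are clamped to `[0, ctot]` (clamp events are counted and
  essentially never occur in practice because the off-rate relaxes
  compressed regions first).
* Late-time behaviour under the open rim (slow decay toward a single-species
  state) takes hours of simulated time; runs stop at the conventional
  40-minute evaluation point.
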