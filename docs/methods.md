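# Model and methods

`adhesim` simulates the assembly of a nascent integrin adhesion on a small
patch of cell membrane, and the way an overlying actin fiber stabilises and
elongates it. This note records the model, its numerical treatment, the
design choices that were genuinely open, and what the simulator does and does
not capture.

## The physical model

**Geometry.** A 2D square domain of side `L = 1 um` with periodic boundary
conditions represents the membrane patch. Extracellular ligands are fixed at
the vertices of a 20x20-cell lattice (50-nm spacing, both edges included:
21x21 = 441 ligands; the edge vertices on opposite sides are periodic images
of each other but are kept as distinct ligands so the advertised count is
exact). `N = 300` integrins are point particles, initially uniform over the
domain, each either *free* (diffusing) or *ligated* (bound to exactly one
ligand).

**Motion.** Inertia is negligible at these scales, so each integrin follows
overdamped Langevin dynamics, integrated with explicit Euler:

    r_i(t + dt) = r_i(t) + F_i / zeta_i * dt,
    F_i = F_T + F_sub + F_myo.

* `F_T`: thermal force; each component is Gaussian with zero mean and
  standard deviation `sqrt(2 kBT zeta_i / dt)` (fluctuation–dissipation), so
  the per-step displacement scale is `sqrt(2 D dt)` ≈ 3.4 nm at the
  defaults. All integrins, free or ligated, receive it.
* `F_sub`: the harmonic integrin–ligand bond, `k * dL` directed toward the
  ligand, where `dL` is the minimum-image separation minus the rest length
  `L0 = 0.01 nm` and `k` (0.1–0.7 pN/nm) mimics substrate stiffness. Only
  ligated integrins feel it.
* `F_myo`: a constant actomyosin load (0–40 pN) along the fiber axis (+x),
  applied to ligated integrins in scope (see *fiber* below).

The friction coefficient comes from the Einstein relation,
`zeta = kBT / D = 4.11e-3 pN um / 0.058 um^2/s ≈ 0.0709 pN s/um`, and is the
single mobility parameter: a 5 pN force drifts an integrin ~7 nm per step,
30 pN ~42 nm.

**Binding.** A free integrin within 20 nm (the reach of the extended
integrin headpiece) of at least one unoccupied ligand binds during a step
with probability `p_on = 1 - exp(-kon dt)`, pairing with the *nearest* free
ligand. The bond forms at the current separation; the spring then pulls the
integrin in (relaxation time `zeta/k` ≈ 0.1–0.7 ms). `kon = 1/s` baseline.

**Unbinding.** Each bond ruptures with `p_off = 1 - exp(-koff(F) dt)` at the
current spring tension `F = |k * dL|`, with two-pathway catch–slip kinetics

    koff(F) = a1 exp(-b1 F) + a2 exp(+b2 F),
    (a1, b1, a2, b2) = (2 /s, 0.1 /pN, 4e-6 /s, 0.3 /pN).

The lifetime `1/koff` rises with load up to
`F* = ln(a1 b1 / a2 b2)/(b1 + b2) ≈ 30.06 pN` (catch regime) and falls
beyond (slip); above ~43.7 pN a loaded bond is shorter-lived than an
unloaded one. The rupture-rate argument is the spring tension, not the
instantaneous total force: thermal and myosin forces load the bond only by
stretching it, which at quasi-equilibrium they do almost completely (the
spring relaxes three orders of magnitude faster than bonds turn over).

**The actin fiber** is not a mechanical object but a 300-nm-wide strip
across the domain centre with three local effects:

* *bundling-enhanced activation*: each step, each free in-strip integrin
  draws the enhanced rate `kon = 3/s` with probability `P_bundling`
  (fresh Bernoulli per integrin per step — the expected enhanced fraction
  equals `P_bundling` with no hidden persistent state);
* *contractility*: ligated in-strip integrins are loaded with `F_myo` along
  +x. A `myo_scope = "global"` mode loads *every* ligated integrin instead,
  for contractility-versus-stiffness experiments without a fiber template
  (this is the reading that reconciles the domain-wide ~55–65% peak ligation
  in the load/stiffness regime with the much lower fiber-restricted values);
* *variants*: a friction multiplier for free in-strip integrins (slowed,
  directed motion under a fiber; the thermal noise follows the local
  friction so Einstein's relation gives `D/multiplier` under the strip) and
  an imposed retrograde actin flow displacing ligated in-strip integrins by
  `v dt` per step (default 0; at 100 nm/s the spring absorbs the drift with
  a ~0.01 nm offset, leaving bond tensions unchanged).

Strip membership is evaluated on the integrin's current position, boundary
inclusive.

**Update order within one step** (engine contract): (1) resolve per-integrin
friction and binding rate; (2) assemble forces; (3) Euler move + wrap
(+ flow shift); (4) unbinding attempts; (5) binding attempts; (6) ligated-
time accounting. Sampling records the instantaneous state every 1 s. The
first 100 s are a burn-in marker — analysis windows default to
(t_burnin, t_total] but any window can be requested, so both 100–300 s and
100–500 s conventions are expressible.

## Parameters that matter

| name | default | units | role |
|---|---|---|---|
| `k_sub` | 0.6 | pN/nm | substrate stiffness; sets bond tension per stretch and hence rupture rate |
| `F_myo` | 0 | pN | actomyosin load on ligated integrins in scope |
| `P_bundling` | 0 | – | probability a free in-strip integrin activates at the enhanced rate |
| `kon_base`, `kon_fiber` | 1, 3 | 1/s | activation/binding rates outside/under the fiber |
| `r_bind` | 20 | nm | capture radius (integrin headpiece reach) |
| `D_free` | 0.058 | um²/s | free-integrin diffusivity; fixes `zeta` via Einstein |
| `dt` | 1e-4 | s | Euler step; see *numerics* |
| `t_total`, `t_burnin` | 300, 100 | s | run length and analysis-window start |

All parameters are validated together (positivity, `P_bundling` in [0,1],
lattice spacing tiling the domain exactly, `zeta` within 2% of the Einstein
value unless kBT = 0, integer step/sample ratios).

## Numerics

* **Timestep.** `dt = 1e-4 s` resolves the stiffest default spring
  marginally: the dimensionless rate `a = k dt / zeta` reaches 0.99 at
  k = 0.7 pN/nm (stable for a < 2). Euler discretisation inflates the
  stationary bond-extension variance by `2/(2 - a)` (up to ~1.7x at
  k = 0.6–0.7), i.e. mean thermal tensions of ~2.5 pN instead of ~2 pN.
  Because `koff` is locally flat there, steady-state observables are
  insensitive: runs at dt = 1e-4 and 1e-5 agree within replicate noise
  (asserted in the suite). Equipartition itself (`var = kBT/k` per
  component, e.g. 6.85 nm² at k = 0.6) is asserted at dt = 1e-6 where the
  inflation is 0.4%.
* **Sub-rest-length bonds.** The per-axis bond force divides by `dL`; for
  `dL <= 0` (separation under 0.01 nm — measure-zero) the force is set to
  zero instead of diverging.
* **Degenerate PCA.** The adhesion angle is the acute angle between the
  leading covariance eigenvector of the ligated positions and the fiber
  axis, folded into [0°, 90°]. Periodic coordinates are first unwrapped
  about their per-axis circular mean so clusters straddling the seam are
  treated whole. Samples with fewer than two ligated integrins, coincident
  points, or an isotropic covariance return *undefined* (NaN) and are
  excluded from window means.
* **Abort on corruption.** A non-finite position aborts the run with a
  diagnostic rather than being clamped; positions are also kept wrapped even
  under runaway spring transients, so lattice indexing stays in-bounds.
* **Event accounting.** Per-integrin total ligated time is reconstructed
  exactly from the event log (closed-bond durations plus open bonds at
  t_total); it equals the time-integral of the ligated count to within one
  dt per event.

## Random numbers

The production kernel consumes ~6x10^6 random variates per simulated second
(two Gaussian components per integrin per step plus kinetic draws), which
makes generation the dominant cost. It therefore carries its own
xoshiro256++ bit generator (seeded from the run seed via SplitMix64) and a
128-layer Marsaglia–Tsang ziggurat for normals, inlined into the compiled
loop; the suite verifies the output distribution against scipy
(Kolmogorov–Smirnov, moments, |z|>3 tail mass) and stream determinism. Rare
Bernoulli events are *thinned*: one uniform per bond (or per free integrin)
is compared against a precomputed upper bound of the per-step probability,
and the exact probability — which needs the rupture-law exponentials or the
nearest-ligand search — is evaluated only when the uniform falls under the
bound. Thinning is exact: `P(u < p)` is unchanged by skipping the evaluation
when `u >= p_cap >= p`. Binding contention (two integrins drawing the same
ligand in one step) is resolved by shuffling the per-step list of successful
candidates and committing them sequentially, re-searching if a ligand was
just taken — equivalent to visiting all integrins in random order, at a cost
proportional to the (rare) successes. The initial positions are drawn from a
numpy PCG64 generator seeded with the same run seed; a trajectory is a pure
function of (parameters, seed) and is reproduced bit-for-bit on re-run.

A readable numpy reference implementation of the identical update
(`engine.step`, `method="reference"`) backs the unit tests; kernel and
reference are cross-checked statistically on shared conditions.

## What the simulation does and does not emulate

The model reproduces, with literature-scale parameters, the regime structure
of nascent-adhesion stabilisation: a steady ~20–25% ligated fraction on a
stiff substrate without load; load-and-fail non-monotonicity of ligation
with contractile force (rising toward the ~30 pN lifetime optimum, collapsing
deep in the slip regime); enrichment, faster binding, longer total bound
times and elongation along the fiber under a non-contractile bundled strip;
and additive bundling x contractility gains at intermediate force.

Two families of published anchor values are *not* reproduced by these
equations, and the package reports its honestly computed values instead
(see the acceptance script):

* the absolute domain-wide binding-event rate: at steady state the binding
  flux must equal `B * <koff>` (B = bound count); with `koff(F≈0) ≈ 2/s` and
  ~25% ligation this is ~100–150 events/s, not ~18–23/s. The *relative*
  fiber enhancement (~1.3x) is reproduced;
* the location of the collapse threshold: with bond tension equilibrating to
  `F_myo`, ligation falls below its unloaded level only beyond ~44 pN (where
  `koff(F) > koff(0)`), not at 30–35 pN.

Real nascent adhesions also involve talin unfolding and force buffering,
vinculin recruitment, ligand mobility, membrane curvature and 3D geometry —
all outside this model: cytoskeletal force acts directly on the
integrin–ligand spring, and activation is collapsed into the binding rate.
Passing tests therefore certify the stochastic mechanics/kinetics engine and
its observables, not a quantitative model of any particular cell system.

## Problem sizes used by the automated checks

The acceptance script runs the full study conditions: 300 integrins,
dt = 1e-4 s, three replicate seeds per condition, 300-s runs analysed over
100–300 s (500-s runs analysed over 100–500 s for the fiber/no-fiber event
rates and bound times). The pytest acceptance layer uses scaled-down runs
(150–300 s, two seeds) — the asserted metrics are stationary after burn-in,
so the scale affects replicate noise, not the expectation; micro-scale
physics checks (diffusion, equipartition, single-bond lifetimes) use the
small dedicated fixtures described above.
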