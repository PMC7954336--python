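# Methods

`nfsim` models the slow axonal transport of neurofilaments (NFs) along a
single axon that contains one unmyelinated node of Ranvier embedded in
myelinated internode. Experimentally, NFs move ~7.6-fold faster through
the node than through the internode, and the internode holds ~7.6-fold
more NF per unit length. The package asks whether phosphorylation of the
NF side arms — high in the internode, low in the node — can produce both
observations purely by modulating the rate at which an NF engages a
microtubule track.

## The stop-and-go chain

The core is a continuous-time Markov chain over kinetic states:

* `Pa`, `Pr` — running anterograde (`v_a = 0.52 um/s`) / retrograde
  (`v_r = -0.36 um/s`);
* `Pa0`, `Pr0` — pausing while on track;
* off-track pausing states (disengaged from the microtubule).

Transition rates (defaults, s^-1): `gamma_10 = 0.14` (run → on-track
pause), `gamma_01 = 0.064` (pause → run), `gamma_off = 4.45e-3`
(on-track → off-track), `gamma_on` (off-track → on-track, the regulated
quantity), and the very slow direction reversals `gamma_ar = 4.2e-6`,
`gamma_ra = 1.4e-5`. With `q1 = gamma_10/gamma_01`,
`q2 = gamma_off/gamma_on`, `q3 = gamma_ar/gamma_ra` the steady state is

    pa = rho,        pr = q3 rho,
    pa0 = q1 rho,    pr0 = q1 q3 rho,
    pap = q1 q2 rho, prp = q1 q2 q3 rho,
    rho = 1 / ((1 + q1 (1 + q2)) (1 + q3)),

and the long-run mean velocity is `vbar = rho (v_a + q3 v_r)`. Because
`vbar` is monotone in `gamma_on`, a target regional velocity can be
inverted for the on-track rate (`gamma_on_from_velocity`); the admissible
interval is `(0, (v_a + q3 v_r)/((1+q3)(1+q1)))`, the velocity of a chain
that never leaves the track.

## Phosphorylation variants

Phosphorylation/dephosphorylation is a two-state switch with rates
`gamma_ph`, `gamma_de` (defaults 0.8/0.1 s^-1 in the internode, swapped
in the node), giving equilibrium phosphorylated fraction
`alpha1 = gamma_ph/(gamma_ph+gamma_de)`.

**six_phospho** duplicates all six states into phosphorylated /
dephosphorylated copies (12 labelled states); the on-track rate is
`2.75e-4 s^-1` while phosphorylated and `5.16e-3 s^-1` while
dephosphorylated. No closed form exists; its steady state is the null
eigenvector of the 12x12 rate matrix.

A modelling subtlety with consequences: with `gamma_ph, gamma_de` far
above the on/off-track rates, a literal label that keeps switching in
every state averages the *rates* (fast-exchange limit), whereas the
analytic treatment — mean velocity as the phospho-weighted mixture
`V = v_fast f_de + v_slow f_ph` — assumes each sub-population transports
at its own velocity (slow-exchange limit). The two limits give different
node:internode ratios (2.85 vs 3.96 at the default parameters; for a
two-component mixture the slow-exchange ratio equals
`(8 A1 + A2)/(A1 + 8 A2)` with `A_p = 1 + q1 (1 + q2_p)`, which the
rate-averaging limit does not reproduce). The default therefore freezes
the phospho label for the duration of each off-track dwell (exchange
stays active in the four on-track states, where the label has no kinetic
effect); `SixPhosphoRates(exchange_off_track=True)` selects the literal
all-state exchange instead. The frozen-dwell chain reproduces the
mixture regime exactly at steady state.

**eight** splits only the off-track pausing states:
`Pap1/Prp1` (phosphorylated, re-engage at `gamma_on1`) and `Pap2/Prp2`
(dephosphorylated, `gamma_on2 > gamma_on1`), with phospho exchange
inside the off-track pool. The mean velocity keeps the six-state form
with the effective

    q2 = 2 gamma_off / (alpha1 gamma_on1 + alpha2 gamma_on2),

and the closed-form occupancies split the off-track mass by
`alpha1 : alpha2`. That split is the fast-phospho-exchange
approximation, not the exact null eigenvector: at the default internode
parameters it agrees with the eigenvector to ~0.1%, at the node
parameters the small `Pap1` entry deviates ~30% relative (3e-3
absolute) while all headline velocities agree to 0.3%.
`steady_state(..., method="numeric")` returns the exact eigenvector;
the property tests compare the two only in the phospho-dominant regime.

Inverting the eight-state velocity for `gamma_on2`
(`gamma_on2_from_velocity`) at the target velocities 1.01 mm/day
(internode) and 7.6 x 1.01 mm/day (node) gives `5.12e-3` and
`5.76e-2 s^-1`; the quoted values `5.16e-3` / `6.01e-2` differ by
0.7% / 4% because they inherit the 2–3 significant figures of the
printed velocities. The bundled profiles recompute the rates from the
velocities by default (`canonical_profile_eight(reconstruct=False)` uses the
quoted values).

## Analytic ratio curves

If the fast (dephosphorylated) mode is `n`-fold faster than the slow
mode and the internode phospho ratio is `r` (node `1/r`), the mixture
velocities give the node:internode ratio `(n r + 1)/(r + n)`
(`ratio_curve_six`). The curve saturates at `r`, never exceeds `n`, and
inverts in closed form: reaching a 7.6-fold boost with `r = 8` requires
`n = 149.5`. `ratio_surface_eight` computes the same ratio for the
eight-state chain from two closed-form velocities.

## PDE engine

Per-state concentrations on a uniform grid obey advection–reaction
equations: only `Pa` and `Pr` advect; all states react through the rate
matrix of the local region (node rates on the half-open interval
`[node_start, node_end)` = [20, 30) um of a 50 um axon). Space is
discretized by first-order upwind differences (backward for `v_a > 0`,
forward for `v_r < 0`), time by explicit Euler. Defaults `dx = 0.1 um`,
`dt = 0.1 s` give CFL number 0.52; the stiffest reaction rate
(0.8 s^-1) is stable at this step. Boundary conditions: the proximal
ghost cell is empty (pure outflow for `Pr`, no inflow for `Pa`), the
distal ghost is zero-gradient — which both lets `Pa` leave and sustains
the retrograde pool as an infinite-axon continuation would. One NF unit
per second enters the running-anterograde state of the first cell.

The initial interior condition places the expected equilibrium density
`influx / vbar(x)` in each cell, split across states by the local
steady-state fractions; the run then only has to relax boundary layers
and the slow retrograde mode. Convergence is declared when the maximum
relative change of the per-cell total density over a 60 s window drops
below `tol = 1e-6`; with `t_max = 3.6e5 s` the canonical eight-state run
converges at ~3.0e5 s of model time (~2 min of wall time). The density
profile is piecewise flat much earlier (stable to four digits from ~3
model hours); the strict tolerance waits out the slow
anterograde↔retrograde mode (`gamma_ra + gamma_ar ~ 1.8e-5 s^-1`).
`equilibrium_direct` solves the same discrete operator by a sparse
linear solve and is used as an independent oracle for the stepping.

A conservation note: the eight-state retrograde pausing balance couples
`Prp2` (not `Pap2`) into `Pr0` — the variant that re-uses `Pap2` breaks
the zero-column-sum property of the generator and cannot hold a
normalized steady state. The implementation builds every engine from
one `transition_matrix`, so conservation is structural.

## Monte Carlo engine

Independent particles follow the same chain under a fixed-step kinetic
Monte Carlo scheme: per step of `dt = 0.1 s`, at most one transition,
each candidate sampled with probability `rate * dt` (max total exit
rate 0.9 s^-1 keeps the per-step probability <= 0.1; larger `dt` is
rejected at setup). Running particles move by `v dt` using the rate set
at the pre-step position; a particle crossing the node boundary
mid-step simply uses the pre-step region (O(dt) error). One NF is
injected at `x = 0` every 10 s in the running-anterograde
(dephosphorylated) state; particles leaving [0, 50] um are removed.
300 replicates by default (50 in the bundled reproduction runs), each
on its own RNG stream spawned from the master seed, so results are
independent of scheduling or worker count.

Censuses are time-averaged after a burn-in. The default burn-in is the
internode transit time `L / vbar` plus five off-track pool turnover
times (pool occupancy / influx at steady state, ~3.3e3 s for the
six-phospho internode): transit alone is not enough, because the
off-track pool — holding ~90% of the mass — fills on the `1/gamma_on`
scale. Observation then runs for 6000 s, sampling every 10 s. Counts
are binned in 2 um bins (25 bins); regional populations *and* regional
state occupancies are tallied over region interiors, trimming one bin
width at every domain and region boundary, so that the velocity
estimator `V = p_a v_a + p_r v_r` and the population estimator sample
identical cells (otherwise the injection layer near `x = 0` inflates
the internode velocity and the continuity residual).

Boundary removal has a physical consequence worth knowing when
comparing with closed forms: the anterograde→retrograde conversion
(`gamma_ar ~ 4e-6 s^-1`) is far slower than the ~1 h residence time, so
the retrograde family is strongly depleted relative to the infinite-
axon steady state and absolute MC velocities exceed the closed-form
values. Ratios between node and internode survive, because the
retrograde factor `(1 + q3)` is region-independent and cancels.

## Summaries

`summarize_census` / `summarize_field` report per-region populations
(mean count per interior bin), occupancy-based velocities in um/s and
mm/day (1 mm/day = 1000/86400 um/s), fluxes `N V`, the node:internode
velocity ratio, the internode:node population ratio, and the continuity
residual `|N1 V1 - N2 V2| / (N1 V1)`, which is <2% for the equilibrated
bundled runs (threshold 5% in the tests).

## What the simulations do and do not show

All inputs are model parameters; there is no external data. The engines
demonstrate internal consistency of the phosphorylation mechanism —
that one parameter, the phospho-controlled on-track rate, yields the
reciprocal 7.6-fold velocity and population contrasts, and that PDE,
particle simulation and closed forms agree where they should. They do
not fit the phospho rates to measurements (no such measurements exist
per region), model NF–NF bundling or track occupancy, or resolve
multi-site phosphorylation: the NF is a single unit with a binary
phospho state. Node length is 10 um for display purposes; real nodes
are ~1–2 um, and all results depend on the rates, not the node length.

## Problem sizes of the bundled reproductions

PDE: 500 cells x 8 states, run to the 1e-6 window criterion (~3e6
steps). Monte Carlo: 50 replicates, ~2.8e4 s (six-phospho) / ~1.8e4 s
(eight-state) of model time per replicate at `dt = 0.1 s`, ~300–500
live particles at steady state. The closed-form quantities are exact
arithmetic.
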