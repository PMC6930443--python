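# Methods

## The model

`clicksim` simulates *click assemblies*: sets of immune cell populations
connected by directional kill interactions ("clicks" — receptor–ligand
pairings in which exactly one partner dies), within-lineage maturation, and
bystander help. Two structural rules define a valid assembly: a click is
exclusive to a pair of populations, and killing is directional, so the
kill graph has at most one edge per unordered pair and every directed
cycle has length ≥ 3. The sustaining core of an assembly is its smallest
directed kill cycle; `smallest_directed_cycle` finds it by per-node
breadth-first search, with ties broken by the lexicographic order of the
sorted member list and the cycle reported starting from its smallest
member.

### Mean-field dynamics

The deterministic backend integrates a generalized Lotka–Volterra system.
For population i with growth rate r_i, death rate d_i, help coefficient
β_i at help level h_i, carrying capacity K shared across the assembly,
kill rates κ_{ji}, and maturation rates m:

    dP_i/dt = P_i [ r_i (1 + β_i h_i)(1 − Σ_j P_j / K) − d_i − Σ_{j⊣i} κ_{ji} P_j ]
              + Σ_{l→i} m_l P_l − m_i P_i

This is the simplest form that expresses all four ingredients: logistic
self-limitation through the shared total (which bounds every trajectory),
mass-action contact killing, linear maturation flow, and bystander help as
a multiplicative growth modifier that changes population sizes without
touching the kill wiring. Four-species Lotka–Volterra systems of this kind
are known to support coexistence, bistability, and sensitive transitions,
which is the repertoire the canonical assembly needs.

Integration uses LSODA with absolute/relative tolerances 1e-9/1e-7 by
default; output is sampled on a uniform grid, negative solver undershoot
is clamped to zero after sampling (the clamp magnitude is logged), and a
run is flagged converged when max |dP/dt| < 1e-6 at the final time.
Equilibria are located with a hybrid Newton root finder (residual
< 1e-10 required) and classified by the dominant eigenvalue of a central
finite-difference Jacobian (step 1e-7).

### The canonical 4-click and its calibration

The shipped assembly has two lineages with two maturation stages each:
cytotoxic Tc maturing into Tnk (cytotoxic cells bearing NK receptors) and
helper Th maturing into regulatory Tr1. The kill cycle is
Tc ⊣ Tnk ⊣ Th ⊣ Tr1 ⊣ Tc, which satisfies the canonical wiring rule:
within a lineage the young stage regulates the older one, across lineages
the older stage regulates the other lineage's young. Bystander help feeds
the two help-sensitive populations, Th and Tc — help that expands the
helper pool also expands the cytotoxic pool, and this double coupling is
what lets the help level steer the outcome between the two regimes.

The default rates (data shipped in `fixtures/fig1_4click.json`, not code)
were chosen by equilibrium-targeted design: pick the desired resting
state, solve the fixed-point conditions for the growth rates, and keep
parameter sets whose resting state is locally stable and shows the full
regime repertoire. Under the defaults:

- **Resting state (h = 0).** All four populations coexist at a stable
  equilibrium (0.042, 0.090, 0.093, 0.888) dominated by Tr1; from the
  default initial condition (0.05 each) the Tr1 trajectory overshoots
  slightly to a maximum of 0.896. The dominant eigenvalue is
  −0.0042 ± 0.065i, so the approach is a slowly damped oscillation;
  the resting preset integrates to t = 2500 so the convergence flag
  clears the 1e-6 derivative threshold.
- **Tnk knockdown.** Starting without Tnk and with the Tc→Tnk maturation
  rate reduced five-fold, the helper lineage escapes NK-receptor control,
  Th pins Tr1 down, and the cytotoxic response takes over (Tc ≈ 1.23).
- **Help switch.** Raising the shared help level h destabilizes the
  suppressive outcome; above h ≈ 4.04 the default initial condition falls
  into the cytotoxic basin. In a window around the boundary the two
  outcomes' basins interleave, twin trajectories diverge exponentially
  (positive largest-Lyapunov estimate ≈ +0.05, against ≈ −0.05 deep in
  either regime), and the transition path in the delay embedding does not
  self-intersect. At h = 3.75, random initial conditions split roughly
  5:1 between the cytotoxic and suppressive basins.

The carrying capacity of the canonical assembly is K = 1.3077 rather
than 1. A stable interior equilibrium with Tr1 near 0.9 *and* minor
populations large enough to stabilize it is not attainable at K = 1 (the
logistic term 1 − Σ P/K becomes too small and the Tc/Tr1 block loses
stability), so the abundance scale is anchored to the resting state:
resting abundances lie on the familiar 0–1 scale, while a maximally
driven response can modestly exceed 1 (up to K). Time units are
arbitrary throughout.

### Attractor classification

`classify_attractor` works on the time-averaged tail (default: last 20%
of samples): *extinct* when every tail mean is below the extinction
threshold (1e-8); *non_stationary* when any population whose tail mean is
non-negligible (≥ 1e-4) has a tail coefficient of variation above 0.1
(populations below the negligible floor are decaying remnants — their
relative fluctuations carry no regime information); *⟨id⟩_dominant* when
the top tail mean is at least twice the runner-up; otherwise
*coexistence*. Because only tail statistics enter, labels are invariant
to uniform time rescaling. The 2× dominance margin and 0.1 CV threshold
are fixed documented constants.

### Lyapunov estimation

The largest-Lyapunov estimate uses twin-trajectory divergence: integrate
the state and a copy displaced by ε = 1e-6 along the normalized all-ones
direction, fit log separation against time by least squares over the
pre-saturation window (separation under 1% of the mean state norm), and
report the slope. The twin runs use tightened tolerances (rtol ≤ 1e-10,
atol ≤ 1e-12) so solver noise stays below the perturbation scale; a
degenerate fit window returns NaN. On a one-dimensional logistic
equation the estimator reproduces the analytic eigenvalue −r to within a
few tenths of a percent, and at the canonical resting equilibrium it
matches the dominant Jacobian eigenvalue (−0.0042) to the printed
precision. The positive estimate in the transition window measures the
exponential separation of nearby states straddling the basin boundary —
the operational signature of the sensitive, history-dependent switch.

### Return maps

`return_map` builds the delay embedding (x_t, x_{t+lag}) per population
(lag defaults to one output-grid step, but is a parameter). The overlap
statistic is the minimum distance between non-adjacent polyline segments,
normalized by the data range; segments shorter than 1e-4 of the range are
stationary (the path is sitting at an equilibrium or saddle plateau) and
are excluded, since they carry no path information. Zero means the path
revisits itself at the sampling resolution; positive means the transition
paths are non-overlapping.

## The lattice backend

The stochastic backend is a toroidal lattice automaton with von Neumann
(4-neighbour) connectivity and random-sequential updates — the standard
setting for cyclic-dominance lattice games. One sweep performs
width × height single-site updates (site chosen uniformly with
replacement): the focal cell picks a uniform neighbour and resolves, in
order, kill (victim empties with the edge's probability; exactly one cell
changes, the killer always survives) else reproduction into an empty
neighbour. After the contact pass, every occupied site independently dies
with its spontaneous-death probability, else matures along its outgoing
maturation edge. Randomness comes from one named generator seeded by
(run seed, sweep index), so runs are bit-reproducible from the initial
lattice alone.

**Rate mapping.** The lattice has unit capacity (occupied fractions sum
to ≤ 1) while an assembly carries capacity K, so the automaton simulates
the K-rescaled system: densities correspond to abundance/K and kill rates
are scaled by K. Event probabilities are rate × Δt with Δt chosen so the
largest probability is 0.5; reproduction of help-sensitive populations is
boosted as min(1, p·(1 + βh)). Occupied fractions multiplied by K are
comparable with ODE abundances.

**Validity of the mean-field comparison.** Lattice dynamics develop pair
correlations (offspring sit next to parents; killing happens at cluster
interfaces), so agreement with the well-mixed ODE is only expected in the
dilute regime. The shipped calibrated default sits at ~90% occupancy with
strong kills, where the lattice genuinely departs from mean field (the
helper population can be driven extinct by interface effects). The
documented consistency parameterization (`wellmixed_4click`, canonical
wiring with moderate rates and ~30% empty space) tracks the ODE
equilibrium to within ~0.05 occupied fraction per population on a
200 × 200 lattice, comfortably inside the 0.1 band the consistency check
uses. Consistency runs use 800 sweeps with the mean taken over the final
100; the lattice is initialized at the ODE equilibrium densities.

## Intransitive dice

The dice module makes the assembly's logic exact: Efron's four dice
({4,4,4,4,0,0}, {3,3,3,3,3,3}, {6,6,2,2,2,2}, {5,5,5,1,1,1}) form a
directed cycle in which each die beats the next with probability exactly
24/36 = 2/3 and no roll draws, yet no die beats all others — choosing
after the opponent guarantees a win, just as the winning immune response
depends on the threat. All probabilities are exact rationals from
enumeration of the 36 ordered face pairs; floating point appears only in
the seeded Monte-Carlo cross-check, which converges at the binomial rate.

## What the simulations do and do not show

The synthetic presets demonstrate that the two click rules plus simple
population dynamics reproduce the claimed repertoire: a stable suppressive
resting state, a knockdown-triggered cytotoxic response, a help-dependent
bistable switch with a sensitive transition, and exact intransitivity at
the game-theoretic core. They are not fits to measured cell counts: the
rates are calibrated constants on an arbitrary time scale, real immune
populations are not well mixed (the lattice backend probes, but does not
remove, that gap), antigen dynamics and cytokine fields are reduced to a
single help parameter, and each lineage is reduced to two discrete
stages. Agreement of the package's presets with the qualitative regimes
says nothing about parameter values in any real tissue.

## Numerical choices and degenerate inputs

- Integration: LSODA (stiff-capable, adaptive); defaults atol 1e-9,
  rtol 1e-7; halving tolerances moves the canonical final state by < 1e-5.
- Non-negativity is enforced by clamping output samples at zero; the
  clamped magnitude is logged (it is at solver-noise scale).
- Extinction threshold 1e-8 for reporting a population lost; negligible
  floor 1e-4 for the stationarity test.
- `find_equilibrium` requires residual < 1e-10 and reports stability from
  the finite-difference Jacobian (central differences, step 1e-7).
- Shortest-cycle ties: lexicographic on the sorted id sequence; the
  all-zero state is an absorbing fixed point of every assembly; an empty
  lattice is a fixed point of the automaton.
- Basin sampling draws initial conditions uniformly from [0, 0.5]^N with
  a recorded seed; fractions over all labels (including solver failures)
  sum to one.
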