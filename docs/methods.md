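# Methods

## Model overview

`signalfate` simulates how two diffusible chemical signals organize a plane
of two competing stem-cell populations (SC1, SC2) into a six-phenotype
tissue pattern, and how much of the driving signal structure can be read
back from the finished pattern.

The pipeline has three stages:

1. **Signal layers.** Each signal is the activator concentration `s_u` of a
   confined activator–inhibitor (Turing) pair, or a static
   positional-information profile (Gaussian bump, sinusoid), or a
   user-supplied matrix. Signals are frozen on the (0, 5) decision scale
   before the population stage (see below).
2. **Intracellular switch.** Every lattice site hosts a stem cell with a
   tri-stable two-determinant switch whose self-activation rates are biased
   by the local signal pair.
3. **Population loop.** Cycles of stochastic switch evolution produce
   *virtual* division outcomes accumulated in per-type 6×6 look-up tables
   over binned (s1, s2); the loop stops when the emergence probabilities
   stabilize and the plane is painted from the tables.

## Reaction–diffusion signals

The confined dynamic per channel is

    ds_u/dt =   lap(s_u) + gamma (A s_u - s_v + C)
    ds_v/dt = d lap(s_v) + gamma (B s_u - s_v - 1),    0 <= s_u <= su_max

with reflective boundaries. Defaults: A = 0.9, B = 1.2, C = 0.2,
gamma = 10^4, lattice spacing h = 0.01, grid 100×100. The homogeneous root
is su* = (C+1)/(B−A) = 4, sv* = B su* − 1 = 3.8; with d = Dv/Du large
enough the root is Turing-unstable and small seeded perturbations (default
1% multiplicative noise) grow into stationary patterns whose *class* is
selected by the activator cap `su_max`.

Both the deterministic integrator and the stochastic lattice work in
activator-scaled units: effective diffusivities (1, d), time in units of
1/Du. Only the ratio d matters for the steady pattern; this keeps the
d = 500 channel integrable with an explicit scheme (time step
0.2 h²/max(1, d), comfortably under both the diffusive CFL bound and the
reaction-stability bound).

**Pattern presets.** The caps are not first-principles quantities; they were
located by a one-dimensional scan over `su_max` at the reaction constants
above (100×100 grid, t = 0.03, several noise seeds):

| preset        | d   | su_max | steady class            |
|---------------|-----|--------|-------------------------|
| spot          | 20  | 30     | isolated high islands   |
| stripe        | 20  | 6      | elongated labyrinth     |
| reverse_spot  | 500 | 5      | low holes in a plateau  |

Low caps clip the activator plateaus into connected sheets with round holes
(reverse spots), intermediate caps leave winding interleaved troughs
(stripes/labyrinths), high caps let the activator concentrate into isolated
peaks (spots). The reverse-spot cap is pinned at 5 so its steady field
spans the (0, 5) decision scale natively.

**Classifier.** A steady field is binarized at its mean and both phases are
analyzed by 4-connected components. The minority phase decides: at least
three compact, non-spanning islands over a connected majority background
are the spot family (high islands → spot, low holes → reverse spot);
elongated (area-weighted PCA axis ratio ≥ 2.1) or spanning minority
structures mean stripe. "none" is returned only for fields with relative
amplitude below 2% of scale — a heterogeneous field always receives one of
the three real classes. The elongation cut sits between the measured
families at 100×100 (reverse-spot holes ≤ 1.8, spot islands ≤ 1.9,
labyrinth troughs ≥ 2.25). On much smaller grids (≲ 64²) the d = 500
channel holds only ~2 wavelengths and its label becomes realization-
dependent; the pattern-family scan therefore runs at 100×100.

## The signal-biased switch

Determinants x, y of the cell at each site obey

    dx/dt = a_x x^n/(b^n + x^n) + k1 b^n/(b^n + y^n) - g1 x
    dy/dt = a_y y^n/(b^n + y^n) + k2 b^n/(b^n + x^n) - g2 y

with n = 4, b = 42, k1 = k2 = 30, g1 = g2 = 0.38, basal a0 = 30. At zero
bias the system is tri-stable: differentiated states (157.5, 0.4) /
(0.4, 157.5) and the stem state on the diagonal at a0/g1 ≈ 78.95 (closed
form because a0 = k).

Signals enter through the transfer functions
`eta(s) = G s²/(K² + s²)` (increasing) and `zeta(s) = G K²/(K² + s²)`
(decreasing), K = 2.5, gain G = 20:

    lineage 1:  a_x = a0 + eta(s1) eta(s2),   a_y = a0 + zeta(s1) zeta(s2)
    lineage 2:  a_x = a0 + eta(s2) zeta(s1),  a_y = a0 + eta(s1) zeta(s2)

**Gain placement.** The gain multiplies each eta·zeta *product* once, so
the bias tops out at +20 over the basal 30. The alternative (gain on each
factor, products up to 400) maximizes the corner biases but destroys the
cruciform structure of the fate plane: it drives SC1 toward its high-y fate
at (0, 5)/(5, 0), where the model requires SC1 to stay neutral while SC2 is
being driven. Under product placement all four extreme pairs resolve
correctly — (5,5) → A, (0,0) → B, (0,5) → C, (5,0) → D — with the
off-lineage left close to neutral, and the pattern→signal round trip is
exact on differentiated pixels. Per-function placement remains available
via `SwitchParams(scaling="per_function")`.

**Fate reading.** A settled determinant pair is classified by relative
asymmetry: |x − y| ≤ 0.2·max(x, y) is self-renewal, otherwise the larger
determinant names the offspring (lineage 1: x → A, y → B; lineage 2:
x → C, y → D). The 0.2 band was chosen between the settled diagonal states
(asymmetry 0) and the weakest biased endpoints (asymmetry ≥ 0.35 at the
extreme signal pairs). Codes/colors are fixed: 1 SC1 magenta, 2 A blue,
3 B cyan, 4 SC2 green, 5 C yellow, 6 D red.

## Stochastic kinetics

The 20-reaction system (4 kinetic + 2 diffusion channels per signal, 4
reactions per cell) runs under an exact direct-method SSA or tau-leaping
with a bounded relative-propensity-change criterion (epsilon = 0.03;
rejected or too-small leaps fall back to exact steps). Copy numbers use two
system-size factors: `omega` (signals; default 100 copies per concentration
unit) and `omega_det` (determinants; default 1, since the determinant
equations are already posed on O(100) molecule numbers). The activator
production propensity is nullified at the cap `round(su_max·omega)`, and
removal propensities are nullified at zero copies — the stochastic
counterpart of the confinement clamp.

The population loop uses dedicated fixed-step tau-leap kernels
(dt = 0.05 for determinants) and a per-site RK4 descent (dt = 0.1,
horizon 40, early exit) for the virtual-fate assessment; both are compiled
with numba.

## Population algorithm

Grid default 100×100 (50×50 for the desk-scale reproducibility runs), SC1
fraction 0.5, Bernoulli-seeded. One cell cycle = 100 steps of dt = 0.12
time units, calibrated so a cycle (~12 units, several times 1/g1 ≈ 2.6)
lets the switch travel from the stem state into an attractor basin at
extreme signals. Each cycle the determinants are reset to the stem state
(the resident stem cell persists; only its virtual outcome is recorded),
evolved stochastically, and classified by deterministic descent of the
endpoint. Outcomes increment `table[fate][bin(s1), bin(s2)]` with six equal
bins on (0, 5) (`floor(6 s/5)`, top edge clamped).

**Convergence.** Every 1000 steps (10 cycles) the per-site emergence
probabilities are evaluated as cumulative counts divided by the total
number of recorded events (population × recorded cycles — the only
normalization under which the cumulative estimate converges); the loop
stops when the maximum absolute change drops below epsilon = 0.0025,
starting from pb = 0 so the first evaluation already produces a difference.
A configurable cycle cap (default 20 000) raises a non-convergence error
with the difference trace.

**Signal freezing vs co-evolution.** Signals are frozen at their scaled
steady state by default. The signal relaxation time (~10⁻² activator-time
units) is about three orders of magnitude shorter than one switch cycle
(~10¹), so a co-evolving signal field is at steady state for all but a
vanishing fraction of the first cycle; freezing changes nothing
statistically and removes the dominant cost. `signal_mode="coevolve"`
advances the stochastic signal lattice by a configurable time slice each
cycle for users who want the full coupled system.

**Painting.** Default: each site receives the argmax over the per-bin
normalized probabilities *within its resident lineage's triple* (ties
broken uniformly at random under the master seed; unpopulated bins fall
back to the nearest populated bin by Manhattan distance). A `sample` mode
draws from the distribution instead. For reference-pattern comparisons the
scope is widened to all six types and restricted to differentiated fates
(`paint_scope="population"`, `offspring_only=True`): the half-max reference
is a pure signal→fate map with no lineage placement, so lineage-scoped
painting pins roughly half of all pixels to the "wrong" lineage and caps
the resemblance score near 0.5 regardless of how reproducible the pattern
is. The population-scoped protocol is the reading under which replicate
scores measure pattern reproducibility; `score_replicates` uses it.

## Reproducibility scoring

The reference pattern thresholds each signal at half its scale maximum
(2.5 on the (0, 5) scale) and maps the four extreme pairs to fates
((hi,hi) → A, (lo,lo) → B, (lo,hi) → C, (hi,lo) → D). The resemblance
score of a realization is the fraction of pixels with identical codes;
`score_replicates` runs the population loop with seeds derived from one
master seed and reports the score distribution. At 50×50 with frozen
reverse-spot signals the replicate medians are ≈ 0.95–0.98; stripe and
spot pairs behave similarly.

## Inverse route

Reconstruction is the fixed pixel map A → (1,1), B → (0,0), C → (0,1),
D → (1,0), stem → (0.5, 0.5); 0.5-valued pixels are treated as missing by
the plane classifier (an error is raised when > 90% of pixels are
indeterminate). Class-level recovery of the driving signals is only claimed
when the signals come from the known confined-Turing family.

## What the synthetic data does and does not cover

The analytic fixtures (bump lattices, sine bands, random code grids)
satisfy the classifier's defining geometry exactly and exercise every
stage without PDE/SSA cost; they do not reproduce the amplitude statistics,
boundary effects or coarsening history of real confined-Turing fields, so
classifier margins measured on fixtures say nothing about marginal
realizations — those are covered by the seeded PDE scans. All stochastic
tests pin seeds; Monte-Carlo assertions use 3-sigma bands plus a small
absolute floor. No stage models cell movement, death, mechanics, or
spatiotemporal (wave) signals.

## Numerical choices

- Explicit Euler for the PDE with dt = min(0.8·0.25 h²/max(1,d),
  0.5/(gamma(1+A+B))); a user-supplied dt above the diffusive bound raises
  a CFL error.
- Attractor finding: residual-norm local minima on a 60×60 grid over
  [0, (alpha+k)/gamma]², refined by Newton (hybrid), deduplicated,
  stability by Jacobian eigenvalues.
- Determinism: every source of randomness derives from one master seed via
  `numpy.random.SeedSequence` spawning; equal configs and seeds give
  byte-identical outputs.
- Degenerate inputs: B = A raises a degenerate-kinetics error; constant
  fields normalize to the scale midpoint; zero-length cycles leave states
  unchanged; code values outside 1–6 are rejected at the I/O boundary.
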