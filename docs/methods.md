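# Methods

## Model summary

Two species of soft-disk agents move in a square periodic domain of side L
under underdamped dynamics integrated with velocity-Verlet. Prey combine
contact separation, quadratic medium drag, and — while alive — two-state
self-propulsion, a force-based velocity-alignment rule, and long-range
cohesion. Predators combine contact separation, drag, and a three-state
propulsion tied to a hunting cycle (search → select → pursue → satisfied /
refocus). Captures flip the target's alive flag μ to 0; captured prey are
never removed or replaced, and they keep exerting contact forces.

The simulation is natively non-dimensional: d_pr = 1 is the length unit and
t0 = sqrt(d_pr/β_pr,e) = 1 the time unit, so the speed unit is
v0 = sqrt(d_pr·β_pr,e) = 1. The coordination strength
χ = (C_v d_pr/m_pr)·sqrt(d_pr/β_pr,e) is controlled by solving C_v from a
requested χ.

## Default parameters

The defaults are a calibrated, documented stand-in set: the sources fix the
anchors (N = 506 prey, two predators, predator mass 16× prey, r_sep = d_pr,
r_atr = r_d for prey, χ ∈ {17, 31}, predators faster than prey) but not the
remaining values, which were chosen once so that the qualitative regimes of
the study — cohesive escape at small attack angle, near-equal split at
antipodal attack, non-additive predation — reproduce. All lengths in d_pr,
times in t0.

| symbol | value | meaning |
|---|---|---|
| m_pr, d_pr | 1, 1 | prey mass and diameter (units) |
| β_pr,c, β_pr,e | 0.25, 1 | cruising / escape acceleration |
| γ | 0.05 | Rayleigh cap inside the propulsion term |
| ρ c_f A | 1.9 | quadratic drag prefactor ×2 (prey) |
| k_n | 60 | contact stiffness |
| σ_ζ | 0.15 | orientational noise std (rad per step at dt = 0.025) |
| υ_a | 0.003 | attraction strength per neighbour |
| m_fluid | 1 | entrained fluid mass in the alignment shell |
| w_rms | 1 | RMS width of the Gaussian alignment weight |
| r_sep, r_alg, r_atr = r_d | 1, 3.5, 15 | prey zone radii |
| θ_b | π/3 | total rear blind-angle width (both species) |
| m_pd, d_pd | 16, 2 | predator mass and diameter |
| β_pd,h, β_pd,sr | 0.175, 0.11 | pursuit / cruise acceleration |
| R_c, R_d | 1.4, 20 | capture / detection radius |
| τ_P, τ_S, τ_R | 20, 15, 10 | pursuit / satisfied / refocus durations |
| L, dt | 200, 0.025 | domain side, timestep |

Resulting terminal speeds (root of m(β − γv²) = ½ρc_f A v², checked at
config build): prey cruise 0.5, prey escape 1.0, predator pursuit 1.02,
predator cruise 0.81. The predator outruns a lone escaping prey by only
~2 %: a tail chase of a free-running prey essentially never closes within
the pursuit budget τ_P. Aligned groups, however, travel slower than lone
prey because the alignment force matches speed as well as heading (an
escaping group at χ = 17 moves at ≈ 0.85, at χ = 31 slower still), so
predators gain on *groups*, plough into them, and capture targets that are
hemmed in by their own school — and captures get easier as χ grows, which
is how the counter-intuitive cost of excess coordination emerges.

The capture radius sits slightly inside the contact distance
(R_c = 1.4 < (d_pr + d_pd)/2 = 1.5), so a fleeing target riding the
predator's contact "bow wave" is not captured; capture requires the target
to be pressed into the capture zone against the crowd or met with momentum.
This keeps first pursuits long: the predator ploughs through the school for
most of τ_P, and the radial escape fan of prey around each predator drives
the hourglass constriction and the split at large attack angles. If
captures come instantly (faster predator, touch-radius capture), attack
pressure is brief and the split regime disappears — that coupling, not any
single magic constant, ties β_pd,h, R_c, k_n and τ_P together. τ_S/τ_R sit
below "a few tens of t0" so repeated attacks in the long-term study resume
while the group is still deformed.

## Numerical scheme and stability

Velocity-Verlet with one force evaluation per step: positions advance with
cached accelerations; forces are recomputed at the new positions with
half-kick velocities; velocities complete with the mean acceleration. For
the velocity-dependent propulsion/drag terms this is formally first order in
the velocity arguments while retaining the second-order position update.
Behavioural state (cruise/escape, the predator cycle, captures) updates
synchronously once per step after the kinematic update.

A structural constraint surfaced during development: the propulsion form
m(β − γ‖v‖²)x̂ points along the *drive direction* x̂, not along −v. When an
agent overshoots — moving away from its drive direction faster than terminal
speed — the Rayleigh term feeds energy *in* rather than dissipating it, and
the dynamics run away unless the true medium drag dominates: γ·m < ½ρc_f A
per species. Configuration building enforces this inequality; the defaults
satisfy it with a wide margin for prey (0.05 vs 0.95) and a comfortable one
for predators (0.8 vs 1.9).

Orientational noise ζ is drawn independently per prey per step and rotates
the alignment force direction, preserving magnitude. σ_ζ is defined per
step at the default dt (no √dt scaling): the noise enters through a force
direction, not as an additive Wiener term, so diffusion-scaling is not
implied by the model statement.

Two force backends exist: a readable NumPy reference
(`preyflock.forces` / `preyflock.predator`) and a numba kernel
(`preyflock._kernels`) with identical math; tests hold them to 1e-8
agreement on random configurations, and an exact-pair-set test covers the
cell-list vs brute-force neighbour search. Runs are bit-reproducible for a
fixed seed and backend.

## Semantics decided where the model statement was open

- **Blind angle scope.** The rear blind cone (total width θ_b, centred on
  −heading) gates predator detection by prey, prey detection by predators,
  and the social alignment/attraction shells. It never gates contact
  separation: a vision-gated contact force would break Newton's-third-law
  antisymmetry and allow interpenetration from behind. A switch
  (`blind_angle_social=False`) restricts the cone to detection only.
- **Cone boundary.** An agent exactly on the cone edge counts as visible
  (blindness is strict inequality).
- **Escape with several detected predators.** Flee the *nearest* detected
  predator (`escape_from_nearest=True`); the averaged-repulsion alternative
  is available as a switch.
- **No-neighbour alignment limit.** With an empty alignment shell,
  φ·v_surr ≡ 0 and the force reduces to −C_v d_pr v — an implicit social
  drag that heavily damps isolated live prey. This is retained deliberately
  (continuity of the force law as Σm_j → 0) and is why stragglers slow
  down; tests for the closed-form terminal speed disable it via C_v → 0.
- **Attraction direction.** The printed magnitude is applied along the unit
  vector toward each live neighbour in the attraction shell, summed.
- **Capture semantics.** Only the *current target* is captured on entering
  R_c; bystanders inside R_c are unaffected (`opportunistic_capture`
  switch available, default off).
- **Target captured by the other predator mid-pursuit.** The pursuit closes
  immediately as a failure with reason `target_lost`; no mid-cycle
  re-selection.
- **MCP centroid on the torus.** Computed from minimum-image displacements
  relative to the predator (well defined because R_d < L/2, enforced at
  config time); ties broken by lowest prey id for both NP and MCP.
- **Coincident agents.** Exactly overlapping agents repel along a
  deterministic pseudo-random axis hashed from the ordered id pair, keeping
  the interaction antisymmetric and runs reproducible.
- **Zero-velocity heading.** Agents retain their last non-zero heading; at
  t = 0 the initialised heading.
- **Predator search stage.** Between cycles the predator cruises along its
  heading at β_pd,sr while scanning; detection is re-attempted every step.

## Analysis conventions

- DBSCAN uses eps = r_alg and min_pts = 1 % of the initial N (floored: 5
  for N = 506; a point's neighbourhood includes itself, matching
  scikit-learn's `min_samples`). Clusters grow from core points in
  ascending id order, so border-point assignment is deterministic. l_c and
  φ normalise by the *initial* N; only live prey are clustered.
- Ψ_L averages the pairwise heading cosine over live prey pairs within
  r_alg (no blind-angle gating; undefined → NaN when no pair exists).
- α_K takes consecutive-pair slopes of N_l (positive = decay) smoothed by a
  centred moving mean (default window 5 samples; truncated at the edges).
- A pursuit event records the target's cluster-size fraction φ at selection
  time; a noise-point target is booked at the minimum φ = 1/N (isolated
  prey).
- κ(N_d) interpolates first-passage times linearly in τ between bracketing
  samples and ratios the realisation means (single predator over duo).

## Experiment protocol

Each realisation builds a jittered triangular-lattice disc of N prey with a
common random heading at cruise speed, relaxes it for 10 t0 without
predators, then places the predators on a circle of radius 1.1·r_d about
the live-prey centroid at relative angle Ω_P with a uniformly random
bisector, aimed at the centroid. A single-attack run ends once every
predator has closed its first hunting cycle and a further 50 t0 settling
window has elapsed (so split fragments separate beyond r_atr), or at a
120 t0 horizon; clustering is evaluated at the end time. Per-realisation
seeds derive from the master seed via `SeedSequence([seed, study, index])`.

Problem sizes used by the shipped acceptance run and test suite: 28
realisations for the antipodal-attack ensemble and 20 for the low-angle
one (3 at the mid angle, 2 at χ = 31), two realisations for the long-term
(250 t0) and predator-count (700 t0, N_d ≤ 0.006) comparisons, and one or
two 70-t0 runs for the sustained-pursuit order measurement. These are the package's default
desk-scale ensembles; the experiment runners accept larger
`n_realisations`/`T_max` for production-scale studies (the study design
calls for ≥ 50 realisations per condition).

## What the simulations do and do not show

The generator emulates a single idealised school attacked in open, obstacle-
free, homogeneous water with purely visual, occlusion-free perception.
Passing tests demonstrate internal consistency of the force laws, the
state machine and the metrics, and reproduction of the qualitative regime
map under the calibrated defaults — not quantitative agreement with any
real species: the true parameter table of the original study is not
available, so printed magnitudes (capture-success percentages, absolute
capture rates) should be compared at the level of orderings and regime
boundaries, not decimals.

Known limitations: no visual occlusion, no protean evasion, no environmental
heterogeneity, at most two predators, fixed-duration satiation/refocus, and
a first-order treatment of velocity-dependent forces inside the Verlet
scheme. The alignment rule matches velocity magnitude as well as direction,
which suppresses flash-expansion-like responses at high χ. Under the
calibrated stand-in parameters the antipodal split at χ = 31 occurs in
only about half of the realisations (at χ = 17 it is essentially certain),
so the high-coordination end of the regime map is reproduced only in trend
(the mean largest-group fraction still decreases with the attack angle).
Because captures rely on crowding rather than open-water pursuit, the
protective value of dispersal is understated relative to the source
system's behaviour; one consequence is that the predation non-additivity
κ(N_d) is clearly above 2 only while live prey are abundant (N_d ≲ 0.01
at the shipped ensembles) and relaxes towards — sometimes below — 2 as
the captured fraction grows, instead of staying above 2 throughout.
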