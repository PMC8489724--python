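# Methods

This note documents the models implemented in `consortia`, the default
parameters and why they take the values they do, the numerical choices, and
what the simulations do and do not capture.

## Agent-based model

**Cells.** 2D spherocylinders of constant width w = 1 µm; the state of a cell
is its center, axis angle φ ∈ [0, π) from horizontal (orientations are
nematic: φ and φ + π are identical), pole-to-pole length l, birth length l₀,
strain id, intracellular species concentrations, and the most recent axial
load. Lengths grow exponentially, `l ← l·2^(dt/T_d)` with doubling time
T_d = 20 min for both strains, so total population "volume" (area) grows at a
rate independent of mean cell length.

**Division.** A cell divides when l reaches its target
`l_d = √(2 l₀)·√(l̄_d_eff)`. The two daughters occupy the mother's footprint
end-to-end with birth lengths ε₀l and (1−ε₀)l, ε₀ ~ U[0.45, 0.55] drawn
independently at each division; this staggers division times across the
population. Each daughter's angle receives independent Gaussian jitter
(σ = 0.02 rad) to break the perfect-alignment symmetry of an isolated
lineage; the value is small enough not to contribute measurable disorder in a
packed trap. Intracellular concentrations are inherited unchanged, which is
identical to splitting molecular amounts in proportion to birth length.
`l̄_d_eff` is the strain's mean division length l̄_d, multiplied by the
reduction factor a while the cell is in the reduced state (scheduled
induction, or the quorum-sensing threshold controller). Division targets are
always recomputed from the stored l₀, so a newly induced reduction takes
effect at the next division check even for cells born before it.

**Mechanics.** Contacts are detected between axis segments: two cells
interact when the minimum distance between their segments falls below w. The
contact force is linear (Hookean) in the overlap depth, `F = k·(w − d)`,
directed along the line of closest approach and applied at the contact point,
so it exerts both force and torque. Positions and angles follow overdamped
first-order updates with translational drag ζ·l and rotational drag
ζ_rot·l³/12, iterated quasi-statically after each growth increment until the
largest residual overlap is below 0.05 µm or an iteration cap of 120 is hit
(the step is flagged, not fatal). An adaptive pseudo-time step caps the
largest per-iteration displacement at 0.05 µm for stability. Defaults:
k = 40 (force per µm of overlap), ζ = 1, ζ_rot = 3. The rotational drag and
the iteration cap were set by requiring that a single-strain population at
l̄_d = 4.2 µm holds stable columnar order (time-averaged bulk q ≈ 0.96–0.98);
with faster rotational response or an under-converged relaxation the bulk
shows intermittent disorder bursts not seen at this division length in the
reference phenomenology. This contact scheme is a deliberately simple
stand-in for a full rigid-body mechanical integrator; it reproduces the
emergent behaviors of interest (columnar alignment, its loss at small l̄_d,
invasion, bulk forcing) but individual trajectories are not quantitatively
comparable to any particular mechanical code.

**Axial load (growth-expansion force proxy).** After relaxation, each cell's
`F_axial` is the sum over its contacts of the inward-pointing axial component
of the contact force, halved (average of the two poles) and divided by the
cell length. The per-length normalization makes it a compressive axial
*stress* proxy: raw pole loads scale with how much column a cell spans, which
would make a shortened strain's kymograph signal drop for purely geometric
reasons and mask its elevated lateral pushing.

**Trap.** An open rectangle (reference geometry 100 × 20 µm; reduced widths
of 40–60 µm are used for study-size reasons, stated below). Cells whose
centers leave the rectangle are removed each step — the cheap, monotone
center-out rule; protruding bodies relax naturally. The update cycle per step
dt is: grow → divide → relax mechanics → remove exited → signaling. The
mechanics step dt defaults to 0.02 min; the simulations in the test suite use
dt = 0.05 min, at which growth per step (≈ 0.005 µm) is still far below the
relaxation tolerance, and results are indistinguishable at halved steps.

**Seeding.** "random-mixed": n cells (default 64 for two-strain, 32 for
single-strain studies) at uniform non-overlapping positions with random
angles and fair-coin strain labels; "separated": blue in the left half,
orange in the right; "single": one strain. Initial lengths are uniform on
[0.5, 0.9]·l̄_d to stagger first divisions.

## Stochastic lattice model

Cells occupy all M×N sites (default 20 × 100, rows × columns; row 1 is the
bottom); each carries a strain id and an orientation V/H. A vertical cell in
row i divides up/down at rates `v±`, a horizontal cell in column j left/right
at `h±`:

    v⁺(i) = λ e^(−κ(M−i))   v⁻(i) = λ e^(−κ(i−1))
    h⁺(j) = λ e^(−κ(N−j))   h⁻(j) = λ e^(−κ(j−1))

so division is fastest toward the nearest open boundary and κ sets how
strongly the intervening population damps growth. On division the in-place
daughter keeps the mother's site and orientation; the displacing daughter
takes the adjacent site in the growth direction, shifting the half-row/column
one site outward; the cell pushed past the boundary is removed, keeping the
lattice full. The displacing daughter flips orientation with the arithmetic
mean of the intrinsic rotation probabilities of the mother and her existing
Moore neighbors (≤ 8; boundary neighborhoods average over existing cells
only), which couples a cell's rotational freedom to the morphology of its
neighbors. Events are drawn exactly (Gillespie); both a readable
per-operation reference implementation and a compiled event loop are
provided and cross-checked statistically.

**Time unit and damping.** λ = 20 and κ = 0.035 by default. The unit of time
is chosen so that the standard band-forming transient [0, 1] spans roughly
two dozen generations: single-strain vertical bands must be in place when
rotation probabilities are switched at t = 1, because bands make vertical
divisions strain-neutral; with only ~1 generation of transient the rotating
strain *loses* (its rotated cells are a reproductive dead weight in mixed
columns). κ trades off the two displacement mechanisms: interior horizontal
division rates scale as e^(−κN/2), so large κ (≳ 0.1 on N = 100) freezes
both invasion and forcing entirely, while very small κ (≲ 0.02) makes
horizontal churn so strong that single-interface forcing saturates within
the fit window and its rate dependence on p_rot degrades. κ = 0.035 keeps
the banded invasion fit acceptable and the forcing-rate dependence on p_rot
monotone and approximately linear.

**Known limitation.** At the strongest rotation asymmetry studied
(p_rot,o = 0.5 vs p_rot,b = 0), 10–15% of banded replicates end with the
*rotating* strain extinct: its own columns destabilize and its horizontal
churn ejects its own cells through the side boundaries. This caps the
ensemble-mean mutant fraction near 0.85 rather than 1 and makes the fitted
invasion rate α(p_rot) peak near p_rot ≈ 0.2–0.3 instead of increasing up to
0.5. The effect is robust across the κ and λ ranges explored (κ 0.01–0.25,
λ 10–30, 40–100 replicates).

## Quorum-sensing circuit and the consortial oscillator

Each strain constitutively produces one orthogonal signal (blue → C4HSL,
orange → C14HSL) unless repressed by its own LacI. Per cell and molecule m:

    dH_m/dt   = α_m·[m is own]·1/(1 + (LacI/K_L)^{m_L}) + d_m (H_trap,m − H_m)
    dLacI/dt  = β · H_opp^{m_H} / (K_H^{m_H} + H_opp^{m_H}) − δ_L · LacI

The external pools are well-mixed: the trap compartment integrates the
length-weighted membrane flux from all cells and exchanges with a flow
channel (volume ratio 2) that is diluted by media flow at rate γ. With γ = 0
and no production the three-pool mass balance is conserved exactly up to
integrator error. All kinetics use forward Euler at the mechanics step;
halving the step changes trajectories by < 2% (step-doubling test).

A cell is in the reduced-division-length state exactly while its intracellular
opposite-strain signal exceeds H_T (strict inequality, no cell-level
hysteresis — the circuit-level latch provides the memory).

**Defaults and how they were set** (rates per minute, concentrations in units
where a fully producing half-trap population sustains an external signal of
order 1): α = 1 for both molecules; membrane exchange d_C4 = 2 > d_C14 = 1
(the smaller molecule equilibrates faster — the deliberate source of cycle
asymmetry); γ = 0.5; trap–channel exchange 1; K_L = 0.2, m_L = 4; β = 0.3,
K_H = 0.8, m_H = 8; δ_L = 0.15; H_T = 0.45. The structure of these choices
matters more than the numbers: (i) the mutual-repression latch must be
steep (m_H ≈ 8) so one strain's LacI saturates while the other's stays at
zero; (ii) K_H must correspond to the external signal produced when the
opponent still holds ≈ 35–40% of the trap, so the latch releases while the
losing strain can still recover; (iii) H_T must sit well *below* K_H — if
the reduction threshold is near the latched signal level the system stalls
just under threshold with neither strain shortened (a stable stalemate we
observed directly), whereas a low-but-not-too-low H_T keeps reduction
robustly ON during a latched phase and engages quickly on the other strain
after release. With H_T far below any achievable signal both strains lock
into the reduced state and one is eventually ejected — the extinction
failure mode. Oscillator runs use a 60 × 20 µm trap: on narrower traps the
post-release minority occupies too thin a band and leaks out of the open
boundary before recovering.

## Reduced relaxation oscillator

State: interface position x ∈ [0, 1] (blue fills the trap at x = 1) and
division-length memory Q ∈ [0, 1] (Q = 1: blue reduced). Dynamics

    ẋ = Qx − (1−Q)(1−x)
    εQ̇ = −Q·L₁(x) + (1−Q)·L₂(x),   L₁ = 1/(1+((1−x)/(1−K₂))ⁿ),
                                     L₂ = 1/(1+(x/K₁)ⁿ)

with defaults K₁ = 0.2, K₂ = 0.8, n = 8, ε = 10⁻². x is projected onto
[0, 1] during integration (the front cannot leave the trap); without the
projection, swapped thresholds K₁ > K₂ send x to −∞ instead of converging.
ε must remain large relative to the Hill tails: in the mid-band both
switches leak at rate ≈ (K-ratio)ⁿ/ε, so at n = 8 an ε of 10⁻³ erases the
memory band entirely — the default pairs ε = 10⁻² with n = 8, and sharper
switches admit proportionally smaller ε. Integration uses LSODA with tight
tolerances; the period is measured from upward crossings of Q = 1/2
(symmetric and parameter-free), and converges to the closed form
`ln(K₂/K₁) + ln((1−K₁)/(1−K₂))` only when n grows faster than ln(1/ε)
(otherwise the switches fire early and the period undershoots).

## Analysis definitions

- Order parameter `q = √(⟨cos 2φ⟩² + ⟨sin 2φ⟩²)`; on the lattice's binary
  orientations this is identically |2f_H − 1|.
- Regions: edge = outer 15% full-height strips, bulk = central 40% strip,
  scaled to the trap width (the reference 100 µm trap gives 15 µm edges and
  a 40 µm bulk).
- Kymographs bin cells into 1 µm columns by center coordinate. The
  horizontal force statistic is `F_x = (1/n) Σ F_k |cos φ_k|`: with nematic
  angles a signed cosine is ill-defined (φ and φ+π are the same state but
  flip its sign), and the unsigned projection is the quantity that rises
  where order drops.
- Displacement-rate fits: invasion mode fits `1 − 0.5e^(−α(t−t₀))` from t₀
  until the mean fraction first reaches 0.95 (or the end of the series);
  forcing mode fits `0.5e^(α(t−t₀))` on the fixed window [t₀, t₀+1] in
  lattice time units (one unit ≈ the induction-to-ejection timescale) or the
  corresponding window in minutes for the agent-based model. The initial
  rate for the nonlinear solver is obtained by inverting the model at the
  window end, so fits are timescale-independent.

## Study sizes used in the test suite and acceptance script

Chosen as the package's standard reduced-scale study conditions: lattice
experiments run the full 20 × 100 lattice with 100 replicates for headline
fits and 30 per sweep point; agent-based ordering and competition use a
50 × 20 µm trap (32–64 seed cells, horizons of 300–480 min, dt = 0.05 min);
the oscillator circuit runs a 60 × 20 µm trap for 2 400 min. The
acceptance script's bulk-order target averages post-stabilization samples
(t ≥ 300 min of a 420 min run).

## What the synthetic conditions do not capture

No 3D or multilayer growth, no cell–matrix adhesion, no directional channel
flow or spatially resolved external signal gradients (signals are well-mixed
across the trap, as appropriate for fast-diffusing HSLs at this scale), at
most two strains, and a simplified contact law. Passing tests demonstrate
the emergent mechanisms under these idealizations, not quantitative
agreement with any wet-lab trap.
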