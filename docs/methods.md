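# Methods

## Model structure

All well-mixed models share one state layout
`[B, n, R, P, I_R(1..N), I_P(1..N), L(1..N)]` (concentrations per mL) and
one right-hand side; `M0` and `M1` are exact restrictions of the
competition system `MC1` with the unused strain's compartments identically
zero, and the implementation exploits this: a single derivative routine
serves all three, with the LIN trigger pressure (R + P, or P only) the only
branch. The reaction terms are

- division `g(n)·B` with Monod growth `g(n) = g_max·n/(K_n + n)`, and
  nutrient consumption `−g(n)·B` (one nutrient unit builds one cell);
- infection `η·Φ·B`, with every adsorption to any intact cell removing the
  free phage (`−η·Φ·B_tot` per strain), so phage landing on
  already-infected or lysis-inhibited cells are simply inactivated;
- Erlang latency: N sequential substates at per-substate rate `N/τ(n)`;
  the final substate lyses at that rate releasing `β(n)` phage;
- lysis inhibition: a secondary adsorption onto a cell first infected by
  the LIN phage moves it (from any substate) to the first stage of a
  parallel chain with per-substate rate `N/(f_τ·τ(n))` and burst
  `f_β·β(n)`.

### Latency bookkeeping

The canonical latency parameter is the **total** minimum latent period
τ₀ = 20 min; per-substate quantities are always derived as total/N. The
lysis-inhibited chain advances at `N/(f_τ·τ(n))` per substate so that its
mean total latency is exactly `f_τ·τ(n)` — the stretched chain keeps the
Erlang shape (relative SD 1/√N) and, at f_τ = 5, cells infected around 2 h
lyse around 4 h, matching the batch trajectories. All latency dependence
is computed in *rate* form, so the starvation limit with r_l = 0 gives a
rate of exactly zero (arrest) rather than a divergent time.

## Default parameters

Batch (per mL): g_max = 0.034/min (20-min doubling), K_n = n₀/5,
η = 5×10⁻¹⁰ mL/min, τ₀ = 20 min, β₀ = 150, r_l = 0.5, r_b = 0.1, N = 10,
B₀ = 10⁶, phage 10³ (in `MC1` each strain starts at 10³ — the split is a
package choice consistent with both strains entering at the same level),
n₀ = 10⁹. "20 hours" is taken as exactly 1200 min.

Plaque (per µm²): Δa = 500 µm, D_p = 240 µm²/min, D_n = 5×10⁴ µm²/min,
k_n = n₀/5 = 0.1, B₀ = 1/400, n₀ = 0.5, r_l = 0. The adsorption constant
converts to area units as η/Δa = (5×10⁻¹⁰ mL/min × 10¹² µm³/mL)/500 µm
= 1 µm²/min.

f_τ and f_β are controlled independently (each ≥ 1) even though they
correlate in real phages, so the two effects of LIN — delayed lysis and
amplified burst — can be attributed separately.

## Spatial discretisation and integration

The radial domain [0, R_max] is split into M = R_max/dr annuli with cell
centres at (j + ½)dr; defaults dr = 20 µm, R_max = 10 000 µm (500 cells),
t_end = 400 min. dr = 20 µm resolves the phage diffusion length
√(4 D_p τ₀/N) ≈ 60 µm and R_max comfortably contains the arrested plaque
(final r_half ≈ 1.2 mm); both are configurable, and a grid-refinement test
checks that halving dr moves r_half by < 2%. Diffusion uses a conservative
finite-volume operator (face fluxes −D·2πr·∂f/∂r, zero flux at the origin
by symmetry and at R_max as a reflecting wall), which conserves the
area-weighted total exactly and avoids the 1/r singularity. The seed is
one infected cell in the innermost annulus (density 1/A₀) — a discrete
Dirac delta; stochastic nucleation is out of scope, the model being
deterministic.

After spatial discretisation the system is integrated with LSODA
(stiff-capable, adaptive). Ordering the state cell-by-cell makes the
Jacobian banded with bandwidth equal to the number of fields per cell
(13 for MP0, 23 for MP1), which the banded solver exploits; a full default
run takes a few seconds. Batch models use LSODA with rtol 10⁻⁸,
atol 10⁻⁶ mL⁻¹; plaque models rtol 10⁻⁶, atol 10⁻¹² µm⁻². Reaction rates
are evaluated on the nonnegative part of the state (the solver may probe
slightly negative values near extinction); sampled outputs clip residual
negatives within tolerance to zero and integration aborts if any component
falls below the tolerance band. β(n) in the spatial model is evaluated at
the local nutrient level at lysis time (the literal reading of the flux
terms), not at the level when the cell was infected.

## Front metrics

Four radii are extracted per snapshot: r_PB0 (outermost radius with free
phage equal to the initial lawn density B₀ — one phage per microcolony),
r_super (outermost radius with phage equal to total intact cells; inside
it secondary adsorption dominates), r_half (outermost radius where the
total-cell density drops to half its value in the outermost grid cell —
the visible plaque), and r_ZOI (same for uninfected cells only — the zone
of infection). Crossings are found by scanning from the outer boundary
inward and linearly interpolating the first bracket, which is robust to
the double-peaked phage profiles the LIN model produces; using the
same-snapshot outer edge as the half-reference automatically tracks lawn
growth. A metric with no crossing is reported as absent (distinct from 0)
and excluded from ratio computations. The 50% visibility threshold is a
convention — a plaque may need a deeper drop to look clear — and is
exposed as the `half_fraction` knob.

## Stochastic oracle

The event-driven counterpart simulates the identical reaction network at
integer copy numbers in a volume V (propensities use η/V; nutrient is an
integer pool of cell-equivalents so that B + n conservation is exact
without phage). Burst sizes are stochastically rounded
(floor + Bernoulli on the fraction) so the mean burst equals the
real-valued ODE burst exactly. Validation runs use reduced copy numbers
(10²–10³ per species, V = 10⁻⁶ mL) where an exact SSA is cheap; the
reaction structure is volume-independent, so agreement of replicate means
with the ODE at matched concentrations (within 3 Monte-Carlo standard
errors, with a one-molecule floor on the error scale) validates the same
propensities that act at bench-scale concentrations. Mean-field ODEs and
jump-process means differ by terms of order one over the copy number, so
very small systems would fail this comparison for the right reasons;
the chosen scale keeps that bias well inside the Monte-Carlo error.

## What the tests do and do not show

The test suite checks the implementation against constructed ground truth
(step profiles with known crossings, the 2-D heat kernel for diffusion,
Erlang closed forms for latency, mass balances for burst accounting) and
checks the scientific claims at the default conditions: the r-mutant's
free phage declining ~43% from its peak in competition, free phage
overtaking hosts around 2.2 h, plaque expansion arresting by ~230–300 min,
and the plaque-ratio plateau (r_half ≈ 85%, r_ZOI ≈ 97%) for f_τ ≥ 3.
These are properties of the deterministic models at the stated parameters.
Real plaques add microcolony structure, stochastic nucleation at low phage
density, adsorption-number-dependent LIN delays and LIN collapse, none of
which are modelled; absolute radii also depend on the (unreported,
configurable) grid and domain choices, whereas the LIN/r-mutant *ratios*
are insensitive to them.

## Known limitations

- Secondary adsorptions beyond the first have no additional effect on a
  lysis-inhibited cell (no cumulative delay, no LIN collapse).
- No phage decay, host resistance, or plaque–plaque interference.
- The competition model has no spatial version (one strain per plaque).
- The starvation response arrests lysis (r_l = 0) rather than driving the
  burst size to zero; a different choice would change the final plaque
  appearance, and only the burst-size floor r_b·β₀ is implemented.
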