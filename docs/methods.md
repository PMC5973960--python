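# Methods

## Kinetic scheme and assumptions

The receptor is a tetramer with four identical, independently binding
glutamate sites. States are unbound `C0`, bound closed `C1..C4`, open
`O1..O4` and desensitized `D1..D4`; only open states conduct, with
sub-conductance weights `a_1..a_4 = 0.1, 0.4, 0.7, 1.0` relative to the
fully bound open state. Transitions are first-order Markov steps except
binding, which is modulated by the transmitter transient:
`k_b(t) = k_b A e^{−ωt}`. The exponential transient is itself a fit to
cleft glutamate after a single vesicle; it is adequate near the conductance
peak and underestimates the true concentration elsewhere (see the
uncoupling diagnostics below).

Two wiring variants are implemented. In `scheme1` channel closing and
resensitization return vertically (`O_i → C_i`, `D_i → C_i`); in `scheme2`
— the variant the closed form solves — they return diagonally to `C_{i−1}`.
The diagonal routing decouples each closed state from its own mesh's open
and desensitized states and is what makes an exact solution possible. There
are no transitions between desensitized states. Binding carries no site-
multiplicity factors (no `4 k_b`, `3 k_b`, …): the per-mesh equations use
the bare rates, and any statistical factors are regarded as absorbed into
the fitted rate constants.

Default parameters (the calyx-of-Held fit used throughout):

| parameter | meaning | default | units |
|---|---|---|---|
| `k_b` | agonist binding | 1e7 | 1/(M·s) |
| `k_u` | agonist unbinding | 8e3 | 1/s |
| `k_o` | channel opening | 20e3 | 1/s |
| `k_c` | channel closing | 10e3 | 1/s |
| `k_d` | desensitization | 4e3 | 1/s |
| `k_r` | resensitization | 15 | 1/s |
| `A` | peak glutamate | 7.48e-4 | M |
| `ω` | glutamate decay | 2471 | 1/s |
| `Q10` | rate temperature coefficient | 2.4 | — |
| `ν` | fraction normalization | 0.13 | — |

All internal times are seconds; the I/O layer converts to milliseconds.

## Uncoupling and the closed form

Each mesh `C_i–O_i–D_i` is solved as an independent pair under the
assumption that binding influx dominates the return fluxes from the next
order. The mesh sees the fraction of channels feeding it as 1 (`C0 ≫`
everything for the first mesh), and absolute scales are restored by the
chain `λ_i(t) = x_{i−1}(t)`. The cascade

    x_i' = k_b A e^{−ωt} λ_i − (k_o+k_u+k_d) x_i,   y_i' = k_o x_i − k_c y_i,
    z_i' = k_d x_i − k_r z_i,     x_i(0)=y_i(0)=z_i(0)=0

is closed in the algebra of finite sums `Σ c_j t^{n_j} e^{−r_j t}`
(`ExpSum`). Linear ODEs with such forcings are solved exactly by a
coefficient recurrence; when a forcing rate coincides with the decay rate
within a relative tolerance of 1e-9 the resonant particular solution
`c t^{n+1}/(n+1) e^{−Kt}` is used instead. The tolerance only matters for
fitted or user-supplied parameters — the default rates are well separated.
The desensitized equation is usually left implicit; the form used here is
the only one consistent with the mesh's `D_i → C_{i−1}` exit at `k_r`.

The first-order open fraction has the familiar explicit form

    y_1(t) = (A k_b k_o) [ e^{−ωt}/(SP) + e^{−(P+ω)t}/(RP) − e^{−k_c t}/(RS) ]

with `S = k_c − ω`, `P = k_d + k_o + k_u − ω`, `R = −k_c + k_d + k_o + k_u`
(`R + S = P`, which is why the coefficients cancel at `t = 0`). Higher
orders are generated by the recursion rather than transcribed: the cascade
is the specification, and it is certified against direct numerical
integration of the uncoupled pairs (max relative deviation ≤ 1e-5 over
0–5 ms for parameter sets within ±50% of the defaults).

Because each mesh pretends its feeder state has occupancy 1, the summed
state fractions overshoot; multiplying all fractions by `ν = 0.13` aligns
the analytical bound-channel sum with the absolute bound fraction of the
detailed spatial simulation at the conductance peak. `ν` (and `g4`) cancel
in every ratio the package reports.

## Temperature

Temperature enters only through `factor = Q10^((T − T_ref)/10)` applied to
all six rates, with `T_ref = 25 °C` and `Q10 = 2.4`; the single 10-degree
step then multiplies every rate by exactly 2.4. The transmitter parameters
`A` and `ω` are deliberately not scaled: postsynaptic receptor kinetics,
not diffusion, dominate the temperature response. An opt-in `Q10_diff`
coefficient scales `ω` alone for users who want a crude proxy for faster
transmitter clearance; it reduces peak amplitude and is disabled by
default.

## Coupled oracle and uncoupling diagnostics

`integrate_full` solves the complete time-varying master equation (LSODA
with analytic Jacobian, defaults rtol 1e-8, atol 1e-12, 10 ms, 2000 output
points). The generator's columns sum to zero, so occupancy conservation is
structural and serves as an integration check (1 ± 1e-8).

`uncoupling_sides` evaluates both sides of the uncoupling inequality from
the coupled trajectory; the per-order error is `100·rhs/lhs` at the time of
peak conductance, the one instant the theory singles out. For the last
order no fifth mesh exists and the right side reduces to `k_u x_4`. Errors
are reported raw and divided by 1.8, the estimated inflation caused by the
single-exponential transmitter fit underestimating cleft glutamate.

Two caveats, stated openly. First, the diagnostics here are mean-field:
the original validation of the uncoupling idea used stochastic spatial
simulation, whose per-order error pattern (sub-percent at first order) is
not reproduced by deterministic occupancy ratios — in the mean-field
trajectory the occupancy cascade is geometric (each order ≈ 0.16× the
previous), so the flux-ratio errors are several tens of percent at every
order, largest at the third. Second, the absolute errors depend strongly on
the transmitter drive; only their ordering across orders is robust.

## Metrics

Peaks are located on a 1 µs grid and refined by bounded scalar minimization
to ~1e-8 s for callable curves (parabolic refinement for sampled ones).
Rise time is 20% → 80% of peak on the rising branch; the decay constant is
a least-squares fit of `log g` from the peak down to 10% of the peak. The
rise/decay conventions are field standards — the underlying theory names
the constants without defining them. Temperature ratios are hot/cold.

## Reduced comparison schemes

Minimal phenomenological kinetic models in the Destexhe tradition, driven
by the same transmitter pulse: `scheme5` (two-state `C ⇄ O`), `scheme6`
(two-state with two parallel `O → C` exits, which are observationally a
single rate — the schemes collapse onto each other, realizing the known
indistinguishability of those constants) and `scheme7` (three-state with a
desensitized state). The exact topologies are a documented reconstruction
of the canonical minimal AMPA models; they are validated through their fit
behavior, not against a printed solution. Each rate carries its own fitted
Q10 factor; fits are bounded trust-region least squares in log space with
eight seeded multi-starts. Fitted factors below 1 are flagged: a rate that
slows with warming has no physical meaning for a conformational transition.
On reference curves generated by the full model, the two-state schemes
leave large residuals, while the three-state scheme fits the cold curve
well but underfits the hot peak amplitude — precisely the failure the
bridging pipeline avoids by carrying temperature in a mechanistic model.

## Bridging pipeline

`bridge` chains: (1) fit the closed-form model to a source-temperature
curve — free parameters are the product `k_b·A` (the two enter the dynamics
only as a product and are not separately identifiable), the five other
rates, `ω`, and one amplitude absorbing `ν·g4`; bounds default to one
decade around the reference values (no physiological bound table exists for
these constants, so the decade is a package choice, configurable);
(2) multiply all fitted rates by `Q10^(ΔT/10)`; (3) regenerate the curve;
(4) refit the requested waveform family: alpha
`g_max (t/τ) e^{1−t/τ}`, single exponential, or dual exponential
`A e^{αt} − B e^{βt}` with both exponents negative. The contract of step
(1) is recovery in curve space; parameter degeneracy is tolerated because
the common multiplication in step (2) maps equally good source fits to
nearly identical target curves (verified as a property test: degenerate
fits bridge to within 2% relative RMS).

All stochastic pieces (multi-starts, synthetic noise) take explicit seeds
and default to seed 0.

## Synthetic data generator

`generate_fixture` samples the closed-form conductance on a regular grid
(default 0–5 ms at 1 µs, the acquisition raster of the underlying
simulations) and applies multiplicative Gaussian noise of stated relative
standard deviation, seeded and bit-reproducible. It emulates a clean,
single-release, low-frequency conductance transient with amplitude-
proportional measurement noise. It does not emulate trial-to-trial
stochastic channel gating, baseline drift, filtering, or multi-vesicular
release — so fit-recovery tests demonstrate correctness of the estimation
machinery, not robustness to every artifact of real recordings.

## Numerical choices

- ExpSum canonical form merges terms whose rates agree to 1e-12 relative;
  exact-zero coefficients are dropped.
- Resonance switch in the ODE solve at 1e-9 relative rate separation.
- Oracle integration: LSODA, rtol 1e-8/atol 1e-12; refinement tests halve
  the tolerances and require occupancy changes below 10×rtol.
- Optimizers: `scipy.optimize.least_squares` (trf) in log10 parameter
  space; multi-start draws are uniform in the log box around the default
  start; the best-so-far result is returned with a convergence flag rather
  than raising on non-convergence.
- Degenerate inputs (all-zero curves, negative times, non-finite
  temperatures, unknown config keys) raise `ValueError` naming the
  offender.
- Problem sizes used by the shipped analyses: 1 µs grids over 0–5 ms for
  closed-form curves (5001 points), 2000 output points over 10 ms for the
  coupled oracle, 8 multi-starts for production fits (tests use 1–2).

## Known limitations

- Single-pulse, low-frequency regime only; no train stimulation, no
  presynaptic plasticity.
- Mean-field occupancies; no per-trial variability (skewness/CV of
  miniature-event amplitudes is outside scope).
- No spatial geometry: transmitter diffusion, vesicle pore dynamics and
  receptor placement are summarized by the fitted `(A, ω)` pulse.
- The uncoupling-error magnitudes from the mean-field oracle quantify the
  internal consistency of this implementation; they are not a substitute
  for stochastic spatial validation of the uncoupling idea itself.
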