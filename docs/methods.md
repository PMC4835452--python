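# Methods

## Physical model

Transcranial magneto-acoustical stimulation (TMAS) applies focused
ultrasound to tissue sitting in a static magnetic field **B**. The acoustic
wave moves ions at the particle velocity of the medium; the Lorentz force
`q v × B` separates charge and drives a current density perpendicular to
both the propagation axis and the field. For a plane wave of intensity
Γ (W/cm²) in tissue of density ρ and sound speed c₀, the particle-speed
amplitude is

    w = sqrt(2 Γ / (ρ c₀))        (Γ converted to W/m² internally)

and the current-density amplitude is

    J₀ = σ B w,

with σ the tissue conductivity. Defaults are σ = 0.5 S/m, ρ = 1120 kg/m³,
c₀ = 1540 m/s. At the standard operating point (Γ = 3 W/cm², B = 3 T)
J₀ ≈ 0.28 A/m² = 28 μA/cm². The exact acousto-electric expression carries a
phase angle ψ with tan ψ = ωτ, where τ is a femtosecond-scale electrolyte
relaxation time; at 200–700 kHz, ωτ ~ 10⁻⁹, so ψ is dropped and the drive
is treated as in phase with the particle velocity.

The carrier applied to the membrane is the **offset sine**
`J(t) = J₀ (sin 2πft + 1)`: non-negative, mean J₀. A zero-mean sine (or
cosine) carrier averages to zero over each ~2 μs acoustic period; the
membrane, an RC low-pass with a millisecond time constant, attenuates the
oscillatory component by a factor ~1/(2πfτ_m) ≈ 3×10⁻⁴ and responds only to
the mean — which is why the zero-mean carrier elicits no sodium current or
spikes while the offset carrier does (`run_figure2_comparison`). Both
zero-mean forms are retained as selectable waveforms for exactly this
comparison. Pulsed stimulation multiplies the full offset carrier by a
square gate of repetition frequency RF and duty cycle DC; the on-window of
period n is the half-open interval ((n−1)/RF, (n−1+DC)/RF], so the gate is
0 at t = 0 and DC = 1 degenerates to continuous stimulation. The gate
convention is measure-zero but fixed, for bit-reproducibility.

Unit regime: users state Γ in W/cm² and currents in μA/cm² (the membrane
model's native unit); all internal acoustics are SI, and each of the two
conversions (W/cm² → W/m², A/m² → μA/cm²) goes through a single named
constant in `forcing`.

## Membrane model

Classical Hodgkin–Huxley in the shifted frame (rest ≈ 0 mV, depolarisation
positive): Cm = 1 μF/cm², gNa = 120, gK = 36, gL = 0.3 mS/cm², VNa = 115,
VK = −12, VL = 10.59 mV. Gating kinetics are scaled by the Q10 factor
φ = 3^((T−6.3)/10); the default temperature 6.3 °C gives φ = 1. The rate
functions αm and αn have removable 0/0 singularities at V = 25 and
V = 10 mV; within 10⁻⁷ mV of those points the analytic limits (1.0, 0.1)
are substituted, since direct evaluation suffers catastrophic cancellation.
The initial state is (V, m, h, n) = (0, 0.053, 0.596, 0.317) — the V = 0
steady-state gate values rounded to three decimals (n_inf(0) is 0.3177 at
full precision; the package reports full precision).

## Integration

Fixed-step classical RK4. The default step 5×10⁻⁵ ms gives 40 steps per
period of a 500 kHz carrier; an oscillatory drive resolved by fewer than 20
steps per period is refused. The drive is evaluated analytically at the RK4
sub-step times rather than sampled-and-held, avoiding aliasing of the
carrier. Gating variables are clamped to [0, 1] after each step (a no-op
analytically; guards round-off overshoot). Everything is deterministic:
identical inputs produce bit-identical trajectories and CSV output. Error
convergence is verified to be ~4th order (ratio ≈ 2⁴ on step halving) on a
constant-current run. Recorded samples are capped at ~10⁶ by an automatic
record stride; constant-current runs use dt = 10⁻³ ms since no carrier
needs resolving.

## Firing threshold

For constant input the resting equilibrium loses stability through a
subcritical Hopf bifurcation near 9.78 μA/cm²; a stable limit cycle
coexists with the stable rest state down to a saddle-node of periodic
orbits near 6.3 μA/cm². `find_firing_threshold` targets the Hopf point —
the level above which firing is sustained no matter how gently the current
is reached. Each bisection level is therefore classified by *equilibrium
stability*: the run starts at the equilibrium state for that current
(solved with Brent's method on the steady-state current balance), displaced
by a 1 mV probe, and counts ≥ 10 spikes in the 200–500 ms window of a
500 ms run as sustained firing. The probe amplitude (~1 % of a spike
height) is chosen large enough that instability grows to spiking within
the window for levels meaningfully above threshold, yet small relative to
every membrane scale; stepping the current onto the resting cell instead
would latch the coexisting limit cycle and report the ~6.3 saddle-node
current. Bisection of [5, 15] μA/cm² to 0.01 yields 9.79.

## Firing-pattern metrics

A spike is a local maximum of V exceeding 50 mV with ≥ 2 ms separation
(both overridable). Healthy spikes in this regime are ~60–105 mV, so 50 mV
separates them cleanly from subthreshold ripple; note that as the drive
current grows toward the oscillation-death regime (below), spike amplitude
shrinks continuously and eventually passes under any fixed detector.
AMP is the mean peak voltage after an onset transient (100 ms for
continuous input, one repetition period for pulsed — the statistics
describe steady-state behaviour). ISI is the mean gap between adjacent
spikes within a burst; for pulsed input, gaps longer than the off-period
(1−DC)/RF are inter-burst silences and are excluded. (At high DC the
off-period can undercut the within-burst ISI, leaving the statistic
undefined; the burst decomposition is heuristic.) FR counts spikes per
complete repetition cycle, skipping the first cycle.

## Sweeps and what they show

Presets `fig4`–`fig9` sweep B (0.5–7 T), Γ (1–100 W/cm², continuous and
pulsed), f (200–700 kHz), DC (5–95 %) and RF (1–100 Hz) about the operating
point Γ = 3 W/cm², B = 3 T, f = 500 kHz (pulsed: DC = 50 %, RF = 10 Hz).
Smoke grids (the default) use each experiment's showcase values; full
grids cover the stated ranges. Continuous sweep points simulate 500 ms;
pulsed points at least 3 repetition periods.

Because the membrane only sees the cycle-mean of the carrier, each sweep is
effectively a slice through the HH constant-current response: AMP falls and
ISI shortens as the mean current grows with B or Γ; both are flat in f
(J₀ is frequency-independent and the residual ripple is negligible); FR
falls with RF (less on-time per cycle). Two caveats follow from the same
physics. Mean currents below ~6 μA/cm² (B ≤ 0.5 T at Γ = 3) elicit at most
onset spikes, so AMP/ISI are undefined there; and above ~90 μA/cm²
(Γ ≥ 60 W/cm² continuous) spikes shrink below the detector on the way to
oscillation death near 154 μA/cm², so high-Γ points go silent — which also
caps the pulsed FR-vs-Γ trend. FR *rises* with DC in this model (more
on-time per fixed cycle yields more spikes per cycle).

## Scope and limitations

The acoustics are a single plane-wave amplitude relation: no propagation,
attenuation/derating, or skull modelling — the derated pressure entering MI
is a user input. The neuron is a point membrane: no channel noise,
cable/compartment structure, intramembrane cavitation, or thermal effects.
Safety indices implement the unscanned-mode display formulas
MI = p_r.3/(√f·C_MI) (C_MI = 1 MPa·MHz^½) and TI = W·f/C_TIS
(C_TIS = 210 mW·MHz) with the acoustic power taken as Γ × spot area; at
Γ = 3 W/cm², f = 0.5 MHz, 3 mm spot and p_r.3 = 0.2275 MPa these give
MI = 0.32, TI = 0.505 — below the unity guideline.
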