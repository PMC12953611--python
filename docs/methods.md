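# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `irute`, in the spirit of a simulation package's
methods appendix. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model

The segmented IR-UTE sequence is simulated as an event chain per TR:

1. Adiabatic inversion, modelled per tissue by an efficiency
   `Q ∈ [−1, 0]`: `Mz → Q·Mz`. Long-T2 water is fully inverted
   (`Q = −1`); ultrashort-T2* species (myelin, cortical bone) cannot
   follow the long frequency-swept pulse and are saturated (`Q = 0`).
   The 10.24 ms hyperbolic-secant waveform itself is not simulated — only
   its binary outcome matters for the contrast mechanism.
2. T1 recovery to the first excitation, then for each of the
   `spokes_per_segment` spokes: record `Mz`, apply `Mz → Mz·cos α`, and
   recover over the spoke interval; finally recover to the end of the TR.
   Transverse magnetization is assumed fully spoiled between spokes
   (hard-pulse UTE excitation with gradient spoiling at low flip angle),
   so no transverse coherence pathways are tracked and each relaxation
   interval has the exact exponential solution — the evolution is
   event-based and analytically exact, not numerically integrated.
3. Per spoke position `s` and echo `e`:
   `Mxy(s,e) = PD · Mz(s) · sin α · exp(−TE_e / T2*)`, mono-exponential
   decay, no off-resonance or chemical-shift phase.

The steady state is the fixed point of the affine one-TR map
`Mz_pre → Mz_end`, found by iteration from thermal equilibrium
(tolerance 1e−10, guard 10 000 iterations). Null-TI solvers: the fully
recovered null is `T1·ln 2` in closed form; the segmented steady-state
null is found by bisection (tolerance 0.01 ms) on the steady-state Mz of
the segment's **center** spoke. TI is referenced to the center spoke by
default (the segment straddles the null point); a `ti_reference="first"`
switch selects the first-spoke convention.

Presets: `simulation` (15°, TR 1000 ms, TI 379.9 ms, TE 0.03/3 ms,
21 spokes / 6 ms, 220 matrix) and the two in vivo variants
(`invivo_10deg`, `invivo_20deg`: TI 320 ms, TE₂ 2.2 ms, 20 spokes / 5 ms).
The source protocol lists both 10° and 20° (and 20 vs 21 spokes per
segment) in different places; both are offered as presets and neither is
privileged.

## Phantom

A procedural stand-in for a segmented head: nested smoothed ellipses
(background → subcutaneous fat → skull → CSF → cortical GM → deep WM) with
a shared low-order random boundary perturbation (so nesting is preserved
by construction), a **solid deep myelin annulus** plus sinusoidal gyral
myelin/WM stripes inside the white matter, and disk-shaped demyelinated
lesions (labelled separately, tissue parameters equal to long-T2 white
matter — i.e. myelin signal loss). The solid annulus exists so that edge
sharpness (EDR) can be measured across a clean circular tissue boundary.

Default tissue parameters are literature-consistent 3 T values constrained
by the method's physics (myelin T2* = 0.2 ms, `Q = 0`, PD ≈ 1/10 of
water; WM_L T1 = 850 ms so its fully recovered null, 589 ms, lies in the
expected 550–693 ms band; skull also ultrashort and saturated). All
values are config-overridable, and an external NIfTI label image with a
sidecar tissue CSV can replace the procedural phantom.

What the phantom does **not** emulate: realistic cortical folding, 3D
anatomy, B0/susceptibility structure, coil sensitivities, or receiver
noise. Passing tests therefore demonstrate the *sampling and gating
mechanisms* — not absolute in vivo image quality, whose printed CNR/SSIM
values depend on scan data this package does not model.

## Trajectory and view ordering

Center-out half-projections with uniform azimuths; the Nyquist count for a
matrix `N` is `⌈πN⌉` (692 at N = 220). Bit-reversed ordering enumerates
`j = 0..2^B−1` (`B = ⌈log₂ n⌉`), reverses each index over `B` bits, and
keeps values `< n` in reversed-rank order — a bijection for any `n`,
reducing to the classical self-inverse permutation at powers of two. 3D
directions (coverage visualization only) use a Fibonacci sphere lattice.

Radial samples span `|k| ∈ [0, N/2]` cycles/FOV with spacing **0.5**
(two-fold readout oversampling, standard for UTE readouts). The finer
spacing is deliberate: at gridding oversampling σ = 2 a unit k-spacing is
two grid cells — coarser than the W = 3 kernel — and the iterative density
compensation then systematically under-weights (~8% against analytic
annulus areas, with a soft rim), degrading round-trip accuracy. At 0.5
spacing the converged weights match analytic annulus areas to <0.1%.
`readout_oversampling=1` remains available.

## Gating

The navigator profile for segment `s` is the baseline SI projection
translated (circular Fourier shift) by the cumulative rigid SI
displacement in effect at `s`, plus white Gaussian noise. The trace is
the profile amplitude at the argmax pixel of the first profile.
Threshold gating splits the trace greedily into contiguous runs whose
in-run range is ≤ 2·window, selects the run with the most segments (ties
→ earliest), and accepts segments within `window` of the run level. The
run level is the run **midrange**, which makes re-gating an already-gated
trace a no-op unconditionally (a mean level can re-reject extreme run
members). The default window is 3× the robust trace SD
(1.4826 × median absolute deviation); a noiseless trace falls back to a
tiny positive window so a constant trace accepts everything. The
transition between plateaus belongs to no run and is rejected.

The motion model is an instantaneous rigid SI translation (a nod, as seen
by an SI navigator); in-plane components corrupt image spokes via the
Fourier shift theorem but are invisible to the trace — which is exactly
the method's stated blind spot and can be exercised through
`apply_motion_shift` directly.

## Reconstruction

Kaiser–Bessel gridding with width W = 3 grid cells, oversampling σ = 2,
and the Beatty shape parameter β = π√((W/σ)²(σ−½)² − 0.8) ≈ 6.486 by
default; `beta=1.9` reproduces the narrow literature kernel verbatim but
is far from the accuracy optimum, so the default favors the Beatty value.
Adjoint: scatter weighted samples onto the 2σ-oversampled grid, centered
inverse FFT, crop, divide by the kernel's analytic transform
(sinh/sinc branches). Forward: the exact dual (pre-deapodize, zero-pad,
FFT, gather). Grid indices wrap modulo the grid size, which is
phase-exact for integer image coordinates. With the default kernel the
operators agree with direct DFT/conjugate-phase summation to ~1e−2
relative (max error normalized by the spectrum peak); the error decays
exponentially with kernel width (~3e−4 at W = 4).

Density compensation is the Pipe–Menon fixed point `w ← w/(C w)` (C =
grid-then-interpolate with the same kernel), 20 iterations with early
stop when the flatness of `C w` changes by <1e−6. At convergence the
gridded density is `1/A²` per cell (`A = W·sinh β / β`, the 1D kernel
area), which fixes the absolute image scale analytically:
`image = adjoint(w·s) · A⁴/(σ²N²)`. A fully sampled soft-edged disk
round-trips with NRMSE < 0.05. The outermost sample of each spoke sits on
the k-space rim and correctly receives about half the ramp weight (it
covers a half cell); interior weights are linear in |k| (Pearson r > 0.99
against the analytic ramp). The DCF is recomputed on the accepted spoke
set after gating by default; precomputed weights can be passed to reuse
the full-sampling DCF instead — both paths are tested.

Dual-echo processing is signed magnitude subtraction `|e₁| − |e₂|` in
image space. The PSF of a (gated) pattern is the density-compensated
adjoint of unit samples, peak-normalized.

### Side-lobe quantification

Two measures are provided. `sidelobe_energy` is the energy fraction
outside a 3-px core. `peak_sidelobe` is the largest magnitude outside the
core relative to the peak. They rank artifacts differently, and the
difference is physical: a missing angular wedge (sequential ordering +
contiguous rejection) concentrates its artifact into one bright coherent
streak — high peak, moderate energy — whereas the comb-like deletion left
by bit-reversal disperses a *diffuse, isotropic* ghost halo whose total
energy is comparable or larger (by Parseval the deleted-sample energy is
similar; only its concentration differs) but whose amplitude is
noise-like. Coherent-artifact severity, the property that matters for
myelin delineation and that the ordering comparison asserts, is therefore
quantified by the peak measure; the energy fraction is reported alongside.

## Study conditions and problem sizes

- Ordering comparison ("which ordering survives gating"): 220×220 phantom,
  692 spokes in segments of 21, 10% contiguous rejection (the final
  acquisition block, mimicking a late motion event), five phantom seeds.
- SSIM-vs-removal sweep: fractions {0, 5, 10, 20, 30, 40, 50, 60}% at
  matrix 128 (the sweep's matrix size is a package choice; the mechanism
  is scale-free, and 128 keeps the sweep fast).
- Motion experiment: a single 8 mm SI nod after segment 29 of 33 (~12% of
  spokes rejected, mirroring the ~10.7% in-scanner rejection rate),
  navigator baseline = SI projection of the echo-1 composite image,
  navigator noise 1% of the profile peak, bit-reversed ordering. CNR uses
  the eroded solid-myelin annulus vs eroded cortical GM over the SD of a
  background corner patch; EDR is the mean over ≥8 radial profiles across
  the annulus' inner edge, excluding (by ground-truth labels) profiles
  through lesions.

## Degenerate inputs and tie-breaks

Validated errors include: non-positive T1/T2*, TI placing the first spoke
before the inversion or the segment past the TR, no Mz sign change over
the TI search range (no null exists, e.g. for saturated tissues), an
all-zero first navigator profile (no reference pixel), a gating window too
small to form any plateau, empty acceptance masks, and mismatched
phantom/trajectory/sequence matrix sizes. Plateau-selection ties go to
the earliest run; the EDR crossing search takes the last 10% crossing
before the first 90% crossing.

## Known limitations

Single coil, 2D reconstruction only (3D is limited to trajectory/gating
visualization); no gradient-delay, B0, eddy-current, or chemical-shift
modelling; rejection-only gating (no motion correction); golden-angle and
phyllotaxis orderings are out of scope. The in vivo quantitative values
reported for the scanner study (SSIM 0.96/0.99, CNR ≈ 10, EDR ≈ 2.6–3.5)
are not reproducible from simulation and are treated as qualitative
anchors only: the package asserts the *directions* of those effects under
its own controlled conditions.
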