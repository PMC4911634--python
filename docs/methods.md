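# Methods

This note documents the models behind `cliftsim`, the defaults they ship
with, and the choices made where the design was genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Thermal transfer model

A donor slide is modelled as a 1-D layered slab: light-absorbing polyimide
(plus, for the self-adhesive foil, a glue layer) under a thin spin-coated
transfer layer of matrix polymer carrying one building block.  The laser
pulse is treated as a constant heat flux

    q = f · P / (π σ²)

over the focal disc at the incident face (absorbed fraction f, power P,
focus radius σ), applied for the pulse duration τ.  The slab's back face is
insulated.  The analytic temperature rise at depth x is the classical
constant-flux conduction solution, summed over images of the two faces:

    ΔT(x, τ) = (2 q √(α τ) / k) Σₙ [ ierfc((2nD + x)/(2√(ατ)))
                                    + ierfc((2(n+1)D − x)/(2√(ατ))) ]

with diffusivity α = k/(ρc) and total thickness D.  The transfer layer is
assumed to eject once ΔT at its upper interface reaches a characteristic
temperature T꜀.  This captures the operational physics — heating competes
with conduction into the stack, so transfer is favoured by higher power or
longer pulses and suppressed by thicker stacks or wider focus — without
modelling melt hydrodynamics, blistering or plume formation (out of scope).

For layered stacks the analytic model homogenises the slab:
series-effective conductivity k_eff = D / Σ(tᵢ/kᵢ) and thickness-weighted
volumetric heat capacity (ρc)_eff = Σ ρᵢcᵢtᵢ / D.  This is exact in the
long-time lumped limit and a good approximation at millisecond pulses
because the preset layers are thermally similar polymers.

**Numerical oracle.** `numeric_temperature_rise` solves the same problem by
an explicit finite-difference scheme on the *resolved* layers
(conservative cell-centred form, harmonic-mean face conductivities, flux
boundary at the incident face, insulated far face).  The time step defaults
to 0.4× the stability bound dx²/(2α_max); a user-supplied step above the
bound raises an error naming the bound.  Accuracy is controlled by
self-convergence (halving dx changes the result by <2% at the default
resolution of ≥10 nodes in the thinnest layer) and by a closed-form check:
for a single homogeneous layer probed at the heated surface, the solver
matches the semi-infinite constant-flux solution 2q√(ατ/π)/k within 5%.

**Analytic vs numerical agreement** is asserted over a 3×3×3 grid spanning
one decade each of P (0.1–1 W), τ (5–50 ms) and D (foil scale 0.1–1.0× under
the fixed 2 μm transfer layer).  The decade anchors keep the probe depth
within ~2.5 diffusion lengths of the surface; beyond that both models decay
to physically meaningless sub-micro-kelvin tails where relative comparison
measures only discretisation noise.  D is varied through the foil rather
than by scaling every layer because the ≥10-nodes rule on a shrunken
transfer layer would force impractically small time steps — and physically
it is the foil choice that varies between donors.  Measured worst-case
deviation is ≈2.3%, against a 25% contract.

**Defaults.**

| parameter | value | why |
|---|---|---|
| polyimide k, ρ, c | 0.12 W·m⁻¹K⁻¹, 1420 kg·m⁻³, 1090 J·kg⁻¹K⁻¹ | standard literature values for polyimide film |
| glue layer properties | = polyimide | adhesive properties unpublished; thermally similar polymer |
| matrix polymer k, ρ, c | 0.16, 1050, 1300 | typical styrene-acrylic resin |
| thick-foil preset | 50 μm polyimide + 45 μm glue + 2 μm transfer | the ~95 μm self-adhesive foil plus a spin-coated film |
| thin-film preset | 5 μm cured polyimide + 2 μm transfer | high-resolution donor (75 μm pitch) |
| absorbed fraction f | 1.0 | "absorbed power" is the model input; f is a knob because delivered vs absorbed energy differ through AOM/optics losses that are not quantified anywhere |
| operating point | τ = 5 ms, σ = 10 μm | 1 W cw source gated to ms pulses; focus radius consistent with 100–120 μm spots |
| T꜀ calibration | threshold at 450 μJ, thick foil, operating point | anchors the model to the onset of the measured linear deposition regime |

T꜀ is a *characteristic* temperature rise of the transfer layer, not a
tabulated melting point: it absorbs everything the 1-D threshold picture
lumps together (melting, solvent evaporation, expansion).  Calibrating it at
the 450 μJ onset makes `threshold_energy` return the calibration energy by
construction and leaves all other predictions (monotonicities, thickness
scaling, the 900 μJ regime) as genuine model output.

## Deposition calibration

Energy→thickness is piecewise linear: 0 below 400 μJ (the weak 300–400 μJ
staining carries no measurable material and is modelled as zero), a short
ramp to 1 nm at 450 μJ, linear to 50 nm at 900 μJ, constant above, and an
optional burn limit that raises an error.  Thickness is interpreted as
uniform-equivalent thickness over the spot disc (whether the measured value
is peak or mean is not stated; uniform-equivalent is the conservative
reading).  Mass = disc volume × matrix density (110 μm diameter,
1.05 g·cm⁻³), reproducing the 10–500 pg range for 1–50 nm.

## Library design

Sequences are stored in synthesis order — solid-phase synthesis elongates
C→N, so residue 1 is the first-coupled, surface-proximal monomer — and
displayed N→C.  Epitopes are conventionally printed N→C while surface-probe
captions list tokens surface-first; `PeptideSequence` exposes both
(`display` and `surface_str`) rather than forcing one convention onto the
other.  Building blocks are free-form tokens validated against an extendable
registry (biotin and propargyl-glycine ship registered), because the
method's repertoire is limited only by which donor slides exist.

Permutation variants are enumerated in binary-counting order over the
differing positions in display order, 0 = parent A's token, so variant ids
(`HAxFlag-010011`) are self-describing and the enumeration is reproducible.
The variant *count* (64 for HA × Flag; 62 non-parental) is data; the
enumeration *order* is this package's convention.

## Layout

Density uses floor(10⁸/pitch²) — the only formula consistent with all three
printed densities (4,444 / 10,000 / 17,777 per cm²).  Grids are row-major
and order-preserving; empty trailing positions are explicit records because
quantification needs the full lattice.  GAL export follows the ATF framing
with a single block whose geometry encodes origin, pitch and extent; a plain
TSV fallback carries the same information.

## Scheduling and consumption

Per-spot cycle = pulse + laser-on delay + laser-off delay + jump delay +
jump time = 5.91 ms at the defaults.  The "jump speed of 100 μs" machine
setting is read as a fixed 100 μs per-spot jump duration — the only reading
with time units.  The instrument's effective per-spot time is somewhat above
this sum (a 215,000-spot/23 min run implies ~6.4 ms), so planning also
carries a 10 ms per-spot budget that upper-bounds the computed cycle; the
budget, not the optimistic sum, is what the ≤15 min structuring claim is
checked against.

Donor exchanges are counted per distinct donor per patterning pass with no
carry-over between passes (the loader re-fetches each donor), which is the
arithmetic that gives 20 donors → 800 s.  Double coupling (on by default)
repeats patterning+coupling+acetone wash once before deprotection; the fixed
per-layer tail is capping 30 min, 2×5 min DMF, piperidine 20 min, 2×5 min
DMF, 2×2 min acetone.  Parallel wet processing of several acceptor slides is
a throughput multiplier for reporting and deliberately not a per-slide time
change.

Consumption: passes per block (double counting twice) → slides =
⌈passes/reuse limit⌉ (reuse 20) → mass = slides × 15 mg (8 mg for biotin).

## Two-layer activation patterns

Recipes list solids only; solvent evaporates during spin-coating, so mass
fractions are over solids (DIC/HOBt donor: 3.75 mg HOBt + 7.25 mg DIC +
139 mg matrix; free-acid donor: 15 mg Fmoc-Gly-OH + 135 mg matrix — the DIC
mass is printed with a comma decimal, read as 7.25 mg).  Crossed gradients
deposit recipe 1 at row-indexed energies under recipe 2 at column-indexed
energies; per-spot masses come from the deposition calibration, so monotone
energy lists give monotone amounts by construction.  Mixing on melting is
treated as complete within a spot; activation kinetics and the faint
free-acid background are out of scope.  Stoichiometry divides component
masses (deposit × mass fraction) by shipped formula weights (Fmoc-Gly-OH
297.3, DIC 126.2, HOBt 135.1 g·mol⁻¹ — standard values, editable); equal
500 pg deposits of the two preset recipes give DIC:Gly ≈ 1.14.

## Virtual readout

Full-length fraction = (per-layer effective yield)^n with effective yield
1−(1−ε)² under double coupling; capping is assumed to remove truncations
from further growth.  At effective yields ≥0.99 the 9-layer:3-layer ratio is
≥0.94 — the regime consistent with probe series of increasing length showing
no appreciable intensity drop.  This is a consistency property of the model,
not a fitted ε.

Signal defaults to the full-length fraction alone: picogram-scale deposits
are assumed saturating relative to surface site density.  An optional
mapping scales signal by min(deposit/500 pg, 1) for sub-threshold studies.

Rendering: Gaussian profiles (default spread 25 μm) at lattice centres on a
5 μm/px 16-bit image, amplitude linear in signal, additive Gaussian
background noise from a generator seeded per call (byte-reproducible).
Quantification: mean over a fixed-radius circle (default pitch/3) minus the
median of a 1.5–2.5-radius background annulus; replicate CV = sd/mean over
spots sharing an id.  Noiseless round-trips recover relative signals within
1% *provided* the annulus stays clear of neighbouring spot tails — the
round-trip tests use a 10 μm profile and 25 μm radius at 150 μm pitch for
that reason; with the wider default profile the annulus median picks up
neighbour shoulders and ratios degrade at the few-percent level.  This is a
real property of annulus-based backgrounds, not an artefact of the
simulation.

## What the synthetic data does and does not show

The virtual arrays emulate geometry, signal linearity, background and
replicate structure of a scanned array.  They do not emulate chemistry-level
variability (coupling-yield heterogeneity between residues, edge effects,
staining gradients, scanner PSF, photobleaching), so passing round-trip and
CV tests demonstrates the *pipeline's* correctness and the quantifier's
behaviour under controlled conditions — not synthesis quality of any real
array.  Likewise the thermal model's agreement with its FD oracle validates
the conduction mathematics, not the ejection mechanism, which remains an
empirical threshold captured entirely by the 450 μJ calibration.

## Problem sizes

Default test and demo sizes are chosen to run in seconds on one CPU: the
64-member scan, 10,000–100,000-spot scheduling arithmetic, 4×4–8×8 rendered
grids, and 9 FD solves (the P-axis of the 27-point comparison uses the FD
solution's exact linearity in P).  All are full-fidelity computations, not
stubs; larger arrays scale linearly through the same code paths.
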