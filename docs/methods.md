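# Methods

## Physical model

The sensor is a conical glass nanopipette immersed in 125 mM NaCl with an
Ag/AgCl working electrode inside the barrel and a grounded reference in the
external bath.  We solve the steady-state Poisson–Nernst–Planck system in
the axisymmetric (r, z) half-plane, z = 0 at the orifice, z > 0 up the
barrel:

* Poisson: ∇·(ε₀ε∇φ) = −F(c_Na − c_Cl) in the electrolyte and
  ∇·(ε₀ε_g∇φ) = 0 in the glass, with a prescribed surface charge density σ
  on every wetted glass face (jump condition ε₀[ε ∂φ/∂n] = −σ) and on the
  protein surface.
* Nernst–Planck: ∇·J_i = 0 with J_i = −D_i(∇c_i + z_i c_i ∇ψ) + u c_i,
  ψ = φF/RT.  The advective term u (electroosmosis) is an opt-in coupling
  (`SolverOptions.include_stokes`); the headline currents are computed from
  pure drift–diffusion, and switching the Stokes coupling on changes the
  open-pore current at ±0.2 V by ~4%.
* Boundary conditions: φ = V and c_i = c_bulk on the barrel cross-section
  at the top of the window (working electrode side), φ = 0 and c_i =
  c_bulk on the outer bath boundaries, zero normal ion flux on glass and
  protein surfaces, symmetry on the axis.

Default parameters: pore diameter 4.6 nm; cone half-angles 6.5° at the
orifice and 1° up the waist (transition at the window edge, since the
published geometry does not locate it); glass thickness 9 nm at the
orifice with ε_g = 3.9 and σ_glass = −0.032 C/m²; D_Na = 1.33·10⁻⁹,
D_Cl = 2.03·10⁻⁹ m²/s; ε_w = 78.5; T = 298 K.  The Debye length is
0.86 nm and the bulk conductivity 1.58 S/m.  All defaults live in
`nanopipette.config.DEFAULTS`, one key per physical parameter.

Proteins are rigid spheroids with semi-axes a = 1.7015, b = 1.5705 nm
(consistent with a 12 kDa protein at 1.35 g/cm³).  *Prolate* aligns the
major axis with the pore axis; *oblate* puts it radial, leaving a 0.6 nm
annular gap at the orifice.  Chains of 2–3 proteins touch pole-to-pole
(centre spacing 3.403 nm prolate, 3.141 nm oblate) and translate rigidly.
Proteins are impermeable, zero-ion-flux holes in the mesh carrying their
surface charge (+0.012 C/m² by default; alternatively estimated from an
amino-acid sequence by summing Henderson–Hasselbalch fractional charges
with the EMBOSS pKa set over the Thomsen spheroid area).  The protein's
bulk permittivity and the ion radius are carried as configuration but not
used by the default model.

## Discretisation and solver

The mesher lays hexagonal point lattices whose pitch follows a sizing
field — 0.13 nm within ~1.3 nm of the orifice ring and protein surfaces
(≤0.2 Debye lengths), 0.20 nm in a 1 nm band along all wetted glass,
≥4 elements across the bore everywhere, growing to several nm in the far
field — plus explicitly sampled boundary polylines, then Delaunay-
triangulates and classifies triangles by centroid into electrolyte, glass,
or protein (removed).  All lattices and boundary samples are anchored to
absolute coordinates, so moving the protein changes the mesh only in its
neighbourhood; this keeps the position-sweep current numerically smooth
(residual scatter ≲0.05%, versus ~0.3% with unanchored meshes).  Touching
spheroids meet in a cusp that cannot be meshed; a short "neck" cylinder
(half-length 0.35 nm, radius matching the spheroid cross-section at that
offset) fills the dead-end crevice around each contact, which carries no
axial current.

Transport uses the edge-averaged finite element (EAFE) scheme: each edge's
Laplacian weight is modulated by Bernoulli functions of the thermal-unit
potential drop, the 2-D generalisation of the Scharfetter–Gummel flux.
On Delaunay meshes this is an M-matrix scheme — concentrations stay
positive at any bias — and it is well conditioned at the full ±1 V
(±39 kT/e) range.  The nonlinear system is solved by Gummel iteration
(Boltzmann-linearised Poisson–Newton step, then two linear transport
solves) accelerated with depth-5 type-II Anderson mixing on the packed
(ψ, log c) state; cold starts ramp the voltage in 0.2 V continuation
steps, and position sweeps warm-start from the previous protein position.
Successive linear systems share sparsity patterns, so LU factors are
recycled as preconditioners for GMRES and refreshed on stall.

Convergence is declared when the potential update falls below the relative
tolerance, or when the electrode current is stable to the tolerance on
consecutive sweeps with a small potential update.  The solver default is
10⁻⁶; sweeps use 10⁻⁴ (current-based), which resolves fractional
blockades to ~0.01 percentage points at a fraction of the cost.

The reported current is the discrete electrode flux (reaction-force sum of
the transport residuals over electrode nodes, F·(Φ_Na − Φ_Cl)), which is
exactly conservative.  `compute_current` provides an independent estimate
by integrating the P1 fluxes over a pore cross-section; for sections
inside the pipette it integrates the bore only, because the truncated
window grounds the outer bath and a small real leakage current returns
through the external annulus.  Bore sections agree with the electrode flux
to <0.1%, and `check_flux_conservation` monitors the spread across
sections (note that each Gummel sweep solves the linear transport problem
exactly, so species flux is conserved even before self-consistency — an
unconverged state shows up in the convergence flag and a wrong current,
not in a conservation defect).

Validation oracles (in the test suite): zero fields at equilibrium; the
linearised double-layer profile φ(r) ∝ I₀(r/λ_D) next to a weakly charged
wall (within 5%); the uncharged-cylinder conductance against
L/(κπa²) + 1/(4κa) (solver agrees to ~0.4%, asserted at 20%); voltage
antisymmetry of the uncharged pore (R = 1 ± 0.02); open-pore current
change of 0.7% under one mesh-refinement level.

## Simulation windows

The translocation window is ±20 nm with the tip at the centre; position
sweeps run the lead protein from 10 nm outside to 15 nm inside the pore.
The default sweep grid is 0.25 nm through the interaction region
(−4…+10 nm) and 0.5 nm outside, with golden-section refinement of the
current minimum; halving the step moves the fractional blockade by well
under 0.5 points.  The coarse test grid doubles these steps.

Ion-current rectification is a reservoir-scale phenomenon: it arises from
voltage-dependent salt accumulation/depletion that develops over hundreds
of nanometres of barrel and bath, and a ±20 nm window pins the
concentration to its bulk value too close to the tip for any asymmetry to
survive (we measure R = 1.01 there).  The open-pore I–V protocol therefore
places the reservoirs at ±600 nm with a far-field-graded mesh (R grows
with window size: 1.37 at 80 nm, 1.56 at 160 nm, 1.77 at 600 nm, still
rising slowly toward an asymptote near ~2 at micron scale).  600 nm keeps
the two ±0.2 V solves within a few minutes on one CPU; the blockade
quantities are tip-local ratios and stay at the ±20 nm translocation
window.

## Blockade observables

* **Fractional blockade**: 100·(I_open − I_min)/I_open from the sweep
  minimum (golden-section refined).
* **Translocation interval / fluctuation**: the translocation interval is
  delimited by the first and last *prominent* local current minima of the
  chain (prominence ≥3% of the blockade depth, which keeps the genuine
  inter-protein oscillations and rejects solver-level ripple).  The
  fluctuation is the half-range of the current in that interval as a
  percentage of its mean.  A sweep with a single prominent minimum has no
  such interior interval; there the interval runs from the minimum to the
  end of the ±0.5% deviation region (the protein still inside the pore)
  and the result is flagged.
* **Extent**: length of the contiguous region where |I − I_open|/I_open >
  0.5%.  Because the positively charged protein slightly *enhances* the
  current on approach (its counter-ion cloud adds conductance before
  occlusion takes over), the deviation first crosses 0.5% when the lead
  protein is ~5–6 nm outside the pore.
* **Speed**: extent divided by the per-class measured dwell times
  (1.0 / 1.15 / 1.3 ms), a constant-velocity reading.
* **MSE comparison**: templates are position sweeps read out at their
  constant speed, normalised to relative current, aligned to the recorded
  event by registering current minima, and scored by mean squared error on
  the overlapping support.

## Signal pipeline

The digital 8-pole Bessel filter is the bilinear realisation of the analog
prototype with the −3 dB point at the 2 kHz cutoff (causal by default, as
in hardware; a zero-phase mode exists for simulation comparisons), with
its state initialised from the early-sample mean so the start-up transient
stays below the noise floor.  The baseline (open-pore level) is the upper
sustained mode of the sample distribution: seeded at the 97.5th percentile
and refined by an iterated ±3σ-masked median; traces whose baseline covers
less than half the samples are rejected.  QC requires windowed baseline
drift below 2% of I_open, |V| ≤ 1 V, and filtered peak-to-peak noise
(robust 0.5–99.5 percentile span) ≤30 pA.

Detection opens an event when the zeroed current falls below 5 robust σ
and closes at 1σ with hysteresis; the event window is widened to the
±0.5%-of-I_open band.  Dwell is measured between crossings at *half the
event depth*: a causal low-pass delays both edges equally at half depth,
so this estimate is unbiased, whereas ±0.5%-band crossings are stretched
by the filter's settling tails (~+0.8 ms on a 1.3 ms rectangular event).
Classification assigns single/double/triple when (FB, dwell) falls in the
band rectangle (FB 33–36 / 52–57 / 61–70%, dwell within mean ± 3 spreads
of 1.0±0.02 / 1.15±0.03 / 1.3±0.03 ms); everything else is unclassified.

## Synthetic recordings

The generator emulates the instrument chain: 250 kHz digitiser rate,
baseline I_open = 300 pA, white Gaussian noise (σ = 3 pA on event traces;
QC traces carry band-limited noise so their measured filtered peak-to-peak
spans sit at ~15 pA and ~40 pA, on either side of the 30 pA bound),
optional linear drift, and events superposed as rectangular dips or as
position-sweep templates read at constant speed.  Event (FB, dwell) values
jitter around the class band centres (FB s.d. 0.5 points; dwell s.d. equal
to the per-class spreads).  Everything is a pure function of the seed.
What the fixtures do *not* model: 1/f and dielectric noise, capture-rate
statistics, baseline steps from electrode drift, or event–event
interactions — so pipeline tests validate the detection/measurement
machinery, not instrument realism.

## Known limitations

* **Absolute blockade depth.**  The axisymmetric continuum model bounds
  the fractional blockade at roughly the tip constriction's share of the
  total series resistance.  With this geometry the region within ±3 nm of
  the orifice carries only ~25% of the open-pore resistance (the conical
  barrel and access path carry the rest, and wall surface conduction
  further dilutes the constriction's share), so a single protein that
  blocks half the orifice area yields FB ≈ 10–13%, and a 3-chain ≈ 20%.
  Reported experimental blockades for this sensor class (40–75%) would
  require an essentially aperture-limited resistance and are not
  reproducible from the stated geometry by this model; the package
  reproduces the *orderings and contrasts* (deeper with chain length,
  oblate > prolate, contrast growing with n) rather than the absolute
  depths.  Mesh refinement changes these values by <1 point, and the
  protein's surface charge moves them by a few points (positive charge
  partially offsets occlusion; at +0.065 C/m² the counter-ion cloud
  overcompensates and the "blockade" becomes a ~10% current enhancement).
* **Rectification magnitude.**  Pure PNP with desk-scale reservoirs
  underestimates the measured R = 2.57 at ±0.2 V; see the window
  discussion above.
* On-axis, rigid, rotationally aligned proteins only; no Brownian motion,
  no position-dependent velocity, no capture kinetics.
* The Stokes coupling uses stabilised P1-P1 elements and one-way force
  coupling per Gummel sweep; it is a correction, not a validated
  electroosmosis study.
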