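# Methods

This note records the models implemented in `graftflow`, the assumptions
behind them, the numerical choices that affect results, and what the
synthetic fixtures do and do not establish.

## 0D lumped-parameter network

**Model.** The vascular domain is a directed graph. Each segment carries a
nonlinear resistor and an inductor in series:

    ΔP(Q) = a·Q|Q| + b·Q + L·dQ/dt

The (a, b) coefficients are intended to come from fitting pressure-drop vs
flow samples of steady 3D simulations (`fit_quadratic_resistance`, a
zero-intercept least-squares fit — no drop at zero flow). The quadratic
term is implemented as a·Q|Q| rather than a·Q² so the drop opposes
retrograde flow; for forward flow the two coincide. The inertance follows
the large-artery estimate L = (4/3)·ρ·l/A, with blood density ρ = 1056
kg/m³ by default. Each arterial outlet carries a three-element Windkessel:

    C·dP_c/dt = Q − (P_c − P_ref)/R_d,   P_boundary = P_c + R_p·Q

Venous outlets are fixed static pressures (default 8 mmHg); a single node
carries the prescribed pulsatile inflow.

**Discretisation.** Backward Euler with a damped Newton solve per step.
Junction mass balances are equations of the nonlinear system, so flow
conservation holds to the Newton tolerance (1e-12 of the inflow scale;
observed residuals ~1e-16). The backward-Euler error is first order in dt;
with the default dt = T/250 the last-cycle systolic pressure moves by less
than 0.2% under halving of dt. Cyclic convergence uses the same criterion
as transient 3D simulations: < 1% change in peak systolic pressure between
subsequent cycles; runs default to 6–8 cycles, comfortably past that point
for physiological time constants (R_d·C ≈ 0.1–0.5 s).

**WK3 calibration.** Two targets (systolic inlet pressure, cycle-mean
arterial outflow fraction) cannot identify three parameters, so the
proximal:distal resistance ratio is fixed at 0.4:0.6 — the conventional
division of total peripheral resistance — and (R_total, C) are optimised in
log10 space with a bounded trust-region least-squares solve (bounds
R_total ∈ [1e6, 1e13] Pa·s/m³, C ∈ [1e-13, 1e-6] m³/Pa keep the inner
Newton solve well conditioned). Identical parameters are applied at every
arterial outlet; the split among them is then decided by the segment
resistances, mirroring clinical practice when no per-outlet flow data
exist. The optimiser is deterministic; an optional log-space jitter of the
starting point exists to probe robustness. If the optimum misses the
systolic target by more than 1% (relative) or the split target by more
than the stated band (±0.05 absolute by default), a `CalibrationError`
reports the best achieved values — the targets are treated as infeasible
rather than silently approximated. Only the targets are identified:
different (R_p, R_d, C) triples can satisfy them equally well.

## Volume descriptors

Velocity fluctuations are deviations from the single-cycle time mean.
This conflates pulsatile and genuinely turbulent content — a periodic
laminar flow has nonzero "TKE" under this definition — but it is the
standard resolved-fluctuation treatment when only one simulated cycle is
available. TKE is reported at peak systole, defined as the argmax of the
inflow waveform (or of domain kinetic energy when no inflow is supplied).

Vorticity is reconstructed per tetrahedron from the linear (P1)
interpolant — a constant curl per cell, exact for affine velocity fields —
and averaged to nodes with cell-volume weights. Helicity integrals use the
per-cell midpoint rule: the nodal integrand (v·ω for h₁, |v·ω| for h₂ —
the absolute value is taken *before* cell-averaging, matching the
definition of the integrand) is averaged over the four nodes and
multiplied by the cell volume. Time integrals everywhere are trapezoidal
with periodic wrap closure: a series sampled on [0, T) is closed with its
first sample at t₀+T. LNH is set to 0 where |v||ω| < 1e-12 (SI).

## Wall descriptors

TAWSS, OSI and transWSS are per-node; the unit-WSS divergence and TSVI are
per-cell. WSS vectors are projected onto the local tangent plane on load
(WSS is tangential by definition; the removed normal component is
recorded). For transWSS the in-plane direction perpendicular to the mean
WSS is n × m with n the outward normal and m = ∫τdt/|∫τdt|; where the
cycle-mean WSS vector is numerically zero (perfect reversal, OSI → 0.5) the
mean direction is undefined, so the node is flagged and assigned 0.
Numerical floors: |τ| < 1e-6 Pa is treated as zero when normalising the
unit WSS field; ∫|τ|dt < 1e-9 Pa·s makes OSI 0.

The surface divergence is computed per triangle from the P1 shape-function
gradients in the triangle plane (exact for fields affine over a flat
patch); on the refined annulus fixture (32 radial × 128 circumferential
cells) the divergence of the radial unit field matches 1/r within ~2%.
TSVI is the cycle-RMS of the divergence about its own cycle mean.

## Criticality

One patient-specific threshold per descriptor is computed on the
whole-domain luminal distribution as an **area-weighted percentile**
(smallest value at which the cumulative element area reaches the target
fraction, linearly interpolated between adjacent distinct values), then
applied inside each ROI. Defaults: 33rd percentile / below-is-critical for
TAWSS; 66th / above-is-critical for OSI, transWSS, TSVI. The mask uses
strict inequality — equality is non-critical — which is immaterial for
continuous fields but fixed for reproducibility. Thresholding supports
cell-based values (default; node descriptors are averaged over each
triangle's three nodes, weights are cell areas) or node-based values
(weights are lumped node areas, one third of incident triangle areas).
The similarity index between two critical maps is the area-weighted Dice
overlap, 100·2·area(A∩B)/(area(A)+area(B)), with 100 for two empty masks.

## Synthetic fixtures: what they establish

The fixtures replace solver output with analytic fields whose descriptor
values are known in closed form:

- **Cylinder mesh**: structured — a triangulated polygonal disc extruded to
  wedges, each split into three tetrahedra by the smallest-global-index
  diagonal rule, so shared faces conform; deterministic for a fixed spec.
  At the refined setting (6 rings × 32 sectors × 10 layers) volume and
  lateral area agree with πR²l and 2πRl within 1% (the residual is the
  polygonal cross-section, not mesh error).
- **Womersley flow**: fully developed pulsatile pipe flow from flow-rate
  harmonics; the steady harmonic is Poiseuille with wall shear 4μQ/(πR³);
  requires constant viscosity.
- **Helical field** v = (−Ωy, Ωx, W): vorticity (0, 0, 2Ω), helicity
  density 2ΩW, LNH(r) = W/√(Ω²r²+W²).
- **WSS patterns**: unidirectional-pulsatile (OSI = 0, transWSS = 0),
  square-wave reversal (OSI = 0.5 exactly, including under the trapezoidal
  wrap rule), rotating constant magnitude (TAWSS = τ₀), biaxial sinusoid
  (transWSS oracle), divergence-switching radial field (TSVI = 1/r).
- **Toy AVG network**: six segments — inlet, three arterial branches of
  distinct calibre, graft, venous restriction — with three WK3 outlets and
  one 8 mmHg venous sink. Coefficients are chosen to represent a
  functioning ~1 L/min access in which the clinical calibration targets
  (110 mmHg systolic, 27% arterial split) are physically attainable; the
  inflow is a two-harmonic pulsatile waveform (peak ≈ 1.8× mean).
- **Rheology**: Carreau–Yasuda μ(γ̇) = μ∞ + (μ₀−μ∞)[1+(λγ̇)^a]^((n−1)/a)
  with representative whole-blood defaults (μ₀ = 0.056 Pa·s,
  μ∞ = 0.0035 Pa·s, λ = 3.313 s, a = 2, n = 0.3568), all overridable.

Passing on these fixtures establishes the descriptor arithmetic, the
integration rules, and the calibration machinery. It does **not** establish
solver physics: no turbulent or transitional field is emulated, the
velocity fixtures are smooth and axisymmetric, and real patient geometries
add curvature, junctions and separated flow that only a 3D solve provides.

## Numerical conventions and degenerate inputs

- SI units internally (m, s, Pa, m³/s, kg/m³); mmHg accepted in configs at
  1 mmHg = 133.322 Pa. Node indexing is 0-based; converted at file I/O.
- Waveform resampling: cubic spline, periodic end conditions for periodic
  waveforms, not-a-knot otherwise (exact on cubic polynomials).
- Waveform comparison: pointwise percentage difference on a common grid,
  mean and population SD; reference samples with |ref| < 1e-6·max|ref| are
  excluded and counted.
- Tetrahedron orientation is normalised on construction (negative volumes
  are repaired by swapping two nodes; zero volumes are rejected).
- Degenerate triangles, empty ROIs, rank-deficient resistance fits,
  non-finite peaks and topology mismatches across series files all raise
  typed errors rather than propagating NaNs.

## Problem sizes

Defaults are desk-scale: cylinder fixtures of 10³–10⁴ cells, 0D
simulations of 250 steps/cycle × 6–8 cycles, calibration in ~40–60
forward simulations (~20 s single-core). All numerical claims above are
checked by the test suite on exactly these sizes.

## Known limitations

- The 0D model has no vessel compliance outside the WK3 elements and no
  automated extraction of ΔP–Q samples from 3D results.
- The WK3 calibration identifies targets, not parameters; parameter values
  should not be interpreted physiologically beyond order of magnitude.
- TKE mixes pulsatile and turbulent fluctuations (single-cycle mean).
- WSS is consumed as solver output; it is not recomputed from the volume
  velocity field.
- The similarity index is one concrete choice (area-weighted Dice) among
  several overlap measures in use; alternatives can be plugged in at the
  reporting layer.
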