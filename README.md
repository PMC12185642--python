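# graftflow

A toolkit for patient-specific hemodynamic analysis of arteriovenous grafts
(AVGs) — the synthetic conduits that connect an artery to a vein for
hemodialysis access. AVGs fail mostly through neointimal hyperplasia (NIH),
a wall-thickening response that is strongly conditioned by local
hemodynamics. `graftflow` implements the two computational halves of an
AVG modelling workflow around the 3D CFD solve itself:

1. **0D lumped-parameter boundary-condition modelling.** The vascular domain
   is reduced to a directed network of segments, each a nonlinear resistor
   and inductor in series,

   ΔP(Q) = a·Q|Q| + b·Q + L·dQ/dt,  with inertance L = (4/3)·ρ·l/A

   for a segment of length *l* and cross-sectional area *A*. Arterial
   outlets carry three-element Windkessel (WK3) models
   (proximal resistance R_p, compliance C, distal resistance R_d), venous
   outlets a static pressure. An automated calibration adjusts identical
   WK3 parameters at all arterial outlets until the simulated systolic
   inlet pressure and the cycle-mean arterial flow split match measured
   targets (e.g. 110 mmHg and 27% ± 5% of the inflow).

2. **Descriptor post-processing of time-resolved CFD fields.** From velocity
   fields on a tetrahedral mesh and wall-shear-stress (WSS) fields on the
   triangulated lumen over one cardiac cycle of period *T*:

   - turbulent kinetic energy, TKE = ½ρ((u′)² + (v′)² + (w′)²), with
     fluctuations about the cycle-averaged velocity, at peak systole;
   - helicity descriptors h₁ = (1/TV)∬ **v**·**ω** dV dt (net amount),
     h₂ = same with |**v**·**ω**| (intensity), h₃ = h₁/h₂ and h₄ = |h₃|
     (rotational balance), and the local normalised helicity
     LNH = **v**·**ω**/(|**v**||**ω**|);
   - near-wall indices TAWSS = (1/T)∫|**τ**|dt,
     OSI = ½(1 − |∫**τ**dt|/∫|**τ**|dt),
     transWSS = (1/T)∫|**τ**·(**n**×**m**)|dt with **m** the unit mean-WSS
     direction, and TSVI, the cycle-RMS fluctuation of the surface
     divergence of the unit WSS field;
   - patient-specific critical-area detection: area-weighted percentile
     thresholds (33rd for low-TAWSS, 66th for high OSI/transWSS/TSVI),
     per-ROI critical-area percentages, and Dice similarity between
     critical maps.

A fixtures module generates everything needed to exercise the pipeline
without patient data: structured cylinder meshes, Womersley/Poiseuille
pulsatile pipe flow with closed-form wall shear, rigid-rotation helical
fields with closed-form h₁–h₄ and LNH, prescribed spatio-temporal WSS
patterns with known descriptor values, a Carreau–Yasuda blood-rheology
evaluator, and a six-segment 0D twin of a closed-loop AVG circuit.

## Worked example: Windkessel calibration on the synthetic AVG network

```
$ graftflow fixtures --kind toy-network --out net
$ graftflow net0d calibrate --network net/network.yaml --inflow net/inflow.csv \
      --systolic "110 mmHg" --split 0.27
{
 "r_p": 1609856386.764306,
 "r_d": 2414784580.1464586,
 "c": 1.2534027197067594e-10,
 "p_ref": 1066.576,
 "systolic_mmHg": 110.00000000000243,
 "arterial_split": 0.2700000000000004
}
```

The network is the six-segment AVG circuit (inlet → anastomosis node →
three WK3-terminated arterial branches, plus graft and venous-restriction
segments draining to an 8 mmHg venous sink), driven by a pulsatile
~1 L/min inflow. The calibrated proximal/distal resistances (Pa·s/m³) and
compliance (m³/Pa) reproduce the 110 mmHg systolic inlet pressure exactly
and send 27.0% of the cycle-mean inflow to the arterial outlets — the
remaining 73% transits the graft, as in a functioning access.

The descriptor half runs from a YAML config

```
$ graftflow run config.yaml
```

which reads the named velocity/WSS series, writes descriptor fields
(`wall_descriptors.vtk`, `volume_descriptors.vtk`), the helicity table
(`helicity.csv`), the criticality report (`criticality_report.csv`, one row
per descriptor × ROI with threshold, direction and % critical area) and a
JSON summary. Repeated runs on the same inputs are bit-identical.

## Layout

- `graftflow.meshes`, `graftflow.io_core`, `graftflow.vtkio` — mesh and
  field-series containers, VTK/CSV/YAML I/O
- `graftflow.waveforms` — resampling, velocity→flow conversion, waveform
  comparison statistics, cyclic-periodicity detection
- `graftflow.lumped0d` — 0D network model, simulation, WK3 calibration
- `graftflow.volume_descriptors`, `graftflow.wall_descriptors` — TKE,
  helicity, LNH; TAWSS, OSI, transWSS, TSVI
- `graftflow.criticality` — thresholds, critical masks, ROI fractions,
  similarity index, report assembly
- `graftflow.fixtures` — synthetic meshes, analytic flows, WSS patterns,
  rheology, toy network
- `graftflow.pipeline`, `graftflow.cli` — end-to-end orchestration and the
  `graftflow` command

See `docs/methods.md` for the modelling assumptions, numerical choices and
limitations.
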