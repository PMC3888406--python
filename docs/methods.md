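# Methods

This package implements a multiscale study of how early
afterdepolarizations (EADs) at the single-cell level organize into
arrhythmic wave patterns in two-dimensional human ventricular tissue.
This note documents the model, the analysis operators, the numerical
choices, and the limits of what the test suite demonstrates.

## Cell model

The cellular kinetics are the ten Tusscher–Panfilov 2006 (TP06) human
ventricular model, endocardial variant: 12 Hodgkin–Huxley-type gates,
intracellular Na⁺/K⁺/Ca²⁺ handling with SR release–uptake–leak and
calcium buffering in cytosol, subspace and SR. Units are the TP06
conventions (mV, ms, pA/pF, mM, T = 310 K).

Two modifications reduce repolarization reserve so that EADs can be
evoked:

* the maximal L-type conductance baseline is **doubled**
  (G_CaL = 2 × 0.00003980 mm³·µF⁻¹·ms⁻¹), and
* the voltage-inactivation time constant τ_f(V) of I_CaL is **halved**
  (`tau_f_scale = 0.5`, applied uniformly to the whole τ_f(V) curve).

Baselines of the swept channels: G_Ks = 0.3923027 nS/pF,
G_Kr = 0.1532432 nS/pF, k_NaCa = 1000 pA/pF. Four dimensionless
multipliers (`mult_CaL`, `mult_Ks`, `mult_Kr`, `mult_NaCa`) scale the
respective maximal conductances; `(mult_CaL, mult_Ks)` spans the phase
diagrams studied here. All remaining constants are the published TP06
endocardial set.

**EAD mechanism.** During the plateau, halved τ_f lets the f-gate
recover while the cell is still depolarized; with enhanced G_CaL the
re-activated window current I_CaL can transiently exceed the (reduced)
outward K⁺ currents, reversing repolarization. `detect_ead_drivers`
verifies on simulated traces that I_CaL is the dominant inward current
at every EAD onset.

## Integration

Gates are advanced with the Rush–Larsen exact-exponential update;
voltage and concentrations with forward Euler (a pure-Euler gate mode
exists behind the `euler_gates` switch for fidelity checks). Default
`dt = 0.02 ms`. Voltage-dependent gate steady states and time
constants, plus a few pure voltage factors, are pre-tabulated on a
0.05 mV grid over [−150, 150] mV and linearly interpolated inside the
numba kernels; the tables are generated from the same reference
formulas that the (slow, readable) NumPy implementation uses, and a
test pins the two paths together. Voltages outside [−150, 150] mV
abort integration (rate-function overflow guard); NaNs abort naming the
first offending state field.

**Initial state.** Simulations start from the published TP06 initial
conditions (a paced-steady-state snapshot) relaxed for 1 s without
stimulus. This is deliberate: the *deep* quiescent equilibrium of the
unstimulated model is far from the physiological operating range (Na_i
drains to ≈ 3.5 mM over ~20 model-minutes) and is not the state a paced
myocyte ever occupies. The deep equilibrium remains reachable
(`find_rest_state(..., settle_ms≈10⁶)`) and is verified against an
algebraic root of the right-hand side in the tests.

**Stimulus.** 20 pA/pF (depolarizing-positive) for 2 ms, both for
single cells and tissue; both are configurable.

## Single-cell classification

Labels: `NORMAL`, `EAD`, `OSCILLATORY`. An EAD is a local minimum of V
followed by a rise of ≥ `rise_min` (1 mV) occurring while V lies in the
plateau/repolarization band (`plateau_floor` −40 mV < V <
`ead_ceiling` +20 mV), after the upstroke and before the first return
below `rest_threshold` (−75 mV). A trace that never falls below
`rest_threshold` within `window_rest` (3 s) of the last stimulus is
`OSCILLATORY`; non-repolarization dominates any EAD count (tie-break).

The `ead_ceiling` bound exists because the normal AP morphology of this
model has a spike-notch-dome: the notch is a local minimum near +40 mV
followed by a several-mV rise, which the three-threshold rule alone
would miscount as an EAD. EAD take-off voltages sit in the plateau
band, well below the notch.

Phase diagrams (`sweep_phase_diagram`) classify one AP per grid point
(single stimulus, ≥ 4 s observation), sweeping `mult_CaL` against one
of `mult_Ks`, `mult_Kr`, `mult_NaCa`. Along increasing `mult_CaL` the
labels pass NORMAL → EAD → OSCILLATORY with no reverse transitions;
`PhaseDiagram.ordering_violations()` reports any violation rather than
silently accepting it.

### Reference operating points (`ead2d.regimes`)

* `OSC_POINT = (mult_CaL=7, mult_Ks=0.45)` — oscillatory regime. The
  single-cell oscillation period there is 166.7 ms (5.999 Hz measured
  over a 9 s developed window), matching the reported 6 Hz oscillation;
  the published multiplier values themselves are not available, so the
  point was located from this printed period.
* `EAD_POINT = (5, 0.6)` — inside the single-EAD region.
* `SFB_POINT = (2, 0.2)` — no-EAD (normal single-cell) region bordering
  the EAD region.

## 2D tissue

Isotropic monodomain sheet, dV/dt = D∇²V − (I_ion + I_stim)/C_m,
forward Euler, 5-point Laplacian. Coupling lives on *edges*: a boolean
conduction flag per nearest-neighbour pair. A missing or cut edge
contributes zero flux, which implements both the no-flux (Neumann)
domain boundary and internal barriers with one mechanism. Defaults
follow standard TP06 2D practice: dx = 0.25 mm, D = 0.00154 cm²/ms,
dt = 0.02 ms, 600 × 600 nodes (15 × 15 cm); the explicit-stability
bound dt ≤ dx²/(4D) is validated at configuration time.

Protocols:

* **P1** — one stimulus to a 6-node strip at the left edge (full edge
  height by default), producing a plane wave.
* **P2 (S1–S2)** — S1 as P1; S2 stimulates the lower-left quarter.
  S2 timing is event-driven: it fires at the first control interval
  after (i) the S1 front has crossed mid-domain and (ii) the S2 quarter
  has recovered below −70 mV. Condition (ii) places S2 just behind the
  receding waveback, where propagation into the still-refractory right
  half is blocked unidirectionally and a single spiral curls up. (A
  fixed "front crossed mid-domain" trigger alone would stimulate fully
  refractory tissue at realistic domain sizes and do nothing.)
* **paced** — the P1 strip re-stimulated periodically (period
  ≥ 300 ms) during a pacing epoch, then free run.

Barrier grids cut the coupling mask along a square lattice of pitch
`block` (default 40 nodes = 1 cm at the default dx); an alternative
`refractory` mode holds the lattice nodes depolarized by sustained
stimulation instead. Cell states are untouched by `mask` barriers.

Runs are bit-reproducible given a config; the frame stack records V and
the gate products m³hj (Na availability) and d·f·f2·fCass (L-type
openness) at `frame_interval`.

## Pattern analysis

* **Wave attribution.** Upstrokes are upward crossings of −30 mV at
  sampled nodes. An upstroke is Na-mediated iff the pre-upstroke
  voltage floor (since the previous beat) is below `na_floor` (−60 mV)
  *and* m³hj at the crossing exceeds 0.01; otherwise Ca-mediated. The
  SF_a/SF_b boundary is gradual, so the continuous `na_fraction` is
  always reported alongside the label.
* **Pseudo-ECG.** ECG(t) = Σ ∇V·∇(1/r) dA over the sheet, electrode
  2.5 mm above the domain centre; central-difference gradients. Exactly
  zero for uniform fields; equal to a brute-force double-loop oracle to
  1e-12 relative in the tests.
* **Spectra.** Per-node mean-removed periodograms summed over an even
  sublattice of 10 000 points (or all nodes if fewer), no window by
  default. Peaks must exceed 5× the median power and 1e-4 of the
  strongest line. Records shorter than 4 s raise a resolution error
  stating the achievable Δf. Initiation transients are excluded by a
  `t_start` argument when measuring developed-pattern frequencies.
* **Phase singularities.** Per-node phase by time-delay embedding,
  angle(V(t)−V*, V(t−τ)−V*) with τ = 50 ms and V* the per-node
  midrange; spiral tips are plaquettes with ±2π winding of the wrapped
  phase gradient, with quiescent plaquettes (local-in-time amplitude
  < 20 mV) excluded. Hilbert-transform phase would need the whole
  record in memory; the two-frame embedding is the standard
  optical-mapping practice and is O(1) in time samples.
* **Sustainment.** Activity is sustained if any node exceeds −70 mV
  beyond `last_stimulus + sustain_window + one domain crossing` (window
  3 s at full scale; scaled-down runs use shorter windows, stated with
  each experiment).
* **EADs in tissue traces** are detected with the single-cell rule but
  a 10 mV rise threshold: near spiral cores, electrotonic (diffusive)
  bumps of a few mV are not regenerative EADs.

### Pattern labels

Not sustained: `PLAIN_PROPAGATION` (no EADs anywhere),
`NO_SUSTAINED_EAD` (EADs occurred), `SELF_TERMINATED_SFa` (wave breakup
occurred — phase-singularity count persistently above the protocol's
baseline — then activity died). Sustained: `SINGLE_SPIRAL` (tail-median
singularity count of exactly 1, no EAD breaks), `OSC` (no Na-led
upstrokes, 95th-percentile node amplitude < 40 mV, and — when run — a
phase-wave barrier verdict), otherwise `SF_a` if `na_fraction < 0.2`
else `SF_b`. Conflicting evidence yields `UNCLASSIFIED` with the
evidence attached rather than a silent guess.

### Phase waves vs trigger waves

`phase_wave_test` continues a developed run with a barrier lattice
imposed. Trigger (diffusion-mediated) waves are absorbed: activity dies
or stays compartment-confined within the test window → `TRIGGER_WAVES`.
Phase waves are indifferent to barriers: the activity survives and the
spatial phase profile stays continuous across barrier lines (median
wrapped phase step across a cut < 3× the interior median) →
`PHASE_WAVES`. The same verdict operator runs on synthetic fixtures
(decoupled phase-gradient oscillator fields vs diffusive target waves),
where it separates the two classes on every tested seed.

## Synthetic fixtures

`synthetic_fixtures` generates analytic traces (normal, k-EAD,
oscillatory templates) and movies (plane waves, 1–n-core Archimedean
spirals, target waves, pure phase-gradient oscillations, seeded noise)
with gate-product channels synthesized consistently with their declared
Na/Ca truth. They exercise every analysis operator without the PDE
solver, and every fixture's truth label must round-trip through the
analysis pipeline exactly. What fixtures do **not** emulate:
restitution, electrotonic loading, meander, or any ionic realism beyond
the classifier rules — passing the fixture matrix shows the *operators*
implement their definitions, not that the PDE dynamics is correct
(that is what the scaled simulation checks are for).

## Scaled experiment sizes

Full-scale reproduction (600 × 600 nodes, 10 s) is hours of CPU per
run. The packaged checks use scaled domains chosen as the smallest
that exhibit each mechanism:

* plane-wave/CV properties: 12 × 250 strips, dx = 0.15–0.25 mm;
* plain propagation (P1, baseline): 60 × 60, dx = 0.5 mm, 1.5 s;
* single spiral (P2, baseline): 120 × 120, dx = 0.65 mm (7.8 cm),
  ≈ 2.2 s — the spiral wavelength of this model is several cm, so the
  domain cannot be shrunk much further without the tip reaching the
  boundary;
* EAD-regime P1 runs: 100 × 100, dx = 0.5 mm, ≈ 2.5 s;
* oscillatory regime: 50 × 50, dx = 0.5 mm, ≈ 5.5 s (the oscillation
  is a cell property; small patches suffice).

The methods' full-scale defaults remain those stated above; the scaled
sizes are the package's choice for its own verification experiments.

**Desk-scale limit of EAD wavebreak.** On sheets of ≤ 7.5 cm the
EAD-regime plane wave expresses the EAD as a *spatially synchronized*
prolonged plateau: the domain crossing time (70–110 ms) is far shorter
than the plateau (1–3 s), so electrotonic coupling keeps the whole
sheet in phase and the EAD never detaches from the waveback as a new
front. Wavebreak and the ensuing spiral-fibrillation states require the
full-scale domain (~15 cm, ~10 s), where chaotic EAD dynamics can
desynchronize regions faster than diffusion re-synchronizes them. The
corresponding scaled checks in the acceptance tests therefore fail by
construction at desk scale and are kept as explicit red markers of this
limit; the tissue-level EAD itself (voltage reversal during
repolarization behind the front) is demonstrated at desk scale.

## Known limitations

* Endocardial kinetics only; no epi/M-cell variants, no anisotropy,
  heterogeneity, bidomain electrics or 3D domains.
* The spiral-counting operator can transiently over-count during
  wavebreak or decay; classification therefore uses tail medians and
  persistence rules, not single frames.
* At desk-scale domain sizes the spiral-fibrillation states (SF_a,
  SF_b) do not develop at all — see "Desk-scale limit of EAD wavebreak"
  above; their classifiers are exercised on synthetic movies and their
  spectral signatures are full-scale quantities.
* Table-based gate kinetics introduce ≈ 1e-7 interpolation error per
  step; the dt- and table-refinement tests bound the practical effect
  (APD90 shifts < 1 ms).
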