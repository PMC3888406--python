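# ead2d — EAD-driven arrhythmia patterns in human ventricular tissue

Early afterdepolarizations (EADs) — depolarizing reversals of the
membrane voltage during the repolarizing phase of a cardiac action
potential — are a cellular arrhythmia mechanism associated with the
long-QT syndrome and drug cardiotoxicity. How single-cell EADs organize
into tissue-level fibrillation is a multiscale question. `ead2d`
implements the full pipeline for studying it in silico:

1. **Cell model** — the ten Tusscher–Panfilov 2006 (TP06) human
   ventricular model, endocardial variant, modified to reduce
   repolarization reserve: doubled L-type Ca conductance
   (G_CaL = 2 × 3.98·10⁻⁵ mm³·µF⁻¹·ms⁻¹) and a twofold-faster
   voltage inactivation of I_CaL (τ_f × 0.5). Multipliers on G_CaL,
   G_Ks, G_Kr and k_NaCa span the parameter space.
2. **Single-cell stage** — AP simulation, EAD detection and
   classification (NORMAL / EAD / OSCILLATORY), per-current
   decomposition at EAD onsets, and two-parameter phase diagrams.
3. **2D tissue stage** — isotropic monodomain sheet
   (dV/dt = D∇²V − I_ion/C_m, explicit Euler, 5-point Laplacian,
   no-flux boundaries), wave-initiation protocols P1 (plane wave),
   P2 (S1–S2 cross-field spiral) and periodic pacing, plus
   non-conducting barrier grids.
4. **Pattern analysis** — classification of the emergent activity into
   two spiral-fibrillation types (SF_a: small-amplitude,
   L-type-Ca-mediated waves; SF_b: with Na-mediated full-amplitude
   waves), an oscillatory phase-wave regime (Osc), and non-sustained
   outcomes; Na/Ca wave attribution, pseudo-ECGs
   (ECG = Σ ∇V·∇(1/r) dA), summed power spectra, interbeat intervals,
   phase-singularity counting, and a barrier test that discriminates
   phase waves from trigger waves.

A synthetic-fixtures module generates analytic traces and voltage/gate
movies with known ground truth so that every analysis operator is
testable without running the PDE solver.

## Worked example

Classify a single cell deep in the reduced-repolarization-reserve
region, then check what the same cell does on the phase diagram:

```python
>>> from ead2d import make_params
>>> from ead2d.single_cell import simulate_ap, classify_ap, detect_ead_drivers
>>> p = make_params(mult_CaL=5.0, mult_Ks=0.6)     # 5x I_CaL, 60% I_Ks
>>> tr = simulate_ap(p, record_currents=True)
>>> cls = classify_ap(tr)
>>> cls.label, cls.ead_count
('EAD', 5)
>>> detect_ead_drivers(tr)[0].dominant_inward
'i_CaL'
```

The EAD is carried by re-activation of the L-type Ca current. Sweeping
the (G_CaL, G_Ks) plane reproduces the ordered progression of AP
classes (output of `sweep_phase_diagram([1,2,3,4,5,6,7,8], "Ks",
[0.0,0.2,0.4,0.6,0.8,1.0])`, rows = `mult_Ks`, columns = `mult_CaL`):

```
        1      2      3      4      5      6      7      8
0.0: OSCILL OSCILL OSCILL OSCILL OSCILL OSCILL OSCILL OSCILL
0.2: NORMAL    EAD OSCILL OSCILL OSCILL OSCILL OSCILL OSCILL
0.4: NORMAL NORMAL    EAD OSCILL OSCILL OSCILL OSCILL OSCILL
0.6: NORMAL NORMAL NORMAL    EAD    EAD OSCILL OSCILL OSCILL
0.8: NORMAL NORMAL NORMAL NORMAL    EAD    EAD    EAD OSCILL
1.0: NORMAL NORMAL NORMAL NORMAL NORMAL NORMAL    EAD    EAD
```

Increasing the inward Ca current or blocking the slow delayed rectifier
moves the cell from normal APs through EADs to non-repolarizing
oscillations. At the oscillatory reference point
(`mult_CaL=7, mult_Ks=0.45`) the free-running oscillation has a period
of 166.7 ms — a 5.999 Hz dominant spectral peak.

2D runs go through a validated YAML config or the CLI:

```bash
ead2d run --set tissue.nx=100 --set tissue.ny=100 --set tissue.dx=0.5 \
          --set model.mult_CaL=7 --set model.mult_Ks=0.45 \
          --set tissue.duration=5000 --set out_dir=osc-run
ead2d analyze osc-run/frames.h5 --set out_dir=osc-analysis
```

which writes frames (HDF5), a config snapshot, a JSON pattern report
(label, Na-fraction, dominant frequencies, phase-singularity counts),
the pseudo-ECG and the summed power spectrum.

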