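# ktblast-tpm

In-silico evaluation of **k-t BLAST acceleration for tissue phase mapping
(TPM)** of myocardial motion.

TPM is phase-contrast cine MRI of the heart muscle: bipolar gradients give
each spin a phase proportional to its velocity, so a referenced 4-point
acquisition (one reference segment plus one velocity-encoded segment per
spatial direction, VENC = 30 cm/s) yields the full 3-directional myocardial
velocity field per cardiac phase. The price is a long scan. k-t BLAST
shortens it by sampling only every R-th phase-encode line per cardiac phase
on a sheared k-t lattice and resolving the resulting aliasing in x-f space
(space × temporal frequency) with a regularized filter whose signal prior
comes from a low-resolution, fully time-sampled training scan.

This package asks, entirely in simulation, the question a protocol designer
cares about: **how much does k-t acceleration at factors R = 2…7 distort the
quantitative radial and longitudinal myocardial velocity curves?** It is
aimed at MR physicists and image-analysis researchers who want a transparent,
fully seeded pipeline to study the trade-off, or a reference implementation
of the individual pieces.

## What is inside

| module | contents |
|---|---|
| `protocol` | timing arithmetic of the segmented, navigator-gated sequence (phase interval, heart phases, nominal scan times per R) |
| `phantom` | dynamic short-axis left-ventricle phantom: annular myocardium, black-blood pool, static background, smooth two-lobed periodic velocity waveforms, 4-point velocity encoding with a linear background-phase plane |
| `sampling` | centred unitary Fourier encoding, sheared k-t lattice undersampling, training-scan extraction, complex Gaussian k-space noise |
| `ktblast` | `KTBlastReconstructor` (scikit-learn style `fit`/`transform`): training-derived signal variance θ², alias-kernel calibration from the sampling mask's point-spread function, per-alias-set filter ŝ_b = θ²_b ā_b (Σ_j \|a_j\|² θ²_j + ψ)⁻¹ d with baseline protection |
| `quantify` | phase-difference velocity maps v = ∠(E·R̄)/π · VENC, static-tissue plane fit, mask-mean radial/longitudinal curves, periodic cubic-spline resampling, zero-integral shift, peak features (v_p,sys, v_p,dias, Δv, t_dias) |
| `metrics` | PF = Δv₂/Δv₁, nRMSD, Pearson c, Bland-Altman of Δv and t_dias, pooled two-sample t-tests, cohort tables |
| `experiment` / `cli` | seeded cohort runner (R sweep + no-acceleration reproducibility arm) and the `tpm-kt` command line |

## Worked example

```python
from ktblast_tpm import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=42, n_subjects=4, matrix=(64, 64),
                       R_list=(2, 4, 6), dt_ms=0.1)
res = run_experiment(cfg)
print(res.tables["pf"].round(3).to_string(index=False))
```

prints

```
 R metric    direction  mean    sd   p
no     pf       radial 0.999 0.005 NaN
no     pf longitudinal 1.000 0.001 NaN
 2     pf       radial 0.745 0.030 0.0
 2     pf longitudinal 0.736 0.046 0.0
 4     pf       radial 0.465 0.044 0.0
 4     pf longitudinal 0.485 0.063 0.0
 6     pf       radial 0.243 0.006 0.0
 6     pf longitudinal 0.226 0.022 0.0
```

Read this as: repeating the non-accelerated scan reproduces the systolic-to-
diastolic velocity range almost perfectly (PF ≈ 1), while k-t acceleration
attenuates the velocity peaks progressively (PF falls with R) — the
temporal-smoothing signature of the x-f filter. The corresponding `nrmsd`
table rises from ≈ 0.05 at R = 2 to ≈ 0.16 at R = 6, and `dt_dias` shows the
time to the diastolic peak staying within a few ms of the reference — the
timing of contraction survives acceleration far better than the amplitudes.

The protocol table alone (seconds of runtime):

```bash
$ tpm-kt protocol-table
kt_factor,heart_phases,scan_time_s
no,21,225.0
2,20,125.0
3,21,85.0
4,20,69.0
5,20,57.0
6,18,49.0
7,21,45.0
```

i.e. R = 2 gives a 1.8× speed-up (a scan-time reduction of just over 44 %),
with diminishing returns at higher R because the training-stage overhead is
constant.

The CLI also exposes the pipeline stage by stage (`tpm-kt simulate`,
`reconstruct`, `quantify`, `compare`, `run-all`); images travel as NIfTI
stacks with JSON sidecars, curves and tables as CSV.

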