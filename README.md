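# petiq

Desk-scale simulation of how activity-administration protocols and patient
habitus interact to set PET image quality in [⁶⁸Ga]Ga-DOTA-TOC imaging.

Neuroendocrine-tumour PET with ⁶⁸Ga-labelled somatostatin analogues is
usually performed with 100–200 MBq regardless of patient size, and larger
patients pay for it with noisier images: more 511 keV attenuation, and the
same injected activity diluted over more tissue.  `petiq` implements, end
to end and at laptop cost, the simulation chain needed to study this and
to derive a habitus-adapted prescription:

1. **Phantom cohort** — eight voxel code-image phantoms spanning BMI
   19–38 kg/m², with liver, spleen, kidneys, pancreas, stomach wall,
   bladder and lungs, plus eight liver tumours (0.15–8.09 mL) grown from
   seeds whose relative liver positions are shared across phantoms.
2. **Activity painting** — per-voxel activity from standardised uptake
   values, `A_vox = A_inj · SUV_vox · V_vox / w_T`, with ⁶⁸Ga physical
   decay (T½ = 67.71 min) over the 60 min uptake period.
3. **Acquisition + reconstruction** — attenuated parallel-beam forward
   projection, Poisson count sampling, a uniform scatter/randoms
   background, and OSEM (3 iterations × 16 subsets) with attenuation and
   background in the system model, post-filtered with a 5.5/4 mm FWHM
   Gaussian.
4. **Image quality metrics** — NEMA-style sphere SNR/CNR with 60
   background ROIs, liver SNR (`SNR_L = x̄_L/σ_L` in a spherical VOI) and
   tumour CNR (`CNR = (x̄_T − x̄_L)/σ_L`, Rose criterion at CNR ≥ 5).
5. **Protocol engine** — three prescriptions: (i) fixed 100 MBq,
   (ii) 2 MBq/kg, and (iii) a constant-SNR power law.  Arm (ii)'s liver
   SNRs are normalised, `SNR_Norm = SNR_L/√(A_inj·t)`, fitted against
   candidate body-size parameters (weight, BMI, BSA, abdominal
   circumference) with `SNR_Fit = a·p^(−d)`, and the best fit (by R²) is
   inverted into `A_inj = (1/t)·(SNR_Const²/a²)·p^(2d)`.

## Worked example

```python
from petiq import ExperimentConfig, prepare_experiment, run_experiment
import json

cfg = ExperimentConfig(seed=1)          # 8 phantoms, protocols i/ii/iii
ctx = prepare_experiment(cfg)
res = run_experiment(cfg, context=ctx)  # calibrates sensitivity, runs all arms
print(json.dumps(res.summary(), indent=1))
print(res.selected_fit)
```

Output from this exact run (seed 1):

```
{
 "i":   {"n_phantoms": 8, "median_snr": 10.30, "range_snr": 12.29, "n_rose": 61, ...}
 "ii":  {"n_phantoms": 8, "median_snr": 13.42, "range_snr": 7.62,  "n_rose": 63, ...}
 "iii": {"n_phantoms": 8, "median_snr": 14.99, "range_snr": 3.29,  "n_rose": 64, ...}
}
PowerLawFit(body_parameter='weight', a=102.2, d=1.155, r_squared=0.984, ...)
```

Reading it: with a fixed 100 MBq (arm i) the liver SNR collapses for the
heavy phantoms — the cohort spread (`range_snr`) is largest and three
tumours fall below the Rose criterion.  Weight-linear dosing (arm ii)
raises every SNR but leaves most of the spread.  The power-law fit picks
**weight** as the best body-size predictor (d ≈ 1.15), and prescribing by
it (arm iii) pins every phantom near the SNR target of 15: the spread
shrinks several-fold and all 64 tumours clear CNR ≥ 5.

A CLI mirrors the library: `petiq build-cohort`, `petiq paint`,
`petiq run-all --outdir out`, `petiq report --results out/results.csv`.

## Scope

The acquisition model is a deliberate stand-in for a full Monte Carlo +
clinical reconstruction chain: 2-D parallel-beam slices, no TOF, no
detector geometry, no deadtime/pile-up, scatter and randoms folded into a
single uniform background.  It preserves the two mechanisms the analysis
rests on — Poisson counting statistics and body-size-dependent
attenuation — and reproduces trends and calibrated levels, not absolute
scanner noise.  See `docs/methods.md` for the model, its assumptions, and
its limitations.
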