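# pentacardio

Signal-processing and machine-learning pipeline for a five-pad, starfish-style
wearable that records the heart's electrical and mechanical activity
simultaneously — ECG, seismocardiogram (SCG, chest acceleration) and
gyrocardiogram (GCG, chest rotation) — while the wearer moves.

The device geometry drives the whole pipeline: one sensing pad sits over the
heart and acquires cardiac mechanics, while four peripheral pads mostly record
body motion. `pentacardio` implements, end to end:

1. **Synthesis** — a ground-truth generator for five-pad trimodal recordings:
   ECG/SCG/GCG cardiac templates with annotated fiducials (P, Q, R, S, T;
   MC, AO, AC, MO; g_I..g_L), stride-locked motion artifacts per state
   (sitting / walking / jogging / running), pad mixing with known weights, and
   disease phenotypes (normal, A-Fib, MI, HF).
2. **Compensation** — "vector synthesis": the artifact reaching the
   acquisition pad is estimated per axis by ridge-regularized least squares on
   the 24 reference-pad channels and subtracted, leaving raw SCG/GCG.
3. **Motion recognition** — a transformer sequence classifier (implemented in
   numpy with explicit backprop and AdamW; decision-tree, random-forest and
   feed-forward baselines via scikit-learn) maps each 10-s segment to
   composite probabilities over the four motion states.
4. **Adaptive combination filtering** — one zero-phase band-pass + notch
   filter per motion state; the classifier's probabilities weight the filter
   *outputs*, `y = Σ_s p(s) · filter_s(x)`.
5. **Cardiac metrics** — Pan-Tompkins-style R detection, ECG-gated SCG/GCG
   fiducials, and beat-averaged timing metrics: HR, QT, SDRR, MC–MO, SDS1,
   g_I–g_L, SDg_J, and the electromechanical intervals
   EMD = Q→MC, PEP = Q→AO, LVET = AO→AC, PEP/LVET.
6. **Diagnosis** — four-class heart-condition classification from trimodal
   segments, with a paired modality-ablation harness (ECG / SCG / GCG alone
   vs combined).

## Worked example

```python
import pentacardio as pc
from pentacardio.fiducials import compute_metrics, detect_trimodal_fiducials

rec = pc.generate_recording(motion_schedule=[("running", 60.0)], seed=7)
compensated, model = pc.compensate(rec, calibration_interval=(0.0, 30.0))
fid = detect_trimodal_fiducials(compensated)
m = compute_metrics(fid)
print(m.hr, m.pep, m.lvet, m.pep_over_lvet)
```

Running `examples/04_cardiac_metrics.py` on a 60-s resting recording prints

```
HR 75.3 bpm | QT 289 ms | SDRR 43.9 ms
EMD 81 ms | PEP 121 ms | LVET 299 ms | PEP/LVET 0.404
```

i.e. a 75-bpm rhythm whose electromechanical delay (Q wave to mitral-valve
closure), pre-ejection period (Q to aortic-valve opening) and left-ventricular
ejection time are recovered within ~1–2 ms of the generator's ground truth.
Across the heart-rate presets 60→150 bpm the metrics reproduce the expected
exercise physiology — HR rises while QT, SDRR, EMD, PEP and PEP/LVET all fall
(same script):

```
sitting  HR  60.1  QT 324.9 ms  PEP 142.0 ms  PEP/LVET 0.424
running  HR 150.0  QT 206.1 ms  PEP  73.2 ms  PEP/LVET 0.341
```

`examples/02_compensate_artifacts.py` shows 14.3 dB artifact attenuation
during running and mixing-weight recovery (0.404, 0.318, 0.193, 0.111) against
the generator's (0.4, 0.3, 0.2, 0.1); the other examples cover motion
recognition + adaptive filtering and heart-condition diagnosis.

A thin CLI mirrors the library:

```bash
pentacardio simulate --seed 1 --out rec.csv --truth truth.json
pentacardio compensate --in rec.csv --calib 0:30 --out comp.csv --model model.json
pentacardio metrics --in comp.csv --out metrics.csv
```

## Layout

- `src/pentacardio/` — library (`synth`, `compensation`, `motion`,
  `filters`, `fiducials`, `diagnosis`, `nn`, `seqmodel`, `io`, `cli`, ...)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
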