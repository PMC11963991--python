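"""Extract trimodal fiducials and cardiac timing metrics.

Detects ECG R/Q/T peaks, ECG-gated SCG (MC/AO/AC/MO) and GCG (g_I..g_L)
fiducials on a resting recording, and prints the beat-averaged metrics:
heart rate, QT, RR variability, and the electromechanical intervals
EMD (Q->MC), PEP (Q->AO), LVET (AO->AC) with the PEP/LVET contractility
index.  Then repeats across heart-rate presets to show the exercise
trends: HR rises while QT, SDRR, EMD, PEP and PEP/LVET fall.
"""

import pentacardio as pc
from pentacardio.fiducials import compute_metrics, detect_trimodal_fiducials

rec = pc.generate_recording(motion_schedule=[("sitting", 60.0)], seed=3)
fid = detect_trimodal_fiducials(rec)
m = compute_metrics(fid)
print(f"beats detected: {fid.n_beats}")
print(f"HR {m.hr:.1f} bpm | QT {m.qt*1000:.0f} ms | SDRR {m.sdrr*1000:.1f} ms")
print(f"EMD {m.emd*1000:.0f} ms | PEP {m.pep*1000:.0f} ms | "
      f"LVET {m.lvet*1000:.0f} ms | PEP/LVET {m.pep_over_lvet:.3f}")

print("\nintensity sweep (heart-rate presets 60 -> 150 bpm):")
for state in pc.MOTION_STATES:
    r = pc.generate_recording(
        template=pc.template_for_state(state),
        motion_schedule=[("sitting", 60.0)], seed=3,
    )
    mm = compute_metrics(detect_trimodal_fiducials(r))
    print(f"  {state:8s} HR {mm.hr:5.1f}  QT {mm.qt*1000:5.1f} ms  "
          f"PEP {mm.pep*1000:5.1f} ms  PEP/LVET {mm.pep_over_lvet:.3f}")
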