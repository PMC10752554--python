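"""Model-recovery (confusion) analysis at two signal-to-noise levels.

Simulates data under each of the four recovery candidates — SSA(10) and
the three Bayesian-learning outputs at tau_t=20 — for a small cohort,
refits all candidates, bootstraps group model selection, and prints the
confusion matrices.  At high SNR the matrix is (near) identity; at low
SNR selection becomes biased toward specific competitors rather than
random.
"""

import numpy as np

import mmndyn as m
from mmndyn.recovery import confusion_metrics, default_recovery_candidates, run_recovery

sequences = [m.study1_sequence(seed=i) for i in range(8)]
candidates = default_recovery_candidates()
cells = [(4.5, 6.4), (0.45, 12.5)]  # excess SNR ~0.49 and ~0.0013

out = run_recovery(candidates, sequences, cells=cells, n_boot=200, seed=0)

for cell in cells:
    cm = out[cell]
    s = confusion_metrics(cm)
    amp, noise = cell
    print(f"\n(amplitude {amp} muV, noise {noise} muV; excess SNR {amp**2/noise**2:.4f})")
    print("rows = generating model, columns = selected model")
    header = "            " + "  ".join(f"{l:>8s}" for l in cm.labels)
    print(header)
    for label, row in zip(cm.labels, cm.entries):
        print(f"  {label:10s}" + "  ".join(f"{v:8.3f}" for v in row))
    print(f"  TPR {np.round(s.tpr, 2)}  "
          f"dist to identity {s.dist_identity:.2f}, to uniform {s.dist_uniform:.2f}")

print("\nhigh SNR: strongly diagonal; residual confusion only between the")
print("surprise and prediction-error outputs (r > 0.99; full samples of 28+")
print("subjects resolve it).  low SNR: mass drifts off-diagonal toward the")
print("surprise output — selection is biased (far from identity) but not")
print("random (still far from uniform).")
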