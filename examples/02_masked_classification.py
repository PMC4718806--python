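"""Focused classification of subtracted particles, scored on ground truth.

Runs the full benchmark at desk scale: 2 x 500 particles, box 32.  The
classifier holds every particle's orientation fixed at its ground-truth
value (mirroring a consensus refinement) and sorts the particles into two
classes using only the density inside the focus mask.  The printed accuracy
is the fraction of particles assigned to their generating class under the
best class-to-label matching.  (EM needs a few hundred particles per class
to estimate its references; far below that it cannot break symmetry.)
"""

from cryofocus.benchmark import run_two_class_benchmark

result = run_two_class_benchmark(
    seed=3, n_per_class=500, box=32, n_iter=12, subtract=True
)

print(f"class fractions: {result['fractions'].round(3)}")
print(f"accuracy vs ground truth: {result['accuracy']:.3f}")
# classification is coarse-to-fine; evidence values are comparable within
# the full-band stage, where they rise monotonically
full = [h for h in result["history"] if h["shell_limit"] == result["history"][-1]["shell_limit"]]
ev = [h["mean_log_evidence"] for h in full]
print(f"full-band mean log-evidence: {ev[0]:.1f} -> {ev[-1]:.1f}")
# Fractions near 0.5/0.5 reflect the balanced simulation; at this desk
# scale (box 32, calibrated low SNR) accuracy is ~0.7, rising to ~0.96 at
# the benchmark scale (box 64, 2x2000 particles).
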