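"""Simulate one synthetic subject and segment it into microstates.

Builds a ground truth calibrated to healthy-control group statistics,
synthesizes a 60-s eyes-closed recording, runs the 2–20 Hz prefilter,
clusters GFP-peak maps with polarity-invariant K-means, back-fits the
labeled templates and prints the temporal metrics next to the generative
expectations.
"""

import numpy as np

from easleep import (
    assign_canonical_labels,
    backfit_peaks,
    compute_gfp,
    compute_metrics,
    default_truth,
    find_gfp_peaks,
    microstate_prefilter,
    modified_kmeans,
    simulate_state_sequence,
    synthesize_recording,
)

truth = default_truth("hc", snr=2.0, seed=0)
rng = np.random.default_rng(0)
seq = simulate_state_sequence(truth, duration_s=60, rate=256, rng=rng)
rec = synthesize_recording(truth, seq, rate=256, rng=rng)
print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples at {rec.rate:g} Hz")

ms = microstate_prefilter(rec)
gfp = compute_gfp(ms)
peaks = find_gfp_peaks(gfp, ms.rate, min_distance_ms=10.0)
print(f"GFP peaks: {peaks.size} ({peaks.size / ms.duration_s:.1f}/s)")

res = modified_kmeans(ms.data[:, peaks].T, k=4, restarts=100, seed=1,
                      weights=gfp[peaks], channel_names=ms.channel_names)
labeled, match = assign_canonical_labels(res.templates, truth.templates)
print("template recovery |r| per class:",
      {k: round(v, 3) for k, v in match.items()}, f"(GEV {res.gev:.3f})")

metrics = compute_metrics(backfit_peaks(ms, labeled))
expected = truth.expected_metrics()
print(f"\n{'class':>5} {'dur ms (truth)':>16} {'occ /s (truth)':>16} {'cov % (truth)':>15}")
for i, c in enumerate(metrics.labels):
    print(f"{c:>5} {metrics.duration[i]:7.1f} ({expected['duration'][i]:5.1f})"
          f" {metrics.occurrence[i]:8.2f} ({expected['occurrence'][i]:4.2f})"
          f" {metrics.coverage[i]:8.1f} ({expected['coverage'][i]:5.1f})")
print("\nEach row compares one subject's recovered duration/occurrence/coverage "
      "with the generative expectation; they agree to within sampling noise.")
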