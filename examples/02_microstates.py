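"""Recover planted microstate maps with T-AAHC and backfit them.

Four orthogonal topographies alternate with 80 ms mean dwell at 20 dB SNR.
Clustering the GFP-peak maps recovers the planted templates almost exactly,
the meta-criterion picks the right number of maps, and backfitting plus
temporal smoothing yields the classic per-class parameters.
"""

import numpy as np

import preictal as p

rng = np.random.default_rng(0)
planted = p.make_templates(19, 4, rng=rng)
spec = p.SyntheticSpec(seed=0, snr_db=20.0, oscillations=(), templates=planted)
labels, _ = p.simulate_sequence(spec, 120.0)
rec = p.render_eeg(labels, spec)

gfp = p.compute_gfp(rec.data)
peaks = p.find_gfp_peaks(gfp)
print(f"{peaks.size} GFP peaks in {rec.duration_s:g} s "
      f"({peaks.size / rec.duration_s:.1f}/s)")

maps = rec.data[:, peaks].T
keep = np.sort(rng.choice(maps.shape[0], 2000, replace=False))
templates = p.taahc_cluster(maps[keep], 4)
print(f"T-AAHC GEV with 4 maps: {templates.gev:.3f}")

best_k, scores = p.select_optimal_k(maps[keep], k_range=(3, 8))
print(f"meta-criterion selects k = {best_k} (planted: 4)")

match = [max(p.spatial_correlation(t, q)[1] for q in planted)
         for t in templates.maps]
print("matched template |r|:", ", ".join(f"{r:.3f}" for r in match),
      " (1 = perfect recovery)")

seq = p.backfit(templates, rec.data, sample_rate=spec.sample_rate)
raw = p.microstate_parameters(seq)
print(f"\nunsmoothed mean dwell: "
      f"{np.mean(raw.mean_duration_ms):.1f} ms (planted: 80 ms)")

smoothed = p.smooth_sequence(seq, min_duration_ms=32.0)
params = p.microstate_parameters(smoothed)
print("per-class parameters after 32 ms smoothing (absorbing sub-threshold "
      "runs inflates durations):")
print(params.to_frame().round(3).to_string(index=False))
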