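"""From one recording to its connectivity matrix and scalar features.

A 6-channel recording with known correlation structure (off-diagonal mean
0.30, SD 0.10) is simulated with 60 Hz line noise, slow drift and spike
artifacts, then cleaned (band-pass 5-50 Hz, z-score, clip at +/-5 SD) and
summarised: three 90 s interictal segments give three Pearson matrices whose
average yields the patient's (mean, SD) feature pair.  The printed estimates
should sit within a few 0.01 of the generating values.
"""

import numpy as np

from seegconn import (
    ArtifactSpec,
    SegmentWindow,
    average_matrices,
    offdiagonal_features,
    pearson_matrix,
    preprocess_segment,
    sample_target_correlation,
    simulate_recording,
)

rng = np.random.default_rng(42)
target = sample_target_correlation(6, target_mean=0.30, target_sd=0.10, rng=rng)
recording = simulate_recording(
    target,
    sampling_rate=200.0,
    duration=270.0,
    artifacts=ArtifactSpec(),  # 60 Hz mains, drift, spike transients
    region_labels=["HH", "HT", "A", "STG", "MTG", "TP"],
    rng=rng,
)

step = int(90.0 * recording.sampling_rate)
matrices = []
for k in range(3):
    window = SegmentWindow(k * step, (k + 1) * step)
    clean = preprocess_segment(recording, window)
    matrices.append(pearson_matrix(clean, recording.contact_ids))

average = average_matrices(matrices)
est_mean, est_sd = offdiagonal_features(average)
true_mean, true_sd = target.realized_stats()

print("averaged connectivity matrix (3 segments of 90 s):")
print(average.to_frame().round(3).to_string())
print(f"\noff-diagonal mean: estimated {est_mean:.3f}  vs  generated {true_mean:.3f}")
print(f"off-diagonal SD:   estimated {est_sd:.3f}  vs  generated {true_sd:.3f}")
print(
    "\nDespite 2x-signal-SD line noise and injected spikes, the cleaned "
    "segments recover\nthe generating correlation statistics to within "
    "sampling error."
)
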