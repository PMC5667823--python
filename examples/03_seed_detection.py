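"""Detect nuclei seed points with the LoG variants and compare them.

Runs strict-maximum (LoGSM), non-strict (LoGNSM) and fusion (LoGNSM+F)
detection on a simulated image and scores each against the ground-truth
centroids.
"""

from fuzzpipe import (
    AcquisitionConfig,
    DynamicsConfig,
    benchmark_seed_config,
    detect_seeds,
    detection_scores,
    simulate_dataset,
)

ds = simulate_dataset(
    DynamicsConfig(n_initial=60, n_frames=1),
    AcquisitionConfig(),
    grid_shape=(48, 192, 192),
    seed=7,
)
img = ds.images[0][0]
gt = ds.ground_truth.centroids[["x", "y", "z"]].to_numpy()
cfg = benchmark_seed_config()

print(f"{'method':12s} {'n':>5s} {'recall':>7s} {'prec':>6s} {'F':>6s}")
for method in ("logsm", "lognsm", "lognsm+f", "lognsm+f+u"):
    tab = detect_seeds(img, cfg, method=method)
    s = detection_scores(tab[["x", "y", "z"]].to_numpy(), gt, max_dist=cfg.r_min)
    print(f"{method:12s} {len(tab):5d} {s.recall:7.3f} {s.precision:6.3f} {s.f_score:6.3f}")

print(
    "\nNon-strict extrema recover plateau nuclei missed by strict maxima;\n"
    "Ward fusion removes the redundant detections this creates, and the\n"
    "+U variant attaches an FSMD to every seed for downstream operators."
)
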