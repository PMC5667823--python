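"""Uncertainty-guided segmentation: split only what the FSMDs flag.

Compares plain Otsu components against OTSUWW+U, which watershed-splits
only components flagged as larger than expected and removes under-sized
low-FSMD fragments.
"""

from fuzzpipe import (
    AcquisitionConfig,
    DynamicsConfig,
    OperatorThresholds,
    SegmentationConfig,
    benchmark_seed_config,
    detect_seeds,
    segment_stack,
    segmentation_scores,
    simulate_dataset,
    size_fuzzy_sets,
)

ds = simulate_dataset(
    DynamicsConfig(n_initial=80, n_frames=1),
    AcquisitionConfig(),
    grid_shape=(48, 192, 192),
    seed=3,
)
img = ds.images[0][0]
gt_labels = ds.ground_truth.labels[0]

seed_tab = detect_seeds(img, benchmark_seed_config())
sets = size_fuzzy_sets(ds.ground_truth.centroids)  # quantile-fitted trapezoids
cfg = SegmentationConfig(thresholds=OperatorThresholds(alpha=0.1, beta=0.5), sets=sets)

for method in ("otsu", "otsuww+u"):
    labels, records = segment_stack(img, seed_tab, cfg, method=method)
    s = segmentation_scores(labels, gt_labels)
    print(
        f"{method:9s}: {len(records):3d} objects | merged={s.merged:3d} "
        f"split={s.split:2d} added={s.added:2d} missing={s.missing:2d} "
        f"| precision={s.precision:.3f} recall={s.recall:.3f}"
    )

print(
    "\nThe guided variant only crops and splits the flagged components, so\n"
    "under-segmentations disappear without paying for a global watershed."
)
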