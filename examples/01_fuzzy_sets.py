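"""Encode prior knowledge about nucleus size as trapezoidal fuzzy sets.

Builds the reference size trapezoids (volume, width, height, depth),
evaluates a few candidate objects and combines the per-feature
memberships with the minimum t-norm into one FSMD per object.
"""

import pandas as pd

from fuzzpipe import FuzzySet, TrapezoidParams, append_fsmd

sets = [
    FuzzySet("correct", TrapezoidParams(449, 617, 1405, 2016), "volume"),
    FuzzySet("correct", TrapezoidParams(13, 15, 24, 31), "width"),
    FuzzySet("correct", TrapezoidParams(13, 15, 24, 34), "height"),
    FuzzySet("correct", TrapezoidParams(3, 5, 8, 11), "depth"),
]

objects = pd.DataFrame(
    {
        "id": [1, 2, 3, 4],
        "volume": [990.0, 533.0, 3000.0, 100.0],
        "width": [20.0, 20.0, 40.0, 4.0],
        "height": [20.0, 20.0, 40.0, 4.0],
        "depth": [6.0, 6.0, 14.0, 2.0],
    }
)

scored = append_fsmd(objects, sets, kind="minimum")
print(scored[["id", "volume", "fsmd_correct"]].to_string(index=False))
print()
print(
    "FSMD 1.0 marks a typical nucleus, 0.5 a borderline one on the rising\n"
    "volume edge, and 0.0 objects far too large or too small to be valid."
)
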