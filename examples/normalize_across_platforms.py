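"""Subset quantile normalization across two array platforms.

Two platforms measure the same samples with a global scale/offset
difference; normalizing both against the common-feature reference makes
their common features comparable while non-common features follow their
relationship to the subset.
"""

import numpy as np
import pandas as pd

from miratlas import build_reference, normalize_matrix
from miratlas.ingest import SampleMatrix

rng = np.random.default_rng(5)
truth = rng.uniform(5, 12, size=80)


def platform(bias_scale, bias_shift, prefix):
    vals = bias_scale * truth[None, :] + bias_shift + rng.normal(0, 0.1, (12, 80))
    idx = [f"{prefix}{i}" for i in range(12)]
    meta = pd.DataFrame({"label": "cellA", "platform_version": prefix,
                         "batch_id": prefix}, index=idx)
    return SampleMatrix(
        pd.DataFrame(vals, index=idx, columns=[f"g{j:03d}" for j in range(80)]),
        meta,
    )


p1, p2 = platform(1.0, 0.0, "a"), platform(1.3, 2.0, "b")
subset = [f"g{j:03d}" for j in range(50)]  # features shared by both versions

before = np.abs(p1.values.mean() - p2.values.mean()).mean()
ref = build_reference([p1, p2], subset)
n1, n2 = normalize_matrix(p1, ref), normalize_matrix(p2, ref)
after = np.abs(n1.values.mean() - n2.values.mean()).mean()

print(f"mean between-platform difference before: {before:.3f} log2 units")
print(f"mean between-platform difference after:  {after:.3f} log2 units")
print(f"shrinkage: {100 * (1 - after / before):.1f}%")
print()
print("Each sample's common-feature distribution is mapped onto the pooled")
print("reference, so systematic platform offsets vanish; residual")
print("differences reflect only measurement noise.")
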