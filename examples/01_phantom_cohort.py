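"""Generate a small synthetic phantom cohort and inspect its ground truth.

Writes NIfTI volumes + masks + a TSV manifest to ./scratch_cohort, then
shows how the bag label relates to the instance-level labels derived from
the lesion mask (the MIL "positive iff any positive instance" rule).
"""

import numpy as np

from habmil import generate_cohort, generate_phantom, instance_ground_truth
from habmil.phantoms import sample_cohort_specs

manifest = generate_cohort(3, 3, "scratch_cohort", grid_shape=(32, 32, 32), seed=7)
print(manifest[["subject_id", "label"]].to_string(index=False))

specs = sample_cohort_specs(3, 3, grid_shape=(32, 32, 32), seed=7)
for spec, label in specs[:3]:
    _, mask, bag = generate_phantom(spec)
    y = instance_ground_truth(mask, (4, 4, 4))
    print(
        f"{spec.subject_id}: {len(spec.lesions)} lesion(s), bag label {bag}, "
        f"{int(y.sum())}/64 positive instances (max y_i = {int(y.max(initial=0))})"
    )
# The bag label always equals 1{any instance is positive}: lesion-free or
# distractor-only subjects have label 0 and an all-zero instance vector.
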