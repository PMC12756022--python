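"""Key patches and Grad-CAM on a trained phantom model (about a minute).

Trains briefly on a small presence cohort, then renders, for one positive
held-out subject, the top attention patches and the Grad-CAM saliency
volume, and reports whether they land on the true lesion.
"""

import pandas as pd

from habmil import HABMIL, ModelConfig, gradcam3d, key_patches, render_report, train
from habmil.interpret import saliency_enrichment
from habmil.phantoms import instance_ground_truth, sample_cohort_specs
from habmil.training import cohort_from_specs, desk_train_config
from habmil.volumes import make_splits

subjects = cohort_from_specs(sample_cohort_specs(16, 16, seed=2))
ids = pd.DataFrame({"subject_id": [s.subject_id for s in subjects]})
plan = make_splits(ids, seed=2, k_folds=2)
by = {s.subject_id: s for s in subjects}
model = HABMIL(ModelConfig(), seed=2)
result = train(model, [by[s] for s in plan.subjects("train")],
               [by[s] for s in plan.subjects("val")],
               desk_train_config(epochs=6, seed=2))

positive = next(by[s] for s in plan.subjects("test") if by[s].label == 1)
patches = key_patches(result.model, positive.volume, k=3)
y = instance_ground_truth(
    positive.mask, model.config.encoder.target_instance_grid,
    model.encoder.instance_cell_edges(positive.volume.shape[1:]),
)
for p in patches:
    on = "lesion" if y[p.instance_index] else "background"
    print(f"instance {p.instance_index}: weight {p.weight:.3f} -> {on} cell")

sal = gradcam3d(result.model, positive.volume, subject_id=positive.subject_id)
stats = saliency_enrichment(sal, positive.mask)
print(f"saliency mass in lesion {stats['mass_in_lesion']:.2f} vs volume "
      f"fraction {stats['lesion_volume_fraction']:.2f} "
      f"(enrichment {stats['enrichment']:.1f}x)")
render_report(positive.volume, sal, patches, "scratch_panels",
              subject_id=positive.subject_id, mask=positive.mask)
print("panels written to scratch_panels/")
# Enrichment > 1 means the saliency concentrates on the lesion beyond its
# share of the volume; the top patch should be a lesion-overlapping cell.
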