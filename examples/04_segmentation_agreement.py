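"""Segmentation-agreement metrics on a constructed prediction.

Takes a synthetic EPVS mask as ground truth, degrades it (drops some
lesions, trims voxels, adds a spurious blob) and reports voxel-level and
lesion-level agreement.  Lesion-wise Dice only asks whether each lesion
was touched at all, so it is more forgiving than voxel metrics for small
structures.
"""

import numpy as np

from pvspatial import evaluate_pair
from pvspatial.grid import VoxelGrid3D
from pvspatial.morphology import connected_components
from pvspatial.synthetic import GroupConfig, SimulationConfig, simulate_subject

cfg = SimulationConfig(groups=[GroupConfig("demo", 1)], grid_shape=(64, 64, 64))
rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((1, 0))))
truth = simulate_subject(cfg, cfg.groups[0], rng, "t").epvs

pred_arr = truth.values.copy()
for comp in connected_components(truth)[::5]:  # miss every fifth lesion
    pred_arr[tuple(comp.voxel_indices.T)] = 0
erode = rng.random(pred_arr.shape) < 0.15  # trim 15% of voxels
pred_arr = (pred_arr.astype(bool) & ~erode).astype(np.uint8)
pred_arr[5:7, 5:7, 5:7] = 1  # spurious blob
pred = VoxelGrid3D(pred_arr, truth.spacing_mm)

r = evaluate_pair(pred, truth)
print(f"pred lesions {r.n_pred_lesions}, truth lesions {r.n_truth_lesions}")
print(f"precision      {r.precision:.3f}")
print(f"recall         {r.recall:.3f}")
print(f"overall Dice   {r.overall_dice:.3f}")
print(f"voxel-wise Dice  {r.voxelwise_dice:.3f}  (mean per-lesion Dice)")
print(f"lesion-wise Dice {r.lesionwise_dice:.3f}  (2TP/(2TP+FP+FN) over lesion identities)")
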