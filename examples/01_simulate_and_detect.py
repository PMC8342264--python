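"""Render a synthetic block-face stack and detect the microspheres in it.

Builds a toy atlas, scatters 120 fluorescent 20-um beads through it,
renders the serial block-face images (beads shine through up to 400 um of
tissue), then runs threshold -> serial subtraction -> centroid extraction
and compares the detections with the ground truth.
"""

import numpy as np

from embolocate import synthetic_data as sd
from embolocate.pipeline import detect_microspheres

ontology, annotation = sd.generate_toy_atlas(
    depth=5, branching=2, shape=(32, 32, 32), voxel_size_um=100.0, seed=1
)
scene = sd.generate_scene(ontology, annotation, n_spheres=120, seed=2)
res = sd.render_blockface_stack(scene, annotation, sd.RenderSpec(seed=3))
print(f"rendered {res.stack.n_sections} sections of "
      f"{res.stack.frame_shape[1]}x{res.stack.frame_shape[0]} px "
      f"({res.stack.pixel_size_um} um/px, {res.stack.section_thickness_um} um thick)")

detections, _ = detect_microspheres(res.stack)
print(f"detected {len(detections)} microspheres (ground truth: {scene.n_spheres})")

# each bead should surface in its true section, centroid within a pixel
hits = 0
for _, t in res.truth.iterrows():
    cand = detections[detections["section_index"] == t.section_index]
    if len(cand) and np.hypot(cand["x_px"] - t.x_px, cand["y_px"] - t.y_px).min() <= 1.0:
        hits += 1
print(f"{hits}/{scene.n_spheres} beads recovered in the correct section "
      "with centroid error <= 1 px")
# the count equality and per-bead hits show the last-detection rule is
# resolving each bead's z-plane, not just finding bright blobs
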