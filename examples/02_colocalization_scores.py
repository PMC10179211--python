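"""Score per-vesicle colocalization and show what region masks change.

A dual-stained (PC) vesicle carries both content markers, so its two lumen
channels correlate strongly; a singly stained vesicle does not. With a
region mask the score only sees the vesicle's own pixels, so a bright
neighbour in the window cannot move it.
"""

import numpy as np

from guvcolocal.colocalization import ColocParams, default_window_width, score_objects
from guvcolocal.io import FieldOfView
from guvcolocal.segmentation import SegmentationParams, segment_field
from guvcolocal.synthesis import SceneSpec, default_content_exchange_layout, render_scene

channels, amounts = default_content_exchange_layout()
spec = SceneSpec(
    image_shape=(512, 512),
    n_vesicles=30,
    fractions={"P1": 0.4, "P2": 0.3, "PC": 0.3},
    min_gap_px=10.0,
    seed=11,
)
scene = render_scene(spec, channels, amounts)
field = FieldOfView(0, (0, 0), scene.channels, spec.pixel_size)
lipid_map, content_map, records, _ = segment_field(field, channels, SegmentationParams())

width = default_window_width(records, spec.pixel_size)
for mode in ("none", "both"):
    params = ColocParams(window_width_px=width, mask_mode=mode, method="pearson")
    scores = score_objects(
        records, [field], {0: lipid_map}, {0: content_map}, [("dexA", "dexB")], params
    )
    # attach the true population via nearest ground-truth center
    gt = scene.truth
    d = np.hypot(
        records["centroid_row"].to_numpy()[:, None] - gt["center_row"].to_numpy()[None, :],
        records["centroid_col"].to_numpy()[:, None] - gt["center_col"].to_numpy()[None, :],
    )
    pop = gt["population"].to_numpy()[d.argmin(axis=1)]
    vals = scores["value"].to_numpy()
    print(f"mask={mode:4s} window={width}px  "
          f"PC median r={np.median(vals[pop == 'PC']):+.3f}  "
          f"single-positive median r={np.median(vals[pop != 'PC']):+.3f}")
# dual-stained vesicles score near +1 (both markers fill the same lumen);
# singly stained ones score near 0 without masks and lower with masks,
# which is exactly the separation the exchange threshold exploits.
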