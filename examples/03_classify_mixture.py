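"""Quantify the dual-stained fraction of a mixed sample end to end.

Renders a small M3-like mixture (P1:P2:PC at 1:1:0.1 by volume), detects
and measures the vesicles, places automatic antimode thresholds on the two
content channels, classifies, and compares the double-positive percentage
with the generative fraction.
"""

from guvcolocal.colocalization import estimate_background, subtract_background_records
from guvcolocal.population import classify
from guvcolocal.segmentation import SegmentationParams
from guvcolocal.synthesis import MIXTURE_RATIOS, SceneSpec, default_content_exchange_layout, mixture_fractions
from guvcolocal.validation import fluorescence_thresholds, process_sample, render_sample

channels, amounts = default_content_exchange_layout()
roles = {c.channel_id: c.role for c in channels}
fractions = mixture_fractions(MIXTURE_RATIOS["M3"])
spec = SceneSpec(n_vesicles=125, fractions=fractions, min_gap_px=8.0, seed=21)

fields, truth = render_sample(spec, 3, channels, amounts)
records, _, _ = process_sample(fields, channels, SegmentationParams())
background = estimate_background(records, channels)
corrected = subtract_background_records(records, background)
thresholds = fluorescence_thresholds(corrected, ("dexA", "dexB"), roles)
labels = classify(corrected, thresholds, ("dexA", "dexB"), roles)

dp = 100.0 * (labels["population"] == "DP").mean()
true_dp = 100.0 * (truth["population"] == "PC").mean()
print(f"detected {len(records)} of {len(truth)} vesicles")
print(f"thresholds: dexA {thresholds.channel_thresholds['dexA']:.3f}, "
      f"dexB {thresholds.channel_thresholds['dexB']:.3f} (antimode, mixed sample)")
print(f"double-positive: {dp:.2f}%   generative PC fraction: {true_dp:.2f}%")
# the DP percentage is the fusion-product readout; agreement with the
# generative fraction within ~1 point at this sample size shows the
# threshold placement introduces no systematic bias.
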