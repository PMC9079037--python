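"""Evaluate a (mock) keypoint detector with the COCO OKS metrics.

A seeded noise model stands in for a trained pose network: ground-truth
landmarks are jittered, sometimes dropped, and spurious detections are
added.  Detection quality is summarized by AP (mean average precision over
OKS thresholds 0.50:0.05:0.95), AP75 and AR, exactly as keypoint detectors
are benchmarked.
"""

import numpy as np

from neotherm import DetectorNoiseConfig, PhantomConfig, evaluate_ap_ar
from neotherm.keypoints import mock_detect
from neotherm.phantom import generate_phantom_pair, sample_true_map

rng = np.random.default_rng(0)
gts, dets = [], []
for k in range(10):
    cfg = PhantomConfig(rgb_size=(960, 600), irt_size=(512, 384),
                        figure_scale_px=500.0,
                        true_map=sample_true_map(rng, (960, 600)),
                        seed=int(rng.integers(2**31)))
    _, truth = generate_phantom_pair(cfg)
    noise = DetectorNoiseConfig(coord_sd=6.0, dropout_prob=0.1,
                                false_positive_rate=0.5,
                                seed=int(rng.integers(2**31)))
    dets.append(mock_detect(truth.kps_rgb, noise, frame_size=(960, 600)))
    gts.append(truth.kps_rgb)

metrics = evaluate_ap_ar(gts, dets)
print(f"frames: {len(gts)}, detector jitter 6 px, dropout 10%")
print(f"AP    {metrics['AP']:6.1f}   (mean over OKS thresholds .50:.05:.95, x100)")
print(f"AP75  {metrics['AP75']:6.1f}   (single threshold 0.75)")
print(f"AR    {metrics['AR']:6.1f}   (mean recall over thresholds)")
# higher jitter or dropout lowers AP/AR; a perfect detector scores 100/100/100.
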