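"""Pixel-wise SVM segmentation of tumor nests vs stroma, self-trained on
400 labeled pixels per class, scored by Dice overlap with ground truth."""

import numpy as np

from nestquant.preprocessing import preprocess
from nestquant.synthetic import ImageScenario, generate_he_image, generate_labeled_pixels
from nestquant.tissue import classify_pixels, postprocess_mask, train_from_labeled_pixels

image, truth = generate_he_image(ImageScenario(seed=11))
pre = preprocess(image)

sample = generate_labeled_pixels(image, truth, n_per_class=400, seed=11)
clf = train_from_labeled_pixels(pre, sample, seed=0)
print(f"SVM training accuracy on 800 labeled pixels: {clf.training_accuracy:.3f}")

raw = classify_pixels(pre, clf)
mask = postprocess_mask(raw)  # closing r=3 + drop regions < 500 px^2

gt = truth.nest_mask > 0
dice = 2 * np.logical_and(mask > 0, gt).sum() / ((mask > 0).sum() + gt.sum())
print(f"nest/stroma Dice before postprocessing: "
      f"{2 * np.logical_and(raw > 0, gt).sum() / ((raw > 0).sum() + gt.sum()):.3f}")
print(f"nest/stroma Dice after postprocessing:  {dice:.3f}")
# Dice near 1 means the 15 per-pixel features (local homogeneity, raw
# color, LBP texture) separate the two tissue compartments cleanly.
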