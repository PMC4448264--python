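"""Preprocess a synthetic HE frame and unmix it into hematoxylin and eosin
optical densities via Beer-Lambert color deconvolution."""

import numpy as np

from nestquant.preprocessing import color_deconvolve, preprocess
from nestquant.synthetic import ImageScenario, generate_he_image

image, truth = generate_he_image(ImageScenario(seed=3))
pre = preprocess(image)  # 3x3 median + (1, 99) percentile contrast stretch
stains = color_deconvolve(pre)

nuclei = truth.nuclei_mask > 0
print("mean hematoxylin OD inside nuclei: ", round(stains.hematoxylin_od[nuclei].mean(), 3))
print("mean hematoxylin OD outside nuclei:", round(stains.hematoxylin_od[~nuclei].mean(), 3))
print("mean eosin OD in stroma:           ", round(stains.eosin_od[truth.nest_mask == 0].mean(), 3))
# A large nuclei/background hematoxylin contrast is what makes the
# downstream Otsu threshold + watershed segmentation work.
ratio = stains.hematoxylin_od[nuclei].mean() / stains.hematoxylin_od[~nuclei].mean()
print(f"nuclei-to-background hematoxylin contrast: {ratio:.1f}x")
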