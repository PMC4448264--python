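"""Shared fixtures: one default synthetic field taken through the full
image-analysis chain, reused by the feature / classification tests."""

import numpy as np
import pytest

from nestquant import cells, features, nuclei, preprocessing, synthetic, tissue


@pytest.fixture(scope="session")
def default_field():
    """A default-scenario synthetic HE field with ground truth."""
    scen = synthetic.ImageScenario(seed=11)
    image, truth = synthetic.generate_he_image(scen)
    return scen, image, truth


@pytest.fixture(scope="session")
def segmented_field(default_field):
    """The default field taken through preprocessing, nuclei segmentation,
    self-trained tissue segmentation and nucleus classification."""
    scen, image, truth = default_field
    pre = preprocessing.preprocess(image)
    stains = preprocessing.color_deconvolve(pre)
    nuclei_labels, nucleus_objs = nuclei.segment_nuclei(stains.hematoxylin_od)
    sample = synthetic.generate_labeled_pixels(image, truth, 400, seed=11)
    clf = tissue.train_from_labeled_pixels(pre, sample, seed=0)
    tissue_mask = tissue.postprocess_mask(tissue.classify_pixels(pre, clf))
    classified = cells.classify_nuclei(nucleus_objs, tissue_mask)
    nests = features.tumor_nests(tissue_mask, stains.hematoxylin_od)
    return {
        "scenario": scen,
        "image": image,
        "truth": truth,
        "preprocessed": pre,
        "stains": stains,
        "nuclei_labels": nuclei_labels,
        "nucleus_objs": nucleus_objs,
        "classifier": clf,
        "tissue_mask": tissue_mask,
        "classified": classified,
        "nests": nests,
    }


@pytest.fixture(scope="session")
def catalog_vector(segmented_field):
    """The full 730-entry feature vector of the default field."""
    s = segmented_field
    return features.extract_catalog(
        s["preprocessed"], s["tissue_mask"], s["nuclei_labels"], s["classified"], s["nests"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
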