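import logging

import numpy as np
import pytest

import histopatch as hp

logging.getLogger("histopatch").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_params():
    return hp.SynthParams(seed=0)


@pytest.fixture(scope="session")
def tumor_slide(default_params):
    """One positive slide: (SlideImage, mask, label)."""
    return hp.make_slide(default_params)


@pytest.fixture(scope="session")
def normal_slide():
    import dataclasses

    params = dataclasses.replace(hp.SynthParams(seed=0), tumor_fraction=0.0)
    return hp.make_slide(params)


@pytest.fixture(scope="session")
def reference_ext():
    return hp.reference_extractor()


@pytest.fixture(scope="session")
def small_binary_dataset():
    """12 labeled slides (6 per class) with precomputed pooled features."""
    recs = hp.make_classification_dataset(6, hp.SynthParams(seed=0))
    ext = hp.reference_extractor()
    cfg = hp.TilingConfig()
    feats = np.vstack([hp.image_feature(r["image"], ext, cfg) for r in recs])
    labels = np.array([r["label"] for r in recs])
    return recs, feats, labels
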