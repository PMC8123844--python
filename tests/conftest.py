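import numpy as np
import pytest

import nucleoprofile as npf


@pytest.fixture(scope="session")
def t2_nucleus():
    """One clean control T2 nucleus with its ground truth."""
    spec = npf.default_spec("T2")
    return npf.generate_nucleus(spec, nucleus_id=0, seed=100)


@pytest.fixture(scope="session")
def t2_analysis(t2_nucleus):
    image, _ = t2_nucleus
    nucleus = npf.segment_nucleus(image)
    nucleolus = npf.segment_nucleolus(image, nucleus)
    fociset = npf.detect_foci(image, nucleus, nucleolus_mask=nucleolus)
    return image, nucleus, nucleolus, fociset


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 1.0
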