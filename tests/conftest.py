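import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

#: Reference seven-class confusion matrix (rows = real, columns = predicted)
#: from the study this package reimplements; used to verify the metric
#: pipeline against independently published numbers.
REFERENCE_CONFUSION = {
    "classes": ("AF", "AT", "N", "PAC", "PVC", "SBR", "VT"),
    "counts": np.array(
        [
            [357, 0, 4, 1, 3, 2, 2],
            [0, 100, 0, 0, 0, 0, 0],
            [3, 0, 950, 3, 4, 0, 0],
            [1, 0, 1, 62, 0, 2, 0],
            [1, 0, 3, 1, 415, 2, 0],
            [4, 0, 0, 0, 0, 366, 1],
            [2, 1, 1, 0, 0, 0, 55],
        ],
        dtype=np.int64,
    ),
}

#: Published per-class sample counts of the reference dataset.
REFERENCE_CLASS_SIZES = {
    "AF": 1841, "AT": 500, "N": 4800, "PAC": 328, "PVC": 2106, "SBR": 1855, "VT": 294,
}


@pytest.fixture(scope="session")
def reference_confusion():
    from gasfnet.evaluation import ConfusionMatrix

    return ConfusionMatrix(REFERENCE_CONFUSION["counts"], REFERENCE_CONFUSION["classes"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
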