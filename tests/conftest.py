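import numpy as np
import pytest
from sklearn.model_selection import train_test_split

import berryripe as br
from berryripe.pipeline import extract_features_frame

#: Generator seed of the shared synthetic benchmark (100 patches per stage).
BENCHMARK_SEED = 7
BENCHMARK_N_PER_STAGE = 100


@pytest.fixture()
def disk_mask():
    yy, xx = np.mgrid[0:61, 0:61]
    return (yy - 30) ** 2 + (xx - 30) ** 2 <= 25**2


@pytest.fixture()
def square_mask():
    m = np.zeros((14, 14), dtype=bool)
    m[2:12, 2:12] = True
    return m


@pytest.fixture()
def teardrop_mask():
    return br.make_shape_mask(96, 80, rotation=0.0, seed=3)


@pytest.fixture(scope="session")
def benchmark():
    """The shared synthetic benchmark: instances, BGLaS features, 70/30 split.

    Built once per session; used by the classifier-recovery, trend and
    ablation tests as well as the pipeline tests.
    """
    instances, manifest = br.make_dataset(BENCHMARK_N_PER_STAGE, seed=BENCHMARK_SEED)
    frame = extract_features_frame(instances)
    assert not frame.attrs["errors"], frame.attrs["errors"]
    y = frame["label"].to_numpy()
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=0.3, stratify=y, random_state=0
    )
    return {
        "instances": instances,
        "manifest": manifest,
        "frame": frame,
        "labels": y,
        "train": idx_train,
        "test": idx_test,
    }


@pytest.fixture(scope="session")
def benchmark_svm(benchmark):
    """Table-style SVM fitted on the benchmark's BGLaS training features."""
    frame = benchmark["frame"]
    cols = [c for c in frame.columns if c not in ("label", "instance_id")]
    X = frame[cols].to_numpy(dtype=float)
    y = benchmark["labels"]
    tr = benchmark["train"]
    schema = [tuple(c.split("_", 1)) for c in cols]
    return br.fit(X[tr], y[tr], br.make_spec("SVM"), seed=0, schema=schema)
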