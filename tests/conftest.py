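import numpy as np
import pytest

from cocoonsort import synthetic
from cocoonsort.config import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_config():
    """Small but fully representative benchmark conditions."""
    return synthetic.BenchmarkConfig(n_per_category=10)


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory, benchmark_config):
    """A generated benchmark tree shared by the pipeline-level tests."""
    path = tmp_path_factory.mktemp("benchmark")
    manifest = synthetic.make_benchmark_set(path, benchmark_config, seed=123)
    return path, manifest


@pytest.fixture(scope="session")
def pipeline_config(benchmark_config):
    """Pipeline thresholds matched to the benchmark render scale."""
    return PipelineConfig.from_dict(
        {
            "size": {
                "min_px2": benchmark_config.size_min_px2,
                "max_px2": benchmark_config.size_max_px2,
            }
        }
    )


@pytest.fixture(scope="session")
def trained_models(tmp_path_factory, benchmark_dir, pipeline_config):
    """Shape and vital models fitted on the shared benchmark."""
    import warnings

    from cocoonsort import pipeline

    path, _ = benchmark_dir
    out = tmp_path_factory.mktemp("models")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shape = pipeline.train_shape_model(path, pipeline_config, seed=7)
        vital = pipeline.train_vital_model(path, pipeline_config, seed=8)
    shape_path = out / "shape.json"
    vital_path = out / "vital.json"
    pipeline.save_station_model(shape_path, shape)
    pipeline.save_station_model(vital_path, vital)
    return {"shape": shape, "vital": vital, "shape_path": shape_path, "vital_path": vital_path}
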