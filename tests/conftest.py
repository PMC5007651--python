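import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference oracles

from suncache.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """Default-noise synthetic dataset, one observation day per subject."""
    cfg = SynthConfig(seed=12, days_per_subject=1)
    fixes, events, truth = generate(cfg)
    return cfg, fixes, events, truth


@pytest.fixture(scope="session")
def noise_free_synth():
    cfg = SynthConfig(seed=7, days_per_subject=1).noise_free()
    fixes, events, truth = generate(cfg)
    return cfg, fixes, events, truth


@pytest.fixture(scope="session")
def synth_dirs(tmp_path_factory):
    """Small synthetic dataset written to disk for I/O and CLI tests."""
    out = tmp_path_factory.mktemp("synthdata")
    cfg = SynthConfig(seed=12, days_per_subject=1)
    generate(cfg, out_dir=out)
    return cfg, out


@pytest.fixture(scope="session")
def synth_pipeline_report(synth_dirs, tmp_path_factory):
    """Full pipeline run (reduced Monte-Carlo sizes) on the small dataset."""
    from suncache.cli import run_pipeline

    _, data_dir = synth_dirs
    out = tmp_path_factory.mktemp("pipeline_out")
    report = run_pipeline(
        data_dir / "fixes.csv", data_dir / "events.csv", out,
        seed=3, n_mc_dip=200, bootstrap_b=25,
    )
    report["_out_dir"] = out
    return report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
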