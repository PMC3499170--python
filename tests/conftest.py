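from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from snptrack import SampleDataset, worked_example, write_snp_file

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

GOLDEN_DIR = Path(__file__).parent / "golden"


@pytest.fixture()
def trio() -> list[SampleDataset]:
    """The fixed three-sample worked example."""
    return worked_example()


@pytest.fixture()
def trio_files(trio, tmp_path) -> dict[str, Path]:
    """The worked example written out as native-format files."""
    paths = {}
    for ds in trio:
        p = tmp_path / f"{ds.sample_id}.txt"
        write_snp_file(ds, p)
        paths[ds.sample_id] = p
    return paths


@pytest.fixture(scope="session")
def golden_dir() -> Path:
    return GOLDEN_DIR
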