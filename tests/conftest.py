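import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "kinrace",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kinrace")


@pytest.fixture()
def construct_table() -> pd.DataFrame:
    """Published per-construct (dwell, run length) measurements."""
    from kinrace.datasets import table1_frame

    return table1_frame()


@pytest.fixture()
def loop12_fasta(tmp_path):
    """A small FASTA of synthetic loop-like peptides with known charges."""
    path = tmp_path / "loops.fasta"
    path.write_text(
        ">sixK synthetic all-lysine stretch\nKKKKKK\n"
        ">mixed synthetic acidic/basic mix\nDKE\n"
        ">neutral synthetic glutamine stretch\nQQQQ\n"
    )
    return path
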