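from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_inputs() -> pd.DataFrame:
    """Published ξ, H and six exponents for the 32 vertebrate mtDNA genomes."""
    from dnawalk.datasets import load_vertebrate_reference

    return load_vertebrate_reference()


@pytest.fixture(scope="session")
def reference_indices() -> pd.DataFrame:
    """Published (v1, v2, v3) values for the same 32 genomes."""
    return pd.read_csv(DATA_DIR / "reference_indices.tsv", sep="\t")


@pytest.fixture
def make_fasta(tmp_path):
    """Write a FASTA file from (id, symbols) pairs and return its path."""

    def _make(records, name="input.fasta"):
        path = tmp_path / name
        with path.open("w") as fh:
            for rid, symbols in records:
                fh.write(f">{rid}\n{symbols}\n")
        return path

    return _make
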