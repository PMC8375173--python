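import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def write_fasta(tmp_path):
    """Write (id, sequence) pairs to a temporary FASTA file and return its path."""

    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{i}\n{s}\n" for i, s in entries))
        return path

    return _write


@pytest.fixture(scope="session")
def paper_fixture():
    """One shared paper-counts fixture (seed 1) for the expensive round-trips."""
    from zfsurvey.synthetic_data import paper_counts_fixture

    return paper_counts_fixture(seed=1)
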