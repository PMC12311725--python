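import pytest

from crpforge import SequenceRecord, TC1_SEQUENCE, scan_crp_motif


@pytest.fixture(scope="session")
def tc1_record() -> SequenceRecord:
    """The 33-residue 8-cysteine ginsentide-like peptide tC1."""
    return SequenceRecord(id="tC1", seq=TC1_SEQUENCE, kind="protein")


@pytest.fixture(scope="session")
def tc1_match(tc1_record):
    matches = scan_crp_motif(tc1_record)
    assert len(matches) == 1
    return matches[0]
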