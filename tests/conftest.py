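import pytest

from pressc.rna_io import AnnotatedRna

# One A-U, one G-C and one G-U pair (giving both orientations at their two
# ends) plus an ACGU loop: realizes all 10 structure statuses.
COVERING_SEQ = "AGGACGUUCU"
COVERING_STRUCT = "(((....)))"


@pytest.fixture
def covering_record() -> AnnotatedRna:
    return AnnotatedRna(id="cover", residues=COVERING_SEQ, structure=COVERING_STRUCT)


@pytest.fixture
def small_hairpin() -> AnnotatedRna:
    return AnnotatedRna(
        id="hp", residues="GGGAAACCC", structure="(((...)))", mfe=-9.0, label="positive"
    )
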