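import pytest

from operon_dms.core import OperonSpec
from operon_dms.codon_features import SimpleCodonTable, UsageTable

try:  # derandomize hypothesis where available so CI runs are reproducible
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def toy_spec():
    # 6 codons: ATG AAA CTG TCT GAA TGG; positions 2-6 mutagenized
    return OperonSpec(
        gene_id="toy",
        coding_sequence="ATGAAACTGTCTGAATGG",
        mutagenized_positions=[2, 3, 4, 5, 6],
        rbs_region=(5, 6),
    )


@pytest.fixture
def toy_usage():
    # two-codon families with known maxima: Lys (AAA 0.6 max), Glu (GAA 0.7 max)
    return UsageTable(
        {"AAA": 0.6, "AAG": 0.2, "GAA": 0.7, "GAG": 0.1, "TGG": 1.0, "ATG": 1.0},
        source="toy",
    )


@pytest.fixture
def toy_trna():
    return SimpleCodonTable({"GAA": 10.0, "GAG": 5.0, "AAA": 2.0, "AAG": 2.0}, source="toy")


@pytest.fixture
def toy_stall():
    return SimpleCodonTable({"CTG": 2.0, "CTT": 4.0, "AAA": 1.0, "AAG": 3.0}, source="toy")
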