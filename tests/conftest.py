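"""Shared fixtures: validation SNP contexts and small studies.

The five validation variants carry the 31-nt genomic contexts used for the
binding assays (15 nt of true flank per side), with reference/alternative
alleles as annotated in dbSNP.
"""

import pytest

from mpracensus.motif_scan import Variant


@pytest.fixture(scope="session")
def validation_variants() -> dict[str, Variant]:
    return {
        "rs532446": Variant(
            "rs532446", "C", "T", flank5="GTGCTAGTTTCATCA", flank3="CAGGATTTTCTGTGG"
        ),
        "rs2718215": Variant(
            "rs2718215", "T", "C", flank5="TCACTATTTCTACAA", flank3="TTCATCACCCCACAC"
        ),
        "rs6491544": Variant(
            "rs6491544", "T", "C", flank5="CTCTGTTACAATGCA", flank3="GATGAAATACCGTGT"
        ),
        "rs281785": Variant(
            "rs281785", "A", "G", flank5="AAATGCTTGTATGAT", flank3="CAACTCTACCTAAAT"
        ),
        "rs7011846": Variant(
            "rs7011846", "G", "A", flank5="GTGAGCCATGATTGC", flank3="TCACTGCACTCCATC"
        ),
    }


@pytest.fixture(scope="session")
def expected_categories() -> dict[str, tuple[str, str]]:
    """(category, intact_allele) for the validation SNPs."""
    return {
        "rs532446": ("lenient_change", "both"),
        "rs2718215": ("disruption", "ref"),
        "rs6491544": ("disruption", "ref"),
        "rs281785": ("disruption", "alt"),
        "rs7011846": ("switch", "both"),
    }
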