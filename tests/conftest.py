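import pytest

from mitocomp import ANCESTRAL_INSECT_ORDER, GeneOrder, SyntheticSpec, generate_genome


@pytest.fixture(scope="session")
def default_sim():
    """One canonical-plan synthetic genome plus its manifest."""
    return generate_genome(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def ancestral():
    return GeneOrder("ancestral", ANCESTRAL_INSECT_ORDER, circular=True)


GB_SINGLE_CDS = """\
LOCUS       TEST1                      6 bp    DNA     circular INV 01-JAN-2025
DEFINITION  minimal single-feature record.
FEATURES             Location/Qualifiers
     CDS             1..6
                     /gene="COI"
ORIGIN
        1 atgaaa
//
"""

GB_TRNA_ANTICODONS = """\
LOCUS       TEST2                    200 bp    DNA     circular INV 01-JAN-2025
DEFINITION  tRNA-Leu disambiguation by anticodon plus an origin wrap.
FEATURES             Location/Qualifiers
     tRNA            10..75
                     /product="tRNA-Leu"
                     /anticodon="(pos:30..32,aa:Leu,seq:taa)"
     tRNA            complement(80..140)
                     /product="tRNA-Leu"
                     /anticodon="(pos:100..102,aa:Leu,seq:tag)"
     misc_feature    join(150..200,1..20)
                     /note="control region"
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
       61 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      121 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      181 atgcatgcat gcatgcatgc
//
"""


@pytest.fixture
def gb_single_cds(tmp_path):
    p = tmp_path / "single.gb"
    p.write_text(GB_SINGLE_CDS)
    return p


@pytest.fixture
def gb_trna_anticodons(tmp_path):
    p = tmp_path / "trna.gb"
    p.write_text(GB_TRNA_ANTICODONS)
    return p
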