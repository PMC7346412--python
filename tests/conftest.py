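import pytest

from pseudoplast.simulate import SyntheticConfig, build_synthetic_plastome


@pytest.fixture(scope="session")
def panel():
    """A small synthetic plastome panel shared (read-only) across tests."""
    return build_synthetic_plastome(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def panel_records(panel):
    return panel.panel_records()


TOY_GENBANK = """\
LOCUS       toy1                      30 bp    DNA     circular PLN 01-JAN-2020
FEATURES             Location/Qualifiers
     CDS             join(4..9)
                     /gene="g1"
     CDS             join(28..30,1..6)
                     /gene="g2"
     CDS             complement(10..18)
                     /gene="g3"
ORIGIN
        1 atgaaatagc tatttcatgg acccgggttt
//
"""


@pytest.fixture()
def toy_genbank(tmp_path):
    p = tmp_path / "toy1.gb"
    p.write_text(TOY_GENBANK)
    return p
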