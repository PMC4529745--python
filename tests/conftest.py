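import pytest

from secloc.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def noiseless_dataset():
    """A small zero-error synthetic proteome shared across tests."""
    return generate(SimulationConfig(n_proteins=600, seed=11, n_species=2))


@pytest.fixture()
def uniprot_text():
    return (
        "ID   TEST1_SYNTH             Reviewed;         8 AA.\n"
        "AC   P00001;\n"
        "DE   RecName: Full=Test protein 1;\n"
        "OS   Synthetica exempli.\n"
        "OX   NCBI_TaxID=9001;\n"
        "CC   -!- SUBCELLULAR LOCATION: Secreted.\n"
        "SQ   SEQUENCE   8 AA;  880 MW;  0000000000000000 CRC64;\n"
        "     MAASKDEL\n"
        "//\n"
        "ID   TEST2_SYNTH             Unreviewed;         9 AA.\n"
        "AC   P00002;\n"
        "DE   RecName: Full=Test protein 2;\n"
        "DE   Flags: Fragment;\n"
        "OS   Synthetica exempli.\n"
        "OX   NCBI_TaxID=9001;\n"
        "CC   -!- SUBCELLULAR LOCATION: Cell membrane {ECO:0000250|Probable};\n"
        "CC       Single-pass type I membrane protein.\n"
        "SQ   SEQUENCE   9 AA;  990 MW;  0000000000000000 CRC64;\n"
        "     MKLVAAALG\n"
        "//\n"
        "ID   TEST3_SYNTH             Reviewed;         7 AA.\n"
        "AC   P00003;\n"
        "DE   RecName: Full=Test protein 3;\n"
        "OS   Synthetica altera.\n"
        "OX   NCBI_TaxID=9002;\n"
        "SQ   SEQUENCE   7 AA;  770 MW;  0000000000000000 CRC64;\n"
        "     MKLVAAA\n"
        "//\n"
    )
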