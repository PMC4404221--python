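import pytest

import spikegbs as sg


@pytest.fixture(scope="session")
def parts():
    return sg.ConstructParts()


@pytest.fixture(scope="session")
def toy_markers():
    """Two hand-picked loci: one biallelic SNP, one hexaploid dosage locus."""
    return [
        sg.MarkerDefinition(
            "locus1", "ACGGTACT", "TTGACCAT", "CAGTTAGCAT", "CAGTCAGCAT"
        ),
        sg.MarkerDefinition(
            "locus2", "GGATCCAT", "AACCTGGT", "TTGACGGTTA", "TTGACAGTTA",
            class_model=sg.ClassModel.dosage_classes([1, 2 / 3, 1 / 3, 0]),
        ),
    ]


@pytest.fixture(scope="session")
def biallelic_marker(toy_markers):
    return toy_markers[0]


@pytest.fixture(scope="session")
def barcodes12():
    return sg.generate_barcode_set(12, length=10, min_hamming=3, seed=7)
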