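import numpy as np
import pytest

from poolfit.phenotype_core import ScreenPhenotypes
from poolfit.screen_io import InsertionAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotation(barcode, gene_id=None, feature="CDS", confidence=1, plate="P1", well="W1"):
    return InsertionAnnotation(
        barcode=barcode, gene_id=gene_id, feature=feature, confidence=confidence,
        plate=plate, well=well,
    )


def int_barcode(i: int, length: int = 8) -> str:
    """Deterministic ACGT barcode encoding an integer (base-4 digits)."""
    bases = "ACGT"
    out = []
    for _ in range(length):
        out.append(bases[i % 4])
        i //= 4
    return "".join(out)


GA_BARCODES = [int_barcode(i) for i in (1000, 1001, 1002)]
GB_BARCODES = [int_barcode(i) for i in (2000, 2001)]


@pytest.fixture
def toy_screen():
    """A hand-built screen: gene GA has three strong-dropout alleles, gene GB
    two neutral ones, plus a large neutral background of singleton genes."""
    a1, a2, a3 = GA_BARCODES
    b1, b2 = GB_BARCODES
    phi = {a1: 0.03, a2: 0.05, a3: 0.02, b1: 1.0, b2: 1.2}
    annotations = [
        make_annotation(a1, "GA", "CDS", 1),
        make_annotation(a2, "GA", "intron", 2),
        make_annotation(a3, "GA", "5UTR", 4),
        make_annotation(b1, "GB", "CDS", 1),
        make_annotation(b2, "GB", "CDS", 1),
    ]
    for i in range(60):
        b = int_barcode(i)
        phi[b] = 0.8 + (i % 9) * 0.1  # neutral band [0.5, 2)
        annotations.append(make_annotation(b, f"G{i:03d}", "CDS", 1))
    screen = ScreenPhenotypes(
        screen_id="S1",
        phi=phi,
        control_raw={b: 100 for b in phi},
        treatment_raw={b: 0 if p == 0 else 100 for b, p in phi.items()},
    )
    return screen, annotations
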