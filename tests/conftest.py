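import numpy as np
import pytest

from fundusnp.indiv_caller import IndividualLocus
from fundusnp.read_qc import BarcodeTable

# The ten 10-bp individual barcodes of the sequencing design (the segment of
# each barcoded primer between the bead adapter and the restriction-site arm).
BARCODES = {
    "AGCCTAAGCT": "ind1",
    "AGTTCAAGTC": "ind2",
    "ACTTGAACTG": "ind3",
    "ACGGTAACGT": "ind4",
    "ATCCGAATCG": "ind5",
    "ATGGCAATGC": "ind6",
    "CAGGTCCAGT": "ind7",
    "CATTGCCATG": "ind8",
    "CTAAGCCTAG": "ind9",
    "CGAATCCGAT": "ind10",
}


@pytest.fixture
def barcode_table() -> BarcodeTable:
    return BarcodeTable(BARCODES)


def make_locus(n_major: int, n_minor: int, e: float, major="A", minor="C",
               contig="contig1", pos=0) -> IndividualLocus:
    """Locus with n_major copies of `major`, n_minor of `minor`, constant e."""
    bases = np.array([major] * n_major + [minor] * n_minor)
    return IndividualLocus(contig, pos, bases, np.full(n_major + n_minor, e))


def naive_posterior(bases, errors, prior=1e-4) -> float:
    """Independent direct-product oracle for the heterozygosity posterior.

    Plain floating-point products, no log space: valid for short pileups.
    """
    from collections import Counter

    counts = Counter(bases)
    order = sorted(counts, key=lambda b: (-counts[b], b))
    major = order[0]
    minor = order[1] if len(order) > 1 else None
    l_hom = 1.0
    l_het = 1.0
    for b, e in zip(bases, errors):
        l_hom *= (1.0 - e) if b == major else e / 3.0
        l_het *= (0.5 * (1.0 - e) + 0.5 * e / 3.0) if b in (major, minor) else e / 3.0
    return prior * l_het / (prior * l_het + (1.0 - prior) * l_hom)
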