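import numpy as np
import pytest

from vitivar.io_formats import GeneModel, GenomeSequence


@pytest.fixture
def tiny_assembly():
    """Two short chromosomes with fixed sequence for hand-checkable tests."""
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    seqs = {}
    for name, length in (("chr1", 5000), ("chr2", 3000)):
        seqs[name] = GenomeSequence(name, "".join(bases[rng.integers(0, 4, length)]))
    return seqs


@pytest.fixture
def plus_gene():
    """Single-exon plus-strand gene: CDS 100-400 on chr1."""
    return GeneModel("g+", "chr1", "+", cds_intervals=[(100, 400)],
                     utr5_intervals=[(50, 100)], utr3_intervals=[(400, 450)])


def make_cds_sequence(rng, n_codons):
    """Random complete CDS: ATG start, no internal stops, terminal TAA/TAG/TGA."""
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(bases[rng.integers(0, 4)] for _ in range(3))
        if codon not in stops:
            codons.append(codon)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)
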