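import numpy as np
import pytest

from tas2rpop.io import GeneAlignment, PopulationManifest
from tas2rpop.simulate import generate_dataset, study_config


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic dataset (28 genes, 92 western + 20 eastern
    chromosomes, default lesions), shared across tests."""
    return generate_dataset(study_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_manifest():
    entries = [(f"w{i}", f"ws{i // 2}", "west") for i in range(4)] + [
        (f"e{i}", f"es{i // 2}", "east") for i in range(4)
    ]
    return PopulationManifest(entries)


@pytest.fixture
def small_alignment(small_manifest):
    """8 chromosomes, 12-column ORF (ATG + 2 codons + TAA); w0..w3 carry a
    synonymous change at codon 3 (TTT->TTC); e3 a nonsynonymous one."""
    base = "ATG" + "CTT" + "TTT" + "TAA"
    seqs = {}
    for c, _, _ in small_manifest.entries:
        s = base
        if c.startswith("w"):
            s = s[:8] + "C" + s[9:]  # TTT -> TTC (Phe, synonymous)
        if c == "e3":
            s = s[:6] + "G" + s[7:]  # TTT -> GTT (Val, nonsynonymous)
        seqs[c] = s
    return GeneAlignment("toy", seqs, reference_id=None)
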