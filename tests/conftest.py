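import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from g4snp.gene_model import GeneModel  # noqa: E402


@pytest.fixture
def toy_model() -> GeneModel:
    """Two exons (0,10) and (20,30), start codon at offset 2.

    Coding bases c.1..c.8 sit at offsets 2..9 (exon 1), c.9.. at 20..
    (exon 2); offsets 0-1 are transcribed 5'UTR.
    """
    seq = "TTATGGCAAC" + "TTTTTTTTTT" + "ACGTACGTAC"
    return GeneModel("TOY", seq, [(0, 10), (20, 30)], 2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220106)
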