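import numpy as np
import pytest

from mirquant.preprocess import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5
from mirquant.reference import GenomicInterval, MatureMiRNA, ReferenceBundle


@pytest.fixture
def toy_mirnas() -> dict[str, MatureMiRNA]:
    """Three mature miRNAs; mir-2 is encoded at two genomic loci."""
    seqs = {
        "toy-mir-1": "ACGTACGTTAGCCGATTACGGT",      # 22 nt
        "toy-mir-2": "TTGACCGGTAACGTGCATCAAG",      # 22 nt, 2 loci
        "toy-mir-3": "GGCATTCAGTCGATCCTAGG",        # 20 nt
    }
    out = {}
    pos = 100
    for i, (name, seq) in enumerate(seqs.items()):
        n_loci = 2 if name == "toy-mir-2" else 1
        loci = [
            GenomicInterval(f"chr{j + 1}", pos + j * 500, pos + j * 500 + len(seq), "+")
            for j in range(n_loci)
        ]
        out[name] = MatureMiRNA(name=name, mature_seq=seq, loci=loci)
        pos += 50
    return out


@pytest.fixture
def toy_exons() -> dict[str, str]:
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {
        f"exon_{i}": "".join(rng.choice(bases, size=100)) for i in range(1, 4)
    }


@pytest.fixture
def toy_bundle(toy_mirnas, toy_exons) -> ReferenceBundle:
    return ReferenceBundle.build(toy_mirnas, exon_seqs=toy_exons)


@pytest.fixture
def adapters() -> tuple[str, str]:
    return DEFAULT_ADAPTER3, DEFAULT_ADAPTER5
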