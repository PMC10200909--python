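import numpy as np
import pandas as pd
import pytest

from cfquad.fragments import FRAGMENT_COLUMNS
from cfquad.genome import build_genome_model


@pytest.fixture
def small_model():
    """Two tiny chromosomes binned at 1 kb: 5 + 3 bins."""
    return build_genome_model([("chrA", 5000), ("chrB", 2500)], bin_size=1000)


def random_fragments(rng, model, n, sample_id="s1", with_motifs=True):
    """Valid random fragment frame on the given genome model."""
    chrom_names = [c for c, _ in model.chromosomes]
    lengths = dict(model.chromosomes)
    chrom = rng.choice(chrom_names, size=n)
    frag_len = rng.integers(50, 300, size=n)
    start = np.array(
        [rng.integers(0, max(1, lengths[c] - l)) for c, l in zip(chrom, frag_len)]
    )
    n_total = rng.poisson(2, size=n)
    n_meth = rng.binomial(n_total, 0.6)
    motifs = None
    if with_motifs:
        bases = np.array(list("ACGT"))
        motifs = ["".join(rng.choice(bases, size=4)) for _ in range(n)]
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": chrom,
            "start": start,
            "end": start + frag_len,
            "strand_fwd_read": rng.choice(["+", "-"], size=n),
            "n_meth_cpg": n_meth,
            "n_total_cpg": n_total,
            "end_motif": motifs if with_motifs else np.nan,
        },
        columns=FRAGMENT_COLUMNS,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
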