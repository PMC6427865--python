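import numpy as np
import pytest

from tadfuse.genome_io import BinScheme, ContactMatrix
from tadfuse.model import ModelParams


@pytest.fixture
def scheme6():
    return BinScheme(chrom="chrT", bin_size=5000, n_bins=6)


def make_params(n, alpha=0.0, beta=-1.0, r=None, bin_size=5000, chrom="chrT"):
    """Hand-built ModelParams: alpha scalar or array, r a {bin: value} dict."""
    scheme = BinScheme(chrom=chrom, bin_size=bin_size, n_bins=n)
    a = np.full(n, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha, float)
    rr = np.zeros(n)
    if r:
        for k, v in r.items():
            rr[k - 1] = v
    return ModelParams(scheme=scheme, alpha=a, r=rr, beta=np.full(n, float(beta)))


def matrix_from_params(p, max_distance=None):
    """Exact model matrix (no noise) for small-n oracle tests."""
    from tadfuse.model import model_frequency

    n = p.n_bins
    md = max_distance or n - 1
    H = ContactMatrix(p.scheme)
    for i in range(1, n + 1):
        for j in range(i + 1, min(n, i + md) + 1):
            H.set(i, j, model_frequency(p, i, j))
    return H
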