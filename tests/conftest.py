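import numpy as np
import pytest

from tuglocus.quant import PosteriorSamples


def make_posterior(draws_by_key, n_draws=None, eff_lengths=None):
    """Build a PosteriorSamples directly from {(tid, allele): draw vector}."""
    ids = sorted(draws_by_key)
    mat = np.column_stack([np.asarray(draws_by_key[k], dtype=float) for k in ids])
    eff = eff_lengths or {k: 1000.0 for k in ids}
    return PosteriorSamples(
        ids=ids,
        theta=mat,
        eff_lengths=eff,
        n_draws=n_draws or mat.shape[0],
        burn_in=0,
        thin=1,
        tpm=mat,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
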