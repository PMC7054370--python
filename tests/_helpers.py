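import numpy as np

from renalpanel.horseshoe import ShrinkageFit


def constructed_fit(beta_rows, b_rows=None, sigma=1.0, family="linear", nc=2):
    """A ShrinkageFit with fixed draws (no MCMC), for projection oracles."""
    beta = np.atleast_2d(np.asarray(beta_rows, float))
    S, p = beta.shape
    b = (np.atleast_2d(b_rows) if b_rows is not None else np.zeros((S, nc)))
    return ShrinkageFit(
        family=family, n_cov=b.shape[1], n_bio=p,
        alpha=np.zeros(S), b=b, beta=beta,
        lam=np.ones((S, p)), tau=np.ones(S), c2=np.ones(S),
        sigma=np.full(S, sigma) if family == "linear" else None,
        chains=1, diagnostics={"max_rhat": 1.0},
    )
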