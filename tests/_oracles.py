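"""Independent enumeration oracles shared by the test modules.

These deliberately avoid the package's own code paths: the conditional
exact-test law is built by explicit convolution of per-replicate pmfs, and
the Fisher p-value by exhaustive hypergeometric enumeration.
"""

import numpy as np
from scipy import stats


def conditional_p_by_convolution(a, b, n_a, n_b, phi):
    """Two-sided conditional p for group sums (a, b) from per-replicate pmfs
    combined by explicit convolution (a sum over all splits of s)."""
    s = a + b
    mu = s / (n_a + n_b)  # null per-replicate mean
    x = np.arange(s + 1)
    if phi == 0:
        rep_pmf = stats.poisson.pmf(x, mu)
    else:
        r = 1.0 / phi
        rep_pmf = stats.nbinom.pmf(x, r, r / (r + mu))

    def convolve_n(n):
        out = np.zeros(s + 1)
        out[0] = 1.0
        for _ in range(n):
            out = np.convolve(out, rep_pmf)[: s + 1]
        return out

    pa = convolve_n(n_a)
    pb = convolve_n(n_b)
    f = pa * pb[::-1]
    f = f / f.sum()
    return float(f[f <= f[a] * (1 + 1e-12)].sum())


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs * (1 + 1e-7)))
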