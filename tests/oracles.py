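"""Independent brute-force/grid-search oracles shared by the test suite."""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def pairwise_concordance(pred, out):
    """Exhaustive O(n^2) enumeration over all (good, poor) pairs."""
    pos = [p for p, o in zip(pred, out) if o == 1]
    neg = [p for p, o in zip(pred, out) if o == 0]
    num = 0.0
    for a in pos:
        for b in neg:
            num += 1.0 if a > b else (0.5 if a == b else 0.0)
    return num / (len(pos) * len(neg))


def grid_search_alpha(y, out, lo=-8.0, hi=8.0):
    """1-D maximizer of the offset-model log-likelihood by refined grid search."""
    y, out = np.asarray(y, float), np.asarray(out, float)

    def nll(a):
        p = expit(a + y)
        return -(out * np.log(p) + (1 - out) * np.log1p(-p)).sum()

    for _ in range(8):
        grid = np.linspace(lo, hi, 201)
        vals = [nll(a) for a in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 200)]
    return grid[i]


def nelder_mead_slope(y, out):
    """Independent 2-D optimizer of the slope-model log-likelihood."""
    y, out = np.asarray(y, float), np.asarray(out, float)

    def nll(theta):
        p = np.clip(expit(theta[0] + theta[1] * y), 1e-12, 1 - 1e-12)
        return -(out * np.log(p) + (1 - out) * np.log(1 - p)).sum()

    res = minimize(nll, x0=[0.0, 1.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return res.x
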