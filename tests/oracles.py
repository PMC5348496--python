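"""Independent oracles used by the test suite: a grid-search maximizer of
the paired beta-binomial likelihood, written from scratch (math.lgamma,
no shared code with the implementation)."""

import math

import numpy as np


def _loglik(c, t, C, F, r, phi):
    ll = 0.0
    for ci, ti, Ci, Fi in zip(c, t, C, F):
        pi = r * Ci / (r * Ci + Fi)
        if phi == 0.0:
            ll += ci * math.log(pi) + (ti - ci) * math.log(1 - pi)
        else:
            a, b = pi / phi, (1 - pi) / phi

            def lbeta(x, y):
                return math.lgamma(x) + math.lgamma(y) - math.lgamma(x + y)

            ll += lbeta(ci + a, ti - ci + b) - lbeta(a, b)
    return ll


def grid_search_ml(cecum, feces, C, F, rounds=4):
    """Maximize the paired likelihood over (log r, log phi) by iterative
    grid refinement; phi = 0 evaluated explicitly. Returns (r_hat, loglik)."""
    c = np.asarray(cecum, float)
    f = np.asarray(feces, float)
    t = c + f
    keep = t > 0
    c, t = c[keep], t[keep]
    Ck = np.asarray(C, float)[keep]
    Fk = np.asarray(F, float)[keep]

    lr_lo, lr_hi = -10.0, 10.0
    lp_lo, lp_hi = -10.0, 4.0
    best = (-np.inf, 0.0, None)
    for _ in range(rounds):
        lrs = np.linspace(lr_lo, lr_hi, 41)
        lps = [None] + list(np.linspace(lp_lo, lp_hi, 25))
        for lr in lrs:
            for lp in lps:
                phi = 0.0 if lp is None else math.exp(lp)
                ll = _loglik(c, t, Ck, Fk, math.exp(lr), phi)
                if ll > best[0]:
                    best = (ll, lr, lp)
        _, lr_b, lp_b = best
        w = (lr_hi - lr_lo) / 40
        lr_lo, lr_hi = lr_b - 2 * w, lr_b + 2 * w
        if lp_b is not None:
            wp = (lp_hi - lp_lo) / 24
            lp_lo, lp_hi = max(-10.0, lp_b - 2 * wp), min(4.0, lp_b + 2 * wp)
    return math.exp(best[1]), best[0]
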