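"""Inferential core: paired beta-binomial likelihood-ratio test, SGoF
multiple-testing metatest, signed paired fold-changes with a correction
factor, the missing-value filter, and Shannon alpha diversity.

Model
-----
For mouse *i* let ``c_i`` be the cecal count of a feature, ``f_i`` the fecal
count, ``t_i = c_i + f_i`` the pair total, and ``C_i`` / ``F_i`` the cecal /
fecal sample totals (library sizes). Conditional on ``t_i`` the cecal count
is modelled as beta-binomial with mean

    pi_i(r) = r * C_i / (r * C_i + F_i)

where ``r`` is the fold ratio of the feature's relative abundance in cecum
versus feces, and intraclass overdispersion ``phi >= 0`` (``phi = 0`` is the
binomial limit). The null hypothesis is ``r = 1`` (dispersion free); the
alternative frees ``(r, phi)``. Twice the log-likelihood-ratio is referred
to a chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats as sps

__all__ = [
    "IbbResult",
    "SgofResult",
    "FoldChangeResult",
    "bb_loglik",
    "ibb_test",
    "sgof_adjust",
    "paired_fold_change",
    "missing_value_filter",
    "shannon_index",
]

_LOG_PHI_LO = -10.0  # below this the beta-binomial is numerically binomial
_LOG_PHI_HI = 4.0
_LOG_R_BOUND = 14.0


# ----------------------------------------------------------------------
# beta-binomial log-likelihood
# ----------------------------------------------------------------------

def bb_loglik(c, t, pi, phi: float) -> float:
    """Sum of log beta-binomial masses over pairs.

    Parameters are the per-pair counts ``c``, pair totals ``t``, per-pair
    means ``pi`` in (0,1), and a single dispersion ``phi >= 0``. With
    shape parameters ``a = pi/phi`` and ``b = (1-pi)/phi`` the mass is

        C(t, c) * B(c + a, t - c + b) / B(a, b)

    evaluated through log-gamma; ``phi = 0`` is evaluated exactly as the
    binomial log-likelihood.
    """
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any((c < 0) | (c > t)):
        raise ValueError("counts must satisfy 0 <= c <= t")
    if np.any((pi <= 0.0) | (pi >= 1.0)):
        raise ValueError("pi must lie strictly inside (0, 1)")
    if phi < 0:
        raise ValueError("phi must be non-negative")

    comb = special.gammaln(t + 1) - special.gammaln(c + 1) - special.gammaln(t - c + 1)
    if phi == 0.0:
        ll = comb + c * np.log(pi) + (t - c) * np.log1p(-pi)
    else:
        a = pi / phi
        b = (1.0 - pi) / phi
        ll = comb + special.betaln(c + a, t - c + b) - special.betaln(a, b)
    return float(np.sum(ll))


# ----------------------------------------------------------------------
# paired ibb test
# ----------------------------------------------------------------------

@dataclass
class IbbResult:
    """Outcome of the paired beta-binomial likelihood-ratio test."""

    r_hat: float
    phi_hat: float
    lrt: float
    p_value: float
    degenerate: bool = False


def _pi_of_logr(logr: float, C: np.ndarray, F: np.ndarray) -> np.ndarray:
    # pi = r*C / (r*C + F), computed stably in logs
    logit = logr + np.log(C) - np.log(F)
    return special.expit(logit)


def _make_nll(c, t, C, F):
    """Fast negative log-likelihood in (log r, log phi), dropping the
    parameter-free binomial coefficient (cancels in the LRT)."""
    log_cf = np.log(C) - np.log(F)
    tc = t - c

    def nll(logr: float, logphi: float | None) -> float:
        logit = np.clip(logr + log_cf, -30.0, 30.0)
        pi = special.expit(logit)
        # below the phi floor the beta-binomial is numerically binomial and
        # betaln loses all precision; evaluate the exact limit instead
        if logphi is not None and logphi < _LOG_PHI_LO:
            logphi = None
        if logphi is None:
            ll = float(np.sum(c * np.log(pi) + tc * np.log1p(-pi)))
        else:
            phi = np.exp(min(logphi, _LOG_PHI_HI))
            a = pi / phi
            b = (1.0 - pi) / phi
            ll = float(np.sum(special.betaln(c + a, tc + b) - special.betaln(a, b)))
        return -ll if np.isfinite(ll) else np.inf

    return nll


def ibb_test(
    cecum: np.ndarray,
    feces: np.ndarray,
    cecum_totals: np.ndarray,
    feces_totals: np.ndarray,
) -> IbbResult:
    """Paired library-size-aware beta-binomial likelihood-ratio test.

    ``cecum``/``feces`` are one feature's counts per mouse; the totals are
    the corresponding whole-sample counts (used to adjust for sequencing
    depth). Requires at least two mouse pairs. A feature with all pair
    totals zero is returned degenerate with ``p = 1``.
    """
    c = np.asarray(cecum, dtype=float)
    f = np.asarray(feces, dtype=float)
    C = np.asarray(cecum_totals, dtype=float)
    F = np.asarray(feces_totals, dtype=float)
    if not (c.shape == f.shape == C.shape == F.shape):
        raise ValueError("count and total vectors must share one shape")
    if c.size < 2:
        raise ValueError("ibb_test needs at least 2 mouse pairs")
    if np.any(C <= 0) or np.any(F <= 0):
        raise ValueError("sample totals must be positive")

    t = c + f
    keep = t > 0
    if not np.any(keep):
        return IbbResult(r_hat=1.0, phi_hat=0.0, lrt=0.0, p_value=1.0, degenerate=True)
    c, t, C, F = c[keep], t[keep], C[keep], F[keep]

    nll = _make_nll(c, t, C, F)

    # --- null fit: r = 1, phi free (phi = 0 boundary checked explicitly)
    ll0 = -nll(0.0, None)
    res0 = optimize.minimize_scalar(
        lambda lp: nll(0.0, lp), bounds=(_LOG_PHI_LO, _LOG_PHI_HI), method="bounded"
    )
    phi0 = 0.0
    if -res0.fun > ll0:
        ll0 = -res0.fun
        phi0 = float(np.exp(res0.x))

    # --- alternative fit: (r, phi) free
    # moment start for log r from depth-adjusted count ratio
    logr0 = float(
        np.log((c.sum() + 0.5) / (t.sum() - c.sum() + 0.5)) + np.log(F.sum() / C.sum())
    )
    logr0 = float(np.clip(logr0, -_LOG_R_BOUND + 1, _LOG_R_BOUND - 1))

    # binomial profile (phi = 0): 1-D search over log r
    prof = optimize.minimize_scalar(
        lambda lr: nll(lr, None), bounds=(-_LOG_R_BOUND, _LOG_R_BOUND), method="bounded"
    )
    ll1 = -prof.fun
    r1 = float(np.exp(prof.x))
    phi1 = 0.0

    starts = [
        (logr0, np.log(max(phi0, 1e-3))),
        (prof.x, -3.0),
        (0.0, 0.0),
    ]
    for s in starts:
        res = optimize.minimize(
            lambda x: nll(float(np.clip(x[0], -_LOG_R_BOUND, _LOG_R_BOUND)), x[1]),
            x0=np.asarray(s, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 250},
        )
        if -res.fun > ll1:
            ll1 = -res.fun
            r1 = float(np.exp(np.clip(res.x[0], -_LOG_R_BOUND, _LOG_R_BOUND)))
            phi1 = float(np.exp(res.x[1]))

    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(sps.chi2.sf(lrt, df=1))
    return IbbResult(r_hat=r1, phi_hat=phi1, lrt=lrt, p_value=p)


# ----------------------------------------------------------------------
# SGoF multiple-testing metatest
# ----------------------------------------------------------------------

@dataclass
class SgofResult:
    """Sequential-goodness-of-fit adjustment of a p-value list.

    ``R`` is the number of raw p-values at or below ``alpha``; the k-th
    smallest p-value gets adjusted p ``P(Binomial(m, alpha) >= R - k + 1)``
    (exact upper tail) for ``k <= R`` and 1 otherwise; ``K`` features —
    the K smallest p-values — are declared at metatest level ``gamma``.
    """

    m: int
    alpha: float
    gamma: float
    R: int
    K: int
    adjusted_p: np.ndarray = field(repr=False)
    declared: np.ndarray = field(repr=False)


def sgof_adjust(p_values, alpha: float = 0.05, gamma: float = 0.05) -> SgofResult:
    """Adjust p-values with the exact-binomial SGoF metatest."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")

    m = p.size
    R = int(np.sum(p <= alpha))
    order = np.argsort(p, kind="stable")
    adjusted = np.ones(m)
    if R > 0:
        ks = np.arange(1, R + 1)
        # P(Bin(m, alpha) >= R - k + 1), exact tail
        adjusted[order[:R]] = sps.binom.sf(R - ks, m, alpha)
    K = int(np.sum(adjusted[order] <= gamma))
    declared = np.zeros(m, dtype=bool)
    declared[order[:K]] = True
    return SgofResult(
        m=m, alpha=alpha, gamma=gamma, R=R, K=K, adjusted_p=adjusted, declared=declared
    )


# ----------------------------------------------------------------------
# paired fold-change and missing-value filter
# ----------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    """Signed paired fold-change (cecum vs feces) with SEM.

    Per-mouse depth-adjusted counts get a correction factor ``cf`` added to
    both members of each ratio to remove the discontinuity at zero. The
    mean ratio is formed in both orientations (CC/F and F/CC); the larger
    one is reported, signed positive when cecum dominates and negative when
    feces dominates, so the magnitude is always >= 1 and the statistic is
    antisymmetric under site swap. The SEM is the standard error of the
    per-mouse ratios in the reported orientation.
    """

    cf: float
    ratios_cc_over_f: np.ndarray
    ratios_f_over_cc: np.ndarray
    mean_fc_signed: float
    sem: float
    dominant_group: str  # "CC" or "F"


def paired_fold_change(
    cecum,
    feces,
    cecum_totals,
    feces_totals,
    cf: float = 2.0,
) -> FoldChangeResult:
    """Signed paired fold-change on depth-adjusted counts.

    Counts are rescaled to a common reference depth (the mean sample total
    over all samples of the pair design) before the per-mouse ratios are
    taken.
    """
    if cf <= 0:
        raise ValueError("correction factor must be positive")
    c = np.asarray(cecum, dtype=float)
    f = np.asarray(feces, dtype=float)
    C = np.asarray(cecum_totals, dtype=float)
    F = np.asarray(feces_totals, dtype=float)
    if c.size < 1:
        raise ValueError("need at least one pair")
    ref = np.concatenate([C, F]).mean()
    c_adj = c * ref / C
    f_adj = f * ref / F

    up = (c_adj + cf) / (f_adj + cf)
    down = (f_adj + cf) / (c_adj + cf)
    m_up = float(up.mean())
    m_down = float(down.mean())

    if m_up >= m_down:
        dominant, fc, rep = "CC", m_up, up
    else:
        dominant, fc, rep = "F", -m_down, down
    sem = float(np.std(rep, ddof=1) / np.sqrt(rep.size)) if rep.size > 1 else 0.0
    return FoldChangeResult(
        cf=cf,
        ratios_cc_over_f=up,
        ratios_f_over_cc=down,
        mean_fc_signed=fc,
        sem=sem,
        dominant_group=dominant,
    )


def missing_value_filter(cecum, feces, fc: FoldChangeResult) -> bool:
    """True (exclude from the differential list) iff any mouse has a zero
    raw count in the dominant (more abundant) site."""
    dominant = np.asarray(cecum) if fc.dominant_group == "CC" else np.asarray(feces)
    return bool(np.any(dominant == 0))


# ----------------------------------------------------------------------
# alpha diversity
# ----------------------------------------------------------------------

def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p ln p over nonzero features."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if x.sum() <= 0:
        raise ValueError("need at least one positive count")
    return float(sps.entropy(x))
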