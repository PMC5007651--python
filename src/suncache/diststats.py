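"""Distributional analysis of reflected track angles.

Contents: Hartigans' dip statistic and Monte-Carlo dip test, two-component
univariate Gaussian mixture fitted by EM with multi-start, parametric
bootstrap standard errors, two-sample KS comparison and moment diagnostics.

The dip statistic follows the greatest-convex-minorant / least-concave-
majorant algorithm of Hartigan & Hartigan: iteratively shrink a candidate
modal interval, tracking the largest ECDF deviation from the convex fit on
the left tail and the concave fit on the right tail; the dip is half the
largest required deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConvergenceError, InsufficientDataError, InvalidInputError

__all__ = [
    "AngleSample",
    "DipResult",
    "MixtureFit",
    "BootstrapSE",
    "KSResult",
    "dip_statistic",
    "dip_test",
    "em_fit",
    "bootstrap_se",
    "ks_2sample",
    "moments",
    "compare_components",
]

_HALF_PI = math.pi / 2


@dataclass(frozen=True)
class AngleSample:
    """Reflected track angles, radians in [-pi/2, pi/2]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("sample must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("sample contains non-finite values")
        if v.size and (v.min() < -_HALF_PI - 1e-9 or v.max() > _HALF_PI + 1e-9):
            raise InvalidInputError("reflected angles must lie in [-pi/2, pi/2]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, AngleSample):
        return sample.values
    return np.asarray(sample, dtype=float)


@dataclass(frozen=True)
class DipResult:
    D: float
    p: float
    n_mc: int


@dataclass(frozen=True)
class MixtureFit:
    lam: float  # weight of component 1 (the lower-mean component)
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    n: int
    degenerate: bool = False  # near-identical components: lambda unidentifiable

    def as_dict(self) -> dict:
        return {
            "lambda": self.lam, "mu1": self.mu1, "mu2": self.mu2,
            "sigma1": self.sigma1, "sigma2": self.sigma2,
            "loglik": self.loglik, "n_iter": self.n_iter,
            "converged": self.converged, "n": self.n,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class BootstrapSE:
    B: int
    se_lambda: float
    se_mu1: float
    se_mu2: float
    se_sigma1: float
    se_sigma2: float
    n_failed: int = 0
    warning: str | None = None
    params: object = None  # per-replicate parameter array when requested


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float


# ---------------------------------------------------------------------------
# Hartigans' dip


def dip_statistic(sample) -> float:
    """Hartigans' dip statistic of a one-dimensional sample.

    Largest vertical deviation between the ECDF and the closest unimodal
    CDF.  Satisfies ``D >= 1/(2n)``; a two-point sample gives exactly 0.25.
    """
    x = np.sort(_as_values(sample))
    n = x.size
    if n < 2:
        raise InsufficientDataError("dip statistic needs n >= 2")
    if x[0] == x[-1]:
        raise InsufficientDataError("dip undefined for a constant sample")
    return _dip(x)


def _dip(x: np.ndarray) -> float:
    """Core dip computation on sorted data (count units internally)."""
    n = x.size
    # mn[j]: left-most index joined with j in the greatest convex minorant
    mn = np.empty(n, dtype=np.int64)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 0:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # mj[k]: right-most index joined with k in the least concave majorant
    mj = np.empty(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n - 1:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # count units; enforces the 1/(2n) lower bound

    while True:
        # GCM change points from high down to low, LCM from low up to high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)

        ix, iv = l_gcm - 2, 1
        ig, ih = l_gcm - 1, l_lcm - 1
        if l_gcm != 2 or l_lcm != 2:
            # walk both curves, recording the largest LCM-above-GCM gap
            dx = -math.inf
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    # gap at an LCM change point against the GCM chord
                    gcm_ix1 = gcm[ix + 1]
                    den = x[gcm_ix] - x[gcm_ix1]
                    d = (lcm_iv - gcm_ix1 + 1) - (
                        (x[lcm_iv] - x[gcm_ix1]) * (gcm_ix - gcm_ix1) / den
                        if den > 0 else 0.0
                    )
                    iv += 1
                    if d >= dx:
                        dx, ig, ih = d, ix + 1, iv - 1
                else:
                    # gap at a GCM change point against the LCM chord
                    lcm_iv1 = lcm[iv - 1]
                    den = x[lcm_iv] - x[lcm_iv1]
                    d = (
                        (x[gcm_ix] - x[lcm_iv1]) * (lcm_iv - lcm_iv1) / den
                        if den > 0 else 0.0
                    ) - (gcm_ix - lcm_iv1 - 1)
                    ix -= 1
                    if d >= dx:
                        dx, ig, ih = d, ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            dx = 1.0

        if dx < dip:
            break

        # largest ECDF deviation below the GCM chords on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for i in range(jb, je + 1):
                    t = (i - jb + 1) - (x[i] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if max_t > dip_l:
                dip_l = max_t
        # largest ECDF deviation above the LCM chords on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for i in range(jb, je + 1):
                    t = (je - i + 1) - (x[je] - x[i]) * c
                    if t > max_t:
                        max_t = t
            if max_t > dip_u:
                dip_u = max_t

        d = max(dip_l, dip_u)
        if dip < d:
            dip = d
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return dip / (2.0 * n)


def dip_test(sample, n_mc: int = 10000, seed=None, rng=None) -> DipResult:
    """Monte-Carlo dip test against the uniform reference null.

    ``p`` is the proportion of uniform samples of the same size whose dip
    meets or exceeds the observed statistic (the conventional calibration
    of the dip test; the dip is location/scale invariant, so the uniform
    support does not matter).
    """
    x = _as_values(sample)
    if x.size < 4:
        raise InsufficientDataError("dip test needs n >= 4")
    d_obs = dip_statistic(x)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = dip_null_distribution(x.size, n_mc, rng)
    p = float(np.mean(null >= d_obs - 1e-15))
    return DipResult(D=d_obs, p=p, n_mc=n_mc)


def dip_null_distribution(n: int, n_mc: int, rng) -> np.ndarray:
    """Dip statistics of ``n_mc`` uniform samples of size ``n``."""
    return np.array([_dip(np.sort(rng.random(n))) for _ in range(n_mc)])


# ---------------------------------------------------------------------------
# two-component Gaussian mixture


def _em_once(x, lam, mu1, mu2, s1, s2, tol, max_iter, trace=None):
    n = x.size
    loglik = -np.inf
    n_iter = 0
    converged = False
    min_sigma = 1e-4 * (x.std() + 1e-12)
    for n_iter in range(1, max_iter + 1):
        # E step
        logp1 = np.log(lam) - 0.5 * np.log(2 * np.pi) - np.log(s1) - 0.5 * ((x - mu1) / s1) ** 2
        logp2 = np.log1p(-lam) - 0.5 * np.log(2 * np.pi) - np.log(s2) - 0.5 * ((x - mu2) / s2) ** 2
        m = np.maximum(logp1, logp2)
        log_mix = m + np.log(np.exp(logp1 - m) + np.exp(logp2 - m))
        new_loglik = float(log_mix.sum())
        if trace is not None:
            trace.append(new_loglik)
        r1 = np.exp(logp1 - log_mix)
        # M step
        w1 = r1.sum()
        w2 = n - w1
        if w1 < 1e-10 or w2 < 1e-10:
            break  # component collapsed
        lam = w1 / n
        mu1 = float((r1 * x).sum() / w1)
        mu2 = float(((1 - r1) * x).sum() / w2)
        s1 = max(math.sqrt(float((r1 * (x - mu1) ** 2).sum() / w1)), min_sigma)
        s2 = max(math.sqrt(float(((1 - r1) * (x - mu2) ** 2).sum() / w2)), min_sigma)
        gain = new_loglik - loglik
        if gain < tol and n_iter > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    else:
        # ridge crawl: unidentifiable (near-single-component) data can gain
        # forever at a negligible rate; treat sub-1e-4 progress as converged
        if gain < 1e-4:
            converged = True
    return lam, mu1, mu2, s1, s2, loglik, n_iter, converged


def _order_components(lam, mu1, mu2, s1, s2):
    if mu1 > mu2:
        return 1.0 - lam, mu2, mu1, s2, s1
    return lam, mu1, mu2, s1, s2


def em_fit(sample, init=None, tol: float = 1e-8, max_iter: int = 2000,
           n_starts: int = 20, seed=None, rng=None) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Initialisation is a below/above-median quantile split plus
    ``n_starts - 1`` randomly perturbed restarts; the best log-likelihood
    wins.  Components are reported with ``mu1 < mu2``.

    Raises :class:`ConvergenceError` (carrying the best fit) if no start
    converges.
    """
    x = _as_values(sample)
    if x.size < 10:
        raise InsufficientDataError("mixture fit needs n >= 10")
    if rng is None:
        rng = np.random.default_rng(seed)

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    sd = x.std() or 1.0
    base = (
        0.5,
        float(lo.mean()),
        float(hi.mean() if hi.size else lo.mean() + sd),
        float(lo.std() or sd / 2),
        float(hi.std() if hi.size > 1 else sd / 2) or sd / 2,
    )
    if init is not None:
        base = tuple(init)

    best = None
    for s in range(max(1, n_starts)):
        if s == 0:
            start = base
        else:
            start = (
                float(np.clip(base[0] + rng.uniform(-0.2, 0.2), 0.05, 0.95)),
                base[1] + rng.normal(0, sd / 2),
                base[2] + rng.normal(0, sd / 2),
                abs(base[3] * math.exp(rng.normal(0, 0.3))) + 1e-6,
                abs(base[4] * math.exp(rng.normal(0, 0.3))) + 1e-6,
            )
        res = _em_once(x, *start, tol=tol, max_iter=max_iter)
        if best is None or res[5] > best[5]:
            best = res
    lam, mu1, mu2, s1, s2, loglik, n_iter, converged = best
    lam, mu1, mu2, s1, s2 = _order_components(lam, mu1, mu2, s1, s2)
    # degenerate = the two components buy almost nothing over one Gaussian,
    # so lambda (and the component split) is unidentifiable
    single_ll = float(stats.norm.logpdf(x, x.mean(), x.std() or 1.0).sum())
    degenerate = loglik - single_ll < 3.0
    fit = MixtureFit(lam=lam, mu1=mu1, mu2=mu2, sigma1=s1, sigma2=s2,
                     loglik=loglik, n_iter=n_iter, converged=converged,
                     n=x.size, degenerate=degenerate)
    if not converged:
        raise ConvergenceError("EM did not converge in any start", best_fit=fit)
    return fit


def mixture_loglik(x, lam, mu1, mu2, s1, s2) -> float:
    x = np.asarray(x, dtype=float)
    p = lam * stats.norm.pdf(x, mu1, s1) + (1 - lam) * stats.norm.pdf(x, mu2, s2)
    return float(np.log(p).sum())


def sample_mixture(fit: MixtureFit, n: int, rng) -> np.ndarray:
    k = rng.random(n) < fit.lam
    out = np.where(
        k,
        rng.normal(fit.mu1, fit.sigma1, n),
        rng.normal(fit.mu2, fit.sigma2, n),
    )
    return out


def responsibilities(fit: MixtureFit, sample) -> np.ndarray:
    """Posterior probability of component 1 (lower mean) for each point."""
    x = _as_values(sample)
    p1 = fit.lam * stats.norm.pdf(x, fit.mu1, fit.sigma1)
    p2 = (1 - fit.lam) * stats.norm.pdf(x, fit.mu2, fit.sigma2)
    return p1 / (p1 + p2)


def bootstrap_se(fit: MixtureFit, sample, B: int = 2000, seed=None, rng=None,
                 n_starts: int = 1, return_params: bool = False) -> BootstrapSE:
    """Parametric-bootstrap standard errors for the mixture parameters.

    Simulates ``B`` datasets of the original size from the fitted mixture,
    refits each (initialised at the fitted parameters), aligns labels by
    mean ordering and reports the SD of each parameter across replicates.
    """
    if not fit.converged:
        raise InvalidInputError("bootstrap requires a converged fit")
    if B < 1:
        raise InvalidInputError("B must be >= 1")
    x = _as_values(sample)
    if rng is None:
        rng = np.random.default_rng(seed)
    init = (fit.lam, fit.mu1, fit.mu2, fit.sigma1, fit.sigma2)
    params = []
    n_failed = 0
    for _ in range(B):
        xb = sample_mixture(fit, x.size, rng)
        try:
            fb = em_fit(xb, init=init, tol=1e-8, max_iter=2000,
                        n_starts=n_starts, rng=rng)
        except (ConvergenceError, InsufficientDataError):
            n_failed += 1
            continue
        params.append([fb.lam, fb.mu1, fb.mu2, fb.sigma1, fb.sigma2])
    warning = None
    if B == 1:
        warning = "B = 1: SDs over a single replicate are meaningless"
    if n_failed > 0.1 * B:
        warning = f"{n_failed}/{B} bootstrap replicates failed to converge"
    arr = np.asarray(params)
    if arr.shape[0] < 2:
        ses = [0.0] * 5
    else:
        ses = arr.std(axis=0, ddof=1).tolist()
    return BootstrapSE(B=B, se_lambda=ses[0], se_mu1=ses[1], se_mu2=ses[2],
                       se_sigma1=ses[3], se_sigma2=ses[4],
                       n_failed=n_failed, warning=warning,
                       params=arr if return_params else None)


# ---------------------------------------------------------------------------
# classical comparisons


def ks_2sample(a, b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a, b = _as_values(a), _as_values(b)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("KS test needs n >= 2 in both samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(D=float(res.statistic), p=float(res.pvalue))


def moments(sample) -> dict:
    """Sample skewness and excess kurtosis (normal = 0 for both)."""
    x = _as_values(sample)
    if x.size < 4:
        raise InsufficientDataError("moments need n >= 4")
    if x.std() == 0:
        raise InvalidInputError("zero-variance sample")
    return {
        "skewness": float(stats.skew(x, bias=True)),
        "excess_kurtosis": float(stats.kurtosis(x, fisher=True, bias=True)),
    }


def compare_components(fit: MixtureFit, sample) -> dict:
    """Compare the two mixture components on a common positive scale.

    Points are hard-assigned by maximum responsibility; the lower-mean
    (left-of-sun) component's values are negated so that both subsamples
    live on the same scale, then compared by a KS test and a magnitude
    difference; each component mean is also tested against zero (one-sample
    t-test, ignoring any repeated-measures structure, which is handled
    elsewhere by mixed models).
    """
    x = _as_values(sample)
    r1 = responsibilities(fit, x)
    left = x[r1 >= 0.5]
    right = x[r1 < 0.5]
    if left.size < 5 or right.size < 5:
        raise InsufficientDataError(
            f"component subsamples too small: {left.size}, {right.size}"
        )
    left_inv = -left  # put the left-of-sun component on the positive scale
    ks = ks_2sample(left_inv, right)
    t_left = stats.ttest_1samp(left, 0.0)
    t_right = stats.ttest_1samp(right, 0.0)
    return {
        "n_left": int(left.size),
        "n_right": int(right.size),
        "mean_left": float(left.mean()),
        "mean_right": float(right.mean()),
        "mean_abs_left": float(np.abs(left).mean()),
        "mean_abs_right": float(np.abs(right).mean()),
        "magnitude_diff": float(np.abs(left).mean() - np.abs(right).mean()),
        "ks_D": ks.D,
        "ks_p": ks.p,
        "t_left": float(t_left.statistic),
        "p_left": float(t_left.pvalue),
        "t_right": float(t_right.statistic),
        "p_right": float(t_right.pvalue),
    }
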