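"""Distribution statistics for cell-measurement tables.

Covers the comparisons commonly run on per-cell length/width/area samples:
descriptive shape statistics (coefficient of variation, moment skewness,
quantiles), the two-sample Kolmogorov-Smirnov test on empirical CDFs, a
Welch two-sample t statistic, and a two-component univariate Gaussian
mixture fit by expectation-maximization — cell-length histograms become
biphasic when a subpopulation arrests or elongates, and the mixture
quantifies the two modes.

Conventions: the standard deviation is the sample one (divisor n-1); the
skewness is the moment estimator m3 / m2^(3/2) with central moments using
divisor n (a bias-adjusted variant is available via ``bias_correct``);
quantiles use linear interpolation; the KS p-value is the asymptotic
Kolmogorov distribution at effective size nx*ny/(nx+ny).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "SummaryStats",
    "KSResult",
    "MixtureFit",
    "summarize",
    "ks_two_sample",
    "welch_t",
    "fit_mixture2",
    "plot_density",
]

QUANTILE_LEVELS = (0.25, 0.5, 0.75, 0.90)


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    cv: float
    skewness: float
    skewness_defined: bool
    quantiles: dict[float, float]


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float


@dataclass
class MixtureFit:
    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihood_path: list[float] = field(default_factory=list, repr=False)


def _clean(sample, name="sample") -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def summarize(sample, bias_correct: bool = False) -> SummaryStats:
    """Descriptive statistics of a univariate sample.

    Requires n >= 3 (skewness needs three points; sd and cv need two).  A
    constant sample has cv = 0 and skewness flagged undefined.  With
    ``bias_correct`` the skewness is the adjusted Fisher-Pearson estimator
    sqrt(n(n-1))/(n-2) times the moment estimator.
    """
    x = _clean(sample)
    n = x.size
    if n < 2:
        raise ValueError("standard deviation and cv require n >= 2")
    if n < 3:
        raise ValueError("skewness requires n >= 3")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = sd / mean if mean != 0 else math.inf if sd > 0 else 0.0
    centered = x - mean
    m2 = float((centered**2).mean())
    m3 = float((centered**3).mean())
    if m2 == 0.0:
        skew, defined = float("nan"), False
    else:
        skew = m3 / m2**1.5
        if bias_correct:
            skew *= math.sqrt(n * (n - 1)) / (n - 2)
        defined = True
    quantiles = {q: float(np.quantile(x, q)) for q in QUANTILE_LEVELS}
    return SummaryStats(
        n=n, mean=mean, sd=sd, cv=cv, skewness=skew, skewness_defined=defined,
        quantiles=quantiles,
    )


def ks_two_sample(x, y) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    The statistic is the supremum over the pooled sample values of the
    absolute difference of the two empirical CDFs; the p-value comes from
    the asymptotic Kolmogorov distribution evaluated at
    d * sqrt(nx*ny/(nx+ny)).
    """
    xs = np.sort(_clean(x, "x"))
    ys = np.sort(_clean(y, "y"))
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    d = float(np.abs(cdf_x - cdf_y).max())
    en = xs.size * ys.size / (xs.size + ys.size)
    p = float(special.kolmogorov(d * math.sqrt(en)))
    return KSResult(d_statistic=d, p_value=min(1.0, max(0.0, p)))


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t statistic with Satterthwaite degrees of freedom."""
    xs = _clean(x, "x")
    ys = _clean(y, "y")
    if xs.size < 2 or ys.size < 2:
        raise ValueError("welch_t requires n >= 2 in each sample")
    vx = xs.var(ddof=1) / xs.size
    vy = ys.var(ddof=1) / ys.size
    if vx + vy == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    t = (xs.mean() - ys.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (xs.size - 1) + vy**2 / (ys.size - 1))
    return float(t), float(df)


def _normal_pdf(x, mu, sigma):
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


def fit_mixture2(
    sample,
    init: tuple[float, float, float, float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    ``init`` is (pi1, mu1, mu2, sigma1, sigma2); by default the means start
    at the 1/3 and 2/3 sample quantiles with equal weights and the pooled
    sample sd.  Iterations stop when the log-likelihood gain drops below
    ``tol`` or after ``max_iter`` iterations.  Component sds are floored at
    1e-3 times the sample range to prevent the classic likelihood collapse
    onto a single point.  Components are relabeled so mu1 <= mu2.

    Requires n >= 10; an all-equal sample is degenerate and raises.
    """
    x = _clean(sample)
    if x.size < 10:
        raise ValueError("fit_mixture2 requires n >= 10")
    rng_range = float(x.max() - x.min())
    if rng_range == 0.0:
        raise ValueError("degenerate sample: all values equal")
    sigma_floor = 1e-3 * rng_range

    if init is None:
        mu1, mu2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
        if mu1 == mu2:
            mu1 -= 0.05 * rng_range
            mu2 += 0.05 * rng_range
        s = max(float(x.std(ddof=1)), sigma_floor)
        pi1, s1, s2 = 0.5, s, s
    else:
        pi1, mu1, mu2, s1, s2 = (float(v) for v in init)
        if not (0.0 < pi1 < 1.0):
            raise ValueError("initial mixing proportion must lie in (0, 1)")
        s1, s2 = max(s1, sigma_floor), max(s2, sigma_floor)

    ll_path: list[float] = []
    ll_prev = -math.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        f1 = pi1 * _normal_pdf(x, mu1, s1)
        f2 = (1.0 - pi1) * _normal_pdf(x, mu2, s2)
        total = f1 + f2
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        resp = f1 / total
        ll = float(np.log(total).sum())
        ll_path.append(ll)
        # M step
        w1 = float(resp.sum())
        w2 = x.size - w1
        if w1 <= 0 or w2 <= 0:  # one component vanished; keep previous params
            converged = True
            break
        mu1 = float((resp * x).sum() / w1)
        mu2 = float(((1.0 - resp) * x).sum() / w2)
        s1 = max(math.sqrt(float((resp * (x - mu1) ** 2).sum() / w1)), sigma_floor)
        s2 = max(math.sqrt(float(((1.0 - resp) * (x - mu2) ** 2).sum() / w2)), sigma_floor)
        pi1 = w1 / x.size
        if ll - ll_prev < tol and n_iter > 1:
            converged = True
            break
        ll_prev = ll

    if mu1 > mu2:
        pi1, mu1, mu2, s1, s2 = 1.0 - pi1, mu2, mu1, s2, s1
    return MixtureFit(
        weights=(pi1, 1.0 - pi1),
        means=(mu1, mu2),
        sds=(s1, s2),
        log_likelihood=ll_path[-1],
        n_iterations=n_iter,
        converged=converged,
        log_likelihood_path=ll_path,
    )


def plot_density(samples: dict[str, np.ndarray], ax=None):
    """Overlayed Gaussian-KDE density plot (Silverman bandwidth).

    Presentation convenience for visually comparing measurement
    distributions across conditions; not a tested statistic.
    """
    from scipy.stats import gaussian_kde
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, sample in samples.items():
        x = _clean(sample, name)
        kde = gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), 512)
        ax.plot(grid, kde(grid), label=name)
    ax.set_ylabel("density")
    ax.legend()
    return ax
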