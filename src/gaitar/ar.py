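"""Box–Jenkins identification and fitting of autoregressive models.

The modelled series is the interleaved vertical-GRF peak sequence of one limb
in one walking condition. Identification follows the classical workflow:
demean, inspect ACF/PACF (an AR(p) process has a PACF that cuts off after lag
p), fit by conditional least squares, then check residual normality with an
Anderson–Darling test. The fitted (φ1, φ2) pair feeds the stationarity
triangle analysis in :mod:`gaitar.triangle`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as _sps

from . import triangle as _tri

#: Critical value for the Anderson–Darling normality statistic (estimated mean
#: and variance, small-sample adjusted) at significance level 0.05.
AD_CRITICAL_005 = 0.752


def demean(series) -> tuple[np.ndarray, float]:
    """Centre a series about zero; return ``(centered, mean)``.

    The stored mean permits exact reconstruction; centring makes the AR
    intercept δ zero by construction.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 3:
        raise ValueError("series must have length >= 3")
    mean = float(x.mean())
    return x - mean, mean


def acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag (biased, divide-by-n form).

    acf(k) = Σ_{t=k+1..n} (y_t − ȳ)(y_{t−k} − ȳ) / Σ_t (y_t − ȳ)².

    The biased estimator guarantees a valid (positive semi-definite)
    correlation sequence, as the Durbin–Levinson recursion requires.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if not 0 < max_lag < n:
        raise ValueError("max_lag must satisfy 0 < max_lag < n")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValueError("constant series has undefined autocorrelation")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(np.dot(xc[k:], xc[:-k])) / denom
    return r


def _pacf_from_acf(r: np.ndarray) -> np.ndarray:
    """Durbin–Levinson recursion: PACF at lags 1..L from ACF at lags 0..L."""
    L = r.size - 1
    pacf = np.zeros(L)
    phi = np.array([r[1]])
    pacf[0] = r[1]
    v = 1.0 - r[1] * r[1]
    for k in range(2, L + 1):
        if v <= 0.0:
            break  # perfectly predictable series; remaining pacf is 0
        a = (r[k] - float(np.dot(phi, r[k - 1:0:-1]))) / v
        phi = np.concatenate([phi - a * phi[::-1], [a]])
        v *= 1.0 - a * a
        pacf[k - 1] = a
    return pacf


def pacf(series, max_lag: int) -> np.ndarray:
    """Sample partial autocorrelation at lags 1..max_lag (Durbin–Levinson).

    pacf(1) equals acf(1) by definition.
    """
    return _pacf_from_acf(acf(series, max_lag))


@dataclass(frozen=True)
class Correlogram:
    """ACF/PACF values with the ±1.96/√n white-noise confidence bound."""

    lags: np.ndarray          # 0..L
    acf: np.ndarray           # length L+1, acf[0] = 1
    pacf: np.ndarray          # length L, lags 1..L
    n: int
    conf_bound: float


def correlogram(series, max_lag: int) -> Correlogram:
    x = np.asarray(series, dtype=float)
    r = acf(x, max_lag)
    return Correlogram(
        lags=np.arange(max_lag + 1),
        acf=r,
        pacf=_pacf_from_acf(r),
        n=x.size,
        conf_bound=1.96 / np.sqrt(x.size),
    )


def characteristic_roots(phi1: float, phi2: float) -> np.ndarray:
    """Roots of the AR(2) characteristic polynomial m² − φ1 m − φ2.

    m = (φ1 ± sqrt(φ1² + 4 φ2)) / 2; the pair is complex-conjugate when the
    discriminant is negative. Returned sorted by descending modulus.
    """
    disc = phi1 * phi1 + 4.0 * phi2
    if disc >= 0.0:
        s = np.sqrt(disc)
        roots = np.array([(phi1 + s) / 2.0, (phi1 - s) / 2.0], dtype=complex)
    else:
        s = np.sqrt(-disc)
        roots = np.array([(phi1 + 1j * s) / 2.0, (phi1 - 1j * s) / 2.0])
    order = np.argsort(-np.abs(roots), kind="stable")
    return roots[order]


@dataclass(frozen=True)
class ARFit:
    """A fitted AR(p) model on a demeaned series.

    The model is y_t − μ = Σ φ_i (y_{t−i} − μ) + ε_t; equivalently
    δ = μ (1 − Σ φ_i) in the intercept form.
    """

    order: int
    coeffs: np.ndarray        # φ1..φp
    mean: float               # series mean removed before fitting
    sigma2: float             # innovation variance, RSS / (n_eff − p)
    resid: np.ndarray         # length n − p
    fitted: np.ndarray        # one-step predictions of the centered series, t > p
    roots: np.ndarray         # characteristic roots, |m| descending
    n: int
    method: str

    @property
    def phi1(self) -> float:
        return float(self.coeffs[0])

    @property
    def phi2(self) -> float:
        return float(self.coeffs[1]) if self.order >= 2 else 0.0

    @property
    def delta(self) -> float:
        """Intercept δ = μ(1 − Σφ) of the un-centered model form."""
        return self.mean * (1.0 - float(self.coeffs.sum()))

    @property
    def n_effective(self) -> int:
        return self.n - self.order

    @property
    def root_moduli(self) -> np.ndarray:
        return np.abs(self.roots)


def fit_ar(series, order: int = 2,
           method: Literal["cls", "yule_walker"] = "cls") -> ARFit:
    """Fit an AR(p) model by conditional least squares (default) to a series.

    The series is demeaned, then y_t is regressed on (y_{t−1}, …, y_{t−p})
    without intercept, minimising the conditional sum of squared one-step
    errors. ``method="yule_walker"`` instead solves the Yule–Walker equations
    (via statsmodels) on the demeaned series; residuals and σ² are computed
    the same way for both.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if order < 1:
        raise ValueError("order must be >= 1")
    if n < order + 10:
        raise ValueError(f"series of length {n} too short for AR({order}); need >= {order + 10}")
    xc, mean = demean(x)
    if np.ptp(xc) == 0.0:
        raise ValueError("constant series: singular design")

    y = xc[order:]
    X = np.column_stack([xc[order - k: n - k] for k in range(1, order + 1)])
    if method == "cls":
        coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < order:
            raise ValueError("singular design matrix in AR fit")
    elif method == "yule_walker":
        from statsmodels.regression.linear_model import yule_walker

        rho, _ = yule_walker(xc, order=order, method="mle")
        coeffs = np.asarray(rho, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")

    fitted = X @ coeffs
    resid = y - fitted
    sigma2 = float(resid @ resid) / (y.size - order)
    if order == 2:
        roots = characteristic_roots(float(coeffs[0]), float(coeffs[1]))
    else:
        # companion polynomial m^p − φ1 m^{p-1} − … − φp
        roots = np.roots(np.concatenate([[1.0], -coeffs]))
        roots = roots[np.argsort(-np.abs(roots), kind="stable")]
    return ARFit(order=order, coeffs=np.asarray(coeffs, dtype=float), mean=mean,
                 sigma2=sigma2, resid=resid, fitted=fitted, roots=roots,
                 n=n, method=method)


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Anderson–Darling normality check plus a residual histogram."""

    statistic: float          # raw A²
    adjusted_statistic: float  # A² (1 + 4/n − 25/n²)
    critical_value: float
    reject: bool              # True → normality rejected at α = 0.05
    alpha: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n: int


def anderson_darling_normality(values, alpha: float = 0.05) -> ResidualDiagnostics:
    """Composite Anderson–Darling test of normality (mean and variance estimated).

    The raw A² statistic is adjusted by the small-sample factor
    (1 + 4/n − 25/n²) and compared with the 0.752 critical value at α = 0.05.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 values for the Anderson-Darling test")
    if np.ptp(x) == 0.0:
        raise ValueError("zero-variance sample: normality test undefined")
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 is supported")
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = _sps.norm.cdf(z)
    # guard log(0) for extreme tail observations
    cdf = np.clip(cdf, 1e-300, 1.0 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1]))))
    adj = a2 * (1.0 + 4.0 / n - 25.0 / n**2)
    counts, edges = np.histogram(x, bins="auto")
    return ResidualDiagnostics(
        statistic=a2,
        adjusted_statistic=adj,
        critical_value=AD_CRITICAL_005,
        reject=adj > AD_CRITICAL_005,
        alpha=alpha,
        hist_counts=counts,
        hist_edges=edges,
        n=n,
    )


def residual_diagnostics(fit: ARFit, alpha: float = 0.05) -> ResidualDiagnostics:
    """Anderson–Darling normality test on the one-step residuals of a fit."""
    return anderson_darling_normality(fit.resid, alpha=alpha)


@dataclass(frozen=True)
class OrderSelection:
    """Recommended AR order with the correlogram evidence behind it."""

    order: int
    correlogram: Correlogram
    bound: float
    note: str


def select_order(series, max_order: int = 10) -> OrderSelection:
    """Recommend the AR order from the PACF cut-off rule.

    The recommended order is the largest lag k ≤ max_order whose sample PACF
    exceeds the ±1.96/√n white-noise bound; 0 if none does (white noise).
    """
    x = np.asarray(series, dtype=float)
    if max_order >= x.size / 4:
        raise ValueError("max_order must be < n/4")
    cg = correlogram(x, max_order)
    exceed = np.nonzero(np.abs(cg.pacf) > cg.conf_bound)[0]
    if exceed.size == 0:
        return OrderSelection(order=0, correlogram=cg, bound=cg.conf_bound,
                              note="no PACF lag exceeds the white-noise bound; order 0")
    order = int(exceed[-1] + 1)
    return OrderSelection(order=order, correlogram=cg, bound=cg.conf_bound,
                          note=f"largest PACF lag above +/-1.96/sqrt(n): {order}")


def fit_record(fit: ARFit, diagnostics: ResidualDiagnostics | None = None,
               **labels: object) -> dict:
    """Flatten a fit (and optional diagnostics) into a JSON-ready record."""
    member = _tri.is_stationary(fit.phi1, fit.phi2)
    rec: dict = dict(labels)
    rec.update(
        n=fit.n,
        order=fit.order,
        phi1=fit.phi1,
        phi2=fit.phi2,
        delta=fit.delta,
        mean=fit.mean,
        sigma2=fit.sigma2,
        roots=[{"re": float(m.real), "im": float(m.imag), "modulus": float(abs(m))}
               for m in fit.roots],
        stationary=member.inside,
        distance=_tri.distance_from_centroid(fit.phi1, fit.phi2),
    )
    if diagnostics is not None:
        rec["ad_stat"] = diagnostics.adjusted_statistic
        rec["ad_reject_normality"] = diagnostics.reject
    return rec
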