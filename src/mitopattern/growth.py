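"""Stromal-confinement growth model.

Island growth follows the exponential law Y = Y0 * exp(k(s) t); with the
growth time t fixed (day 4) and the confinement-dependent rate linear in
stromal density, k(s) = -k' s, the observable relationship is a single
exponential decay in s:

    Y(s) = Y0 * exp(-k' * s * t)

where s is the initial stromal seeding density (cells/mm²), t the growth
time (days) and k' the confinement rate constant (mm² cell⁻¹ day⁻¹).  The
same decay describes both the island area and the normalized high-potential
peak area.  Fitting is nonlinear least squares on the original scale with a
log-linear initialization; R² is reported on the original scale, matching
the nonlinear-regression convention of the source measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import LinearFit, linear_regression, InsufficientDataError, DegenerateDataError

__all__ = [
    "growth_model",
    "ConfinementDecayModel",
    "ConfinementDecayResults",
    "GrowthFit",
    "fit_exponential_decay",
    "fit_peak_area_decay",
    "linreg_peak_area_vs_density",
]


def growth_model(y0: float, k_prime: float, t: float, s) -> np.ndarray:
    """Exact model evaluation Y = Y0 * exp(-k' * s * t)."""
    if y0 <= 0:
        raise ValueError("Y0 must be positive")
    if t < 0:
        raise ValueError("growth time must be non-negative")
    s = np.asarray(s, dtype=float)
    return y0 * np.exp(-k_prime * s * t)


class ConfinementDecayModel:
    """Exponential confinement decay, statsmodels-style.

    Parameters
    ----------
    endog
        Observed sizes Y (island area in mm², or the dimensionless
        normalized peak area); all must be positive.
    exog
        Stromal seeding densities s (cells/mm²), one per observation.
    t_days
        Fixed growth time; not estimated.

    Examples
    --------
    >>> model = ConfinementDecayModel([3.14, 2.7, 2.3, 1.7],
    ...                               [0, 221, 442, 884], t_days=4)
    >>> res = model.fit()
    >>> res.k_prime  # doctest: +SKIP
    """

    def __init__(self, endog, exog, t_days: float = 4.0):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.shape != self.exog.shape or self.endog.ndim != 1:
            raise ValueError("endog and exog must be equal-length 1-D")
        if np.unique(self.exog).size < 3:
            raise InsufficientDataError("need >= 3 distinct stromal densities")
        if (self.endog <= 0).any():
            raise ValueError("all observed sizes must be positive (log-init undefined)")
        if t_days <= 0:
            raise ValueError("t_days must be positive")
        self.t_days = float(t_days)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, y: str = "Y", s: str = "s", t_days: float = 4.0
    ) -> "ConfinementDecayModel":
        return cls(df[y].to_numpy(), df[s].to_numpy(), t_days=t_days)

    def _start(self) -> tuple[float, float]:
        """Log-linear OLS start: ln Y = ln Y0 - (k' t) s."""
        fit = linear_regression(self.exog, np.log(self.endog))
        y0 = float(np.exp(fit.intercept))
        k_prime = float(-fit.slope / self.t_days)
        return y0, k_prime

    def fit(self, xtol: float = 1e-12, maxfev: int = 10000) -> "ConfinementDecayResults":
        y0_0, k_0 = self._start()
        flat = np.ptp(self.endog) == 0
        if flat:
            # degenerate: no decay information; report the mean with k' = 0
            return ConfinementDecayResults(
                self, np.array([float(self.endog.mean()), 0.0]),
                np.array([[np.nan, np.nan], [np.nan, np.nan]]),
                converged=True, flat_data=True,
            )

        def f(s, y0, k_prime):
            return y0 * np.exp(-k_prime * s * self.t_days)

        try:
            popt, pcov = curve_fit(
                f, self.exog, self.endog, p0=(y0_0, k_0),
                xtol=xtol, ftol=1e-12, gtol=1e-12, maxfev=maxfev,
            )
            converged = np.all(np.isfinite(popt))
        except RuntimeError:
            popt = np.array([y0_0, k_0])
            pcov = np.full((2, 2), np.nan)
            converged = False
        return ConfinementDecayResults(self, popt, pcov, converged=converged)


@dataclass
class ConfinementDecayResults:
    """Fit results: estimates, standard errors, goodness of fit."""

    model: ConfinementDecayModel
    params: np.ndarray                  # [Y0, k']
    cov: np.ndarray
    converged: bool
    flat_data: bool = False

    @property
    def y0(self) -> float:
        return float(self.params[0])

    @property
    def k_prime(self) -> float:
        return float(self.params[1])

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))

    @property
    def fittedvalues(self) -> np.ndarray:
        return growth_model(max(self.y0, np.finfo(float).tiny),
                            self.k_prime, self.model.t_days, self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rsquared(self) -> float:
        """R² on the original scale: 1 - SSR/SST."""
        y = self.model.endog
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            return float("nan")  # flat data: R² undefined
        return 1.0 - float((self.resid**2).sum()) / sst

    def predict(self, s) -> np.ndarray:
        return growth_model(self.y0, self.k_prime, self.model.t_days, s)

    def plot(self, ax=None, n_grid: int = 200):
        """Observed sizes vs stromal density with the fitted decay curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.exog
        ax.scatter(s, self.model.endog, label="observed")
        grid = np.linspace(0, max(s.max(), 1.0), n_grid)
        ax.plot(grid, self.predict(grid),
                label=f"fit: k'={self.k_prime:.3g}, R²={self.rsquared:.3f}")
        ax.set_xlabel("stromal density (cells/mm²)")
        ax.set_ylabel("size Y")
        ax.legend()
        return ax

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Confinement decay fit: Y = Y0 * exp(-k' s t)",
            f"  n obs            : {self.model.endog.size}",
            f"  t (fixed, days)  : {self.model.t_days:g}",
            f"  Y0               : {self.y0:.6g} (SE {se[0]:.3g})",
            f"  k' (mm²/cell/day): {self.k_prime:.6g} (SE {se[1]:.3g})",
            f"  R² (orig. scale) : {self.rsquared:.4f}",
            f"  converged        : {self.converged}" + ("  [flat data]" if self.flat_data else ""),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        se = self.bse
        return {
            "Y0": self.y0,
            "Y0_se": None if not np.isfinite(se[0]) else float(se[0]),
            "k_prime": self.k_prime,
            "k_prime_se": None if not np.isfinite(se[1]) else float(se[1]),
            "t_days": self.model.t_days,
            "r_squared": None if not np.isfinite(self.rsquared) else float(self.rsquared),
            "converged": bool(self.converged),
            "flat_data": bool(self.flat_data),
        }


#: alias: the results object is the "growth fit" the pipeline reports
GrowthFit = ConfinementDecayResults


def fit_exponential_decay(observations, t_days: float = 4.0) -> ConfinementDecayResults:
    """Fit the confinement decay to (s, Y) observations.

    ``observations`` is an iterable of (s, Y) pairs, or a DataFrame with
    ``s``/``Y`` columns.
    """
    if isinstance(observations, pd.DataFrame):
        model = ConfinementDecayModel.from_dataframe(observations, t_days=t_days)
    else:
        arr = np.asarray(list(observations), dtype=float)
        model = ConfinementDecayModel(arr[:, 1], arr[:, 0], t_days=t_days)
    return model.fit()


def fit_peak_area_decay(observations, t_days: float = 4.0) -> ConfinementDecayResults:
    """Same decay law fitted to normalized peak areas (dimensionless Y)."""
    res = fit_exponential_decay(observations, t_days=t_days)
    if (res.model.endog <= 0).any():  # pragma: no cover - guarded upstream
        raise ValueError("peak areas must be positive")
    return res


def linreg_peak_area_vs_density(points) -> LinearFit:
    """OLS of normalized peak area against interfacial cancer-cell density.

    On confinement-dominated data the slope is negative (denser, smaller
    interfacial cells go with a thinner high-potential band).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (density, peak_area) pairs")
    if pts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 points")
    if np.ptp(pts[:, 0]) == 0:
        raise DegenerateDataError("zero variance in density")
    return linear_regression(pts[:, 0], pts[:, 1])
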