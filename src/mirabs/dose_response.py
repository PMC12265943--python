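"""Constrained logistic dose-response fit for reporter cleavage.

The normalized reporter level L as a function of miRNA abundance c
(molecules per 10 pg total RNA) follows an inhibitor dose-response curve

    L(c) = 1 / (1 + exp(slope * (IC50 - c)))

with slope <= 0: the level is ~1 for c << IC50, exactly 0.5 at c = IC50,
and approaches 0 as c grows.  The fit is a bounded nonlinear least squares
(Trust Region Reflective) under the physically meaningful box
-100 <= slope <= 0 and 1 <= IC50 <= 10000, limited to 10,000 function
evaluations.  The standard error of IC50 comes from the parameter covariance
at the solution; goodness of fit is the ordinary R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

IC50_BOUNDS = (1.0, 10_000.0)
SLOPE_BOUNDS = (-100.0, 0.0)
MAX_NFEV = 10_000


def repression_model(conc, ic50: float, slope: float):
    """Normalized reporter level at miRNA abundance ``conc``.

    Overflow-guarded: the exponent is clipped to +-700 before exponentiation.
    Depends on concentration only through ``ic50 - conc``.
    """
    conc = np.asarray(conc, dtype=float)
    z = np.clip(slope * (ic50 - conc), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    May be negative for fits worse than the mean; raises when the
    observations have zero variance (SS_tot = 0 leaves R^2 undefined).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observations have zero variance")
    ss_res = float(((observed - predicted) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def normalize_reporter_level(
    reporter_molecules: float,
    control_molecules: float,
    frac_transfected_reporter: float = 1.0,
    frac_transfected_control: float = 1.0,
) -> float:
    """Normalize raw reporter abundance to the unrepressed control.

    Each absolute abundance is divided by the fraction of transfected cells
    (measured by BFP fluorescence in the reporter assay) before taking the
    reporter/control ratio, so the level reflects expression within the
    transfected population only.
    """
    if control_molecules <= 0:
        raise ValueError("control reporter abundance must be positive")
    if not 0 < frac_transfected_reporter <= 1 or not 0 < frac_transfected_control <= 1:
        raise ValueError("transfected fractions must be in (0, 1]")
    return (reporter_molecules / frac_transfected_reporter) / (
        control_molecules / frac_transfected_control
    )


@dataclass
class DoseResponseFit:
    """Result of a constrained dose-response fit."""

    ic50: float
    slope: float
    ic50_se: float
    slope_se: float
    r_squared: float
    converged: bool
    n_obs: int
    degenerate: bool = False


class DoseResponseCurve:
    """Sklearn-style estimator for the constrained logistic dose-response.

    Parameters
    ----------
    ic50_bounds, slope_bounds : tuple of float
        Box constraints on the two parameters.
    max_nfev : int
        Cap on function evaluations for the Trust Region Reflective solver.

    Fitted attributes (trailing underscore): ``ic50_``, ``slope_``,
    ``ic50_se_``, ``slope_se_``, ``r_squared_`` (raw, may be negative),
    ``r_squared_clamped_``, ``converged_``, ``degenerate_``, ``n_obs_``.
    """

    def __init__(
        self,
        ic50_bounds: tuple[float, float] = IC50_BOUNDS,
        slope_bounds: tuple[float, float] = SLOPE_BOUNDS,
        max_nfev: int = MAX_NFEV,
    ) -> None:
        self.ic50_bounds = ic50_bounds
        self.slope_bounds = slope_bounds
        self.max_nfev = max_nfev

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "ic50_bounds": self.ic50_bounds,
            "slope_bounds": self.slope_bounds,
            "max_nfev": self.max_nfev,
        }

    def set_params(self, **params) -> "DoseResponseCurve":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-D concentrations or a single-column 2-D array")
        return X

    def _initial_guess(self, conc: np.ndarray, level: np.ndarray) -> tuple[float, float]:
        # start IC50 at the concentration whose level is nearest half-maximum,
        # slope at -4/IC50 (the logistic transition width heuristic)
        ic50_lo, ic50_hi = self.ic50_bounds
        ic50_init = float(np.clip(conc[np.argmin(np.abs(level - 0.5))], ic50_lo, ic50_hi))
        if ic50_init <= 0:
            ic50_init = max(ic50_lo, 1.0)
        slope_init = float(np.clip(-4.0 / ic50_init, self.slope_bounds[0], -1e-12))
        return ic50_init, slope_init

    def fit(self, X, y) -> "DoseResponseCurve":
        conc = self._as_1d(X)
        level = np.asarray(y, dtype=float)
        if conc.shape != level.shape:
            raise ValueError("X and y must have the same length")
        if conc.size < 3:
            raise ValueError("need at least 3 observations")
        if np.unique(conc).size < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if (conc < 0).any():
            raise ValueError("concentrations must be >= 0")

        self.n_obs_ = int(conc.size)
        self.degenerate_ = bool(np.ptp(level) == 0)
        p0 = self._initial_guess(conc, level)
        bounds = (
            [self.ic50_bounds[0], self.slope_bounds[0]],
            [self.ic50_bounds[1], self.slope_bounds[1]],
        )
        try:
            popt, pcov = curve_fit(
                repression_model,
                conc,
                level,
                p0=p0,
                bounds=bounds,
                method="trf",
                maxfev=self.max_nfev,
            )
            self.converged_ = True
        except RuntimeError:
            popt = np.array(p0)
            pcov = np.full((2, 2), np.nan)
            self.converged_ = False

        self.ic50_, self.slope_ = float(popt[0]), float(popt[1])
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        self.ic50_se_, self.slope_se_ = float(se[0]), float(se[1])
        if not np.all(np.isfinite(pcov)):
            self.degenerate_ = True
        pred = repression_model(conc, self.ic50_, self.slope_)
        if np.ptp(level) == 0:
            self.r_squared_ = float("nan")
            self.converged_ = False
        else:
            self.r_squared_ = r_squared(level, pred)
        self.r_squared_clamped_ = max(0.0, self.r_squared_) if np.isfinite(self.r_squared_) else float("nan")
        return self

    def predict(self, X):
        if not hasattr(self, "ic50_"):
            raise RuntimeError("estimator is not fitted")
        return repression_model(self._as_1d(X), self.ic50_, self.slope_)

    def result_(self) -> DoseResponseFit:
        return DoseResponseFit(
            ic50=self.ic50_,
            slope=self.slope_,
            ic50_se=self.ic50_se_,
            slope_se=self.slope_se_,
            r_squared=self.r_squared_,
            converged=self.converged_,
            n_obs=self.n_obs_,
            degenerate=self.degenerate_,
        )


def fit_per_replicate(observations) -> tuple[float, float, int]:
    """Fit each replicate separately; return (mean IC50, sample SD, n fits).

    An alternative uncertainty estimate to the covariance-based standard
    error: the spread of IC50 across independent replicate fits.  SD is NaN
    with a single replicate.
    """
    if "replicate" not in observations.columns:
        raise ValueError("observations need a 'replicate' column")
    estimates = []
    for _, grp in observations.groupby("replicate"):
        estimates.append(fit_dose_response(grp).ic50)
    arr = np.asarray(estimates, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, int(arr.size)


def fit_dose_response(observations) -> DoseResponseFit:
    """Fit the constrained dose-response to a table of observations.

    ``observations`` is a DataFrame with columns ``mirna_concentration`` and
    ``level`` (replicates as extra rows), or a (concentrations, levels) pair.
    """
    if hasattr(observations, "columns"):
        conc = observations["mirna_concentration"].to_numpy(dtype=float)
        level = observations["level"].to_numpy(dtype=float)
    else:
        conc, level = observations
    est = DoseResponseCurve().fit(conc, level)
    return est.result_()
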