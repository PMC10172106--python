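"""Pressure-volume modelling: Venegas sigmoid fits, empirical opening/closing
pressures, hysteresis detection, and EIT-style volume calibration.

The core object is :class:`VenegasModel`, a four-parameter sigmoid

    V(P) = a + b / (1 + exp((c - P) / d))

fitted to (pressure, value) pairs by bounded non-linear least squares, where
``a`` is the lower asymptote, ``b`` the span (upper asymptote ``a + b``),
``c`` the inflection pressure (cm H2O) and ``d > 0`` the width (cm H2O).
``fit()`` returns a :class:`VenegasResults` carrying the estimates, their
standard errors, adjusted R^2, a runs test on the residuals and a
``summary()`` table, in the spirit of statsmodels results objects.

Rule-based detectors (largest-step opening/closing pressures, limb-difference
hysteresis) and the affine impedance-to-volume calibration are plain functions
over :class:`PVSeries` / :class:`EITRecord` inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, FitError, ValidationError

PRESSURE_RANGE = (0.0, 35.0)  # cm H2O, atmospheric to maximal inflation

__all__ = [
    "PVSeries",
    "StepPressures",
    "HysteresisResult",
    "VenegasModel",
    "VenegasResults",
    "EITCalibration",
    "venegas_curve",
    "venegas_derivative",
    "empirical_pressures",
    "detect_hysteresis",
    "fit_venegas",
    "predicted_pressures",
    "runs_test",
    "calibrate_eit",
    "pool_series",
]


# ---------------------------------------------------------------------------
# Series container
# ---------------------------------------------------------------------------

@dataclass
class PVSeries:
    """Ordered (pressure, value) points for one subject and signal.

    ``signal_kind`` is one of ``volume_total``, ``volume_regional:<region>``
    or ``delta_mgv``; values are ml/kg for volumes and arbitrary greyscale
    units for delta_mgv. Each limb is ordered by acquisition: inflation by
    increasing pressure, deflation by decreasing pressure.
    """

    lamb_id: str
    signal_kind: str
    inflation_pressures: np.ndarray
    inflation_values: np.ndarray
    deflation_pressures: np.ndarray
    deflation_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("inflation_pressures", "inflation_values",
                     "deflation_pressures", "deflation_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.inflation_pressures.shape != self.inflation_values.shape:
            raise ValidationError("inflation pressures/values length mismatch")
        if self.deflation_pressures.shape != self.deflation_values.shape:
            raise ValidationError("deflation pressures/values length mismatch")

    def matched_pressures(self) -> np.ndarray:
        """Pressures present on both limbs, ascending."""
        return np.intersect1d(self.inflation_pressures, self.deflation_pressures)

    def limb(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if which == "inflation":
            return self.inflation_pressures, self.inflation_values
        if which == "deflation":
            return self.deflation_pressures, self.deflation_values
        raise ValueError(f"unknown limb {which!r}")


def pool_series(series: Sequence[PVSeries]) -> PVSeries:
    """Concatenate per-subject series into one pooled series per limb.

    No averaging is applied: every subject contributes all of its points, so
    a pooled fit weights subjects by their number of acquisitions. All series
    must share a signal kind.
    """
    if not series:
        raise ValidationError("cannot pool an empty collection of series")
    kinds = {s.signal_kind for s in series}
    if len(kinds) > 1:
        raise ValidationError(f"mixed signal kinds in pool: {sorted(kinds)}")
    return PVSeries(
        lamb_id="pooled",
        signal_kind=series[0].signal_kind,
        inflation_pressures=np.concatenate([s.inflation_pressures for s in series]),
        inflation_values=np.concatenate([s.inflation_values for s in series]),
        deflation_pressures=np.concatenate([s.deflation_pressures for s in series]),
        deflation_values=np.concatenate([s.deflation_values for s in series]),
    )


# ---------------------------------------------------------------------------
# Empirical opening / closing pressures and hysteresis
# ---------------------------------------------------------------------------

@dataclass
class StepPressures:
    """Largest-step opening and closing pressures on the acquisition grid.

    The opening pressure is the pressure immediately preceding the largest
    increase along the inflation limb; the closing pressure the one
    immediately preceding the largest decrease along the deflation limb.
    Either is ``None`` (with ``detectable=False``) when every step is zero.
    """

    opening_pressure: float | None
    closing_pressure: float | None
    opening_step_change: float
    closing_step_change: float

    @property
    def detectable(self) -> bool:
        return self.opening_pressure is not None or self.closing_pressure is not None


def empirical_pressures(series: PVSeries) -> StepPressures:
    """Locate opening/closing pressures as the largest single-step change.

    Ties are broken toward the lower pressure on inflation and the higher
    pressure on deflation (the first step encountered in acquisition order),
    which is the conservative reading for recruitment/derecruitment.
    """
    if len(series.inflation_values) < 2 or len(series.deflation_values) < 2:
        raise ValidationError("need at least two points per limb")

    inc = np.diff(series.inflation_values)
    dec = -np.diff(series.deflation_values)  # positive when value falls

    if np.all(inc == 0):
        opening, o_step = None, 0.0
    else:
        i = int(np.argmax(inc))  # first maximal step -> lower pressure
        opening, o_step = float(series.inflation_pressures[i]), float(inc[i])

    if np.all(dec == 0):
        closing, c_step = None, 0.0
    else:
        j = int(np.argmax(dec))  # acquisition order descends -> higher pressure
        closing, c_step = float(series.deflation_pressures[j]), float(dec[j])

    return StepPressures(opening, closing, o_step, c_step)


@dataclass
class HysteresisResult:
    """Limb-separation summary at pressures present on both limbs.

    ``present`` applies the descriptive rule: mean paired deflation-minus-
    inflation difference strictly positive. The one-sided Wilcoxon p and the
    trapezoidal loop area are reported as supporting evidence only.
    """

    present: bool
    mean_paired_difference: float
    loop_area: float
    wilcoxon_p: float
    n_matched: int


def detect_hysteresis(series: PVSeries) -> HysteresisResult:
    matched = series.matched_pressures()
    if matched.size < 2:
        raise ValidationError("need >= 2 pressures present on both limbs")

    inf_at = {p: v for p, v in zip(series.inflation_pressures, series.inflation_values)}
    def_at = {p: v for p, v in zip(series.deflation_pressures, series.deflation_values)}
    diffs = np.array([def_at[p] - inf_at[p] for p in matched])

    mean_diff = float(np.mean(diffs))
    loop_area = float(np.trapezoid(diffs, matched))

    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, alternative="greater",
                                 zero_method="wilcox").pvalue)

    return HysteresisResult(
        present=mean_diff > 0,
        mean_paired_difference=mean_diff,
        loop_area=loop_area,
        wilcoxon_p=p,
        n_matched=int(matched.size),
    )


# ---------------------------------------------------------------------------
# Venegas sigmoid model
# ---------------------------------------------------------------------------

def venegas_curve(pressure, a: float, b: float, c: float, d: float):
    """V(P) = a + b / (1 + exp((c - P) / d)); requires d > 0 (and b > 0 for
    a physically increasing curve)."""
    if d <= 0:
        raise ValidationError("sigmoid width d must be positive")
    pressure = np.asarray(pressure, dtype=float)
    return a + b / (1.0 + np.exp((c - pressure) / d))


def venegas_derivative(pressure, b: float, c: float, d: float):
    """dV/dP = (b/d) s (1 - s) with s = 1/(1+exp((c-P)/d)); peaks at P = c."""
    if d <= 0:
        raise ValidationError("sigmoid width d must be positive")
    pressure = np.asarray(pressure, dtype=float)
    s = 1.0 / (1.0 + np.exp((c - pressure) / d))
    return (b / d) * s * (1.0 - s)


class VenegasModel:
    """Four-parameter sigmoid PV model for one limb of a manoeuvre.

    Parameters
    ----------
    pressure, value : array-like
        Paired observations; at least 5 points (4 parameters + 1) with
        non-degenerate values are required to fit.

    Examples
    --------
    >>> m = VenegasModel([0, 5, 10, 15, 20, 25, 30, 35],
    ...                  venegas_curve([0, 5, 10, 15, 20, 25, 30, 35],
    ...                                2, 28, 22, 3))
    >>> res = m.fit()
    >>> round(res.params["c"], 6)
    22.0
    """

    param_names = ("a", "b", "c", "d")

    def __init__(self, pressure, value):
        self.pressure = np.asarray(pressure, dtype=float)
        self.value = np.asarray(value, dtype=float)
        if self.pressure.shape != self.value.shape or self.pressure.ndim != 1:
            raise ValidationError("pressure and value must be equal-length 1-D")

    @classmethod
    def from_series(cls, series: PVSeries, limb: str) -> "VenegasModel":
        p, v = series.limb(limb)
        return cls(p, v)

    def _initial_guess(self) -> np.ndarray:
        vmin, vmax = float(self.value.min()), float(self.value.max())
        a0 = vmin
        b0 = max(vmax - vmin, 1e-6)
        mid = (vmin + vmax) / 2.0
        c0 = float(self.pressure[np.argmin(np.abs(self.value - mid))])
        d0 = max((self.pressure.max() - self.pressure.min()) / 8.0, 1e-3)
        return np.array([a0, b0, c0, d0])

    def fit(self, n_starts: int = 5, seed: int = 0) -> "VenegasResults":
        """Bounded least squares with multistart over jittered initialisations.

        Five jittered starts (seeded) guard against the flat-tail local minima
        of the sigmoid; the lowest residual sum of squares wins. Bounds keep
        b > 0 and d > 0.
        """
        n = self.value.size
        if n < 5:
            raise ValidationError("need >= 5 points to fit 4 parameters")
        if np.ptp(self.value) == 0:
            raise ValidationError("values have zero range; nothing to fit")

        base = self._initial_guess()
        rng = np.random.default_rng(seed)
        lo = np.array([-np.inf, 1e-9, -np.inf, 1e-9])
        hi = np.array([np.inf, np.inf, np.inf, np.inf])

        best = None
        for k in range(max(1, n_starts)):
            x0 = base.copy()
            if k > 0:
                x0[0] += rng.normal(0, 0.1 * base[1])
                x0[1] *= rng.uniform(0.5, 2.0)
                x0[2] += rng.normal(0, 0.15 * np.ptp(self.pressure) + 1e-9)
                x0[3] *= rng.uniform(0.5, 2.0)
            x0 = np.clip(x0, lo + 1e-12, None)
            try:
                sol = optimize.least_squares(
                    lambda th: venegas_curve(self.pressure, *th) - self.value,
                    x0, bounds=(lo, hi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:  # noqa: BLE001 - a failed start is not fatal
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError("sigmoid fit failed to converge from every start")
        return VenegasResults(self, best)


class VenegasResults:
    """Fit results for :class:`VenegasModel`: estimates, uncertainties and
    goodness-of-fit diagnostics."""

    def __init__(self, model: VenegasModel, solution) -> None:
        self.model = model
        self._solution = solution
        a, b, c, d = solution.x
        self.params = {"a": float(a), "b": float(b), "c": float(c), "d": float(d)}
        self.converged = bool(solution.success)
        self.fittedvalues = venegas_curve(model.pressure, a, b, c, d)
        self.resid = model.value - self.fittedvalues
        self.nobs = model.value.size
        self.bse = self._standard_errors()
        sst = float(np.sum((model.value - model.value.mean()) ** 2))
        sse = float(np.sum(self.resid ** 2))
        self.rsquared = 1.0 - sse / sst if sst > 0 else float("nan")
        n = self.nobs
        # adjusted for the 4 fitted parameters: 1-(1-R^2)(n-1)/(n-5)
        self.rsquared_adj = (1.0 - (1.0 - self.rsquared) * (n - 1) / (n - 5)
                             if n > 5 else float("nan"))
        try:
            self.runs_p = runs_test(self.resid)
        except ValidationError:  # (near-)perfect fit: no non-zero residuals
            self.runs_p = float("nan")

    def _standard_errors(self) -> dict[str, float]:
        J = self._solution.jac
        dof = max(self.nobs - 4, 1)
        s2 = 2.0 * self._solution.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(4, np.nan)
        return dict(zip(VenegasModel.param_names, map(float, se)))

    def predict(self, pressure):
        return venegas_curve(pressure, **self.params)

    def derivative(self, pressure):
        p = self.params
        return venegas_derivative(pressure, p["b"], p["c"], p["d"])

    def predicted_pressure(self, grid_step: float = 0.1,
                           pressure_range: tuple[float, float] = PRESSURE_RANGE) -> float:
        """Pressure of maximal rate of change: peak of dV/dP on a dense grid.

        Analytically the peak sits at P = c; the grid argmax is used so the
        answer stays inside the physiological range even when c falls outside
        it (then a boundary warning is emitted and the boundary argmax is
        returned).
        """
        lo, hi = pressure_range
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        peak = float(grid[np.argmax(self.derivative(grid))])
        c = self.params["c"]
        if not (lo <= c <= hi):
            warnings.warn(
                f"inflection c={c:.2f} cm H2O outside [{lo}, {hi}]; "
                "reporting boundary argmax", stacklevel=2)
        elif abs(peak - c) > grid_step / 2 + 1e-9:
            warnings.warn("grid argmax disagrees with analytic peak at c",
                          stacklevel=2)
        return peak

    def summary(self) -> str:
        lines = [
            "Venegas sigmoid fit  V(P) = a + b/(1+exp((c-P)/d))",
            f"  n obs: {self.nobs}   converged: {self.converged}",
            f"  R2: {self.rsquared:.4f}   adj R2: {self.rsquared_adj:.4f}"
            f"   runs test p: {self.runs_p:.3f}",
            "  param    estimate      std err",
        ]
        for name in VenegasModel.param_names:
            lines.append(f"  {name:>5} {self.params[name]:12.4f} {self.bse[name]:12.4f}")
        return "\n".join(lines)


def fit_venegas(pressure, value, n_starts: int = 5, seed: int = 0) -> VenegasResults:
    """Functional wrapper: ``VenegasModel(pressure, value).fit(...)``."""
    return VenegasModel(pressure, value).fit(n_starts=n_starts, seed=seed)


def predicted_pressures(fit_inflation: VenegasResults, fit_deflation: VenegasResults,
                        grid_step: float = 0.1) -> tuple[float, float]:
    """Model-predicted (opening, closing) pressures from the two limb fits."""
    if not (fit_inflation.converged and fit_deflation.converged):
        raise FitError("both limb fits must have converged")
    return (fit_inflation.predicted_pressure(grid_step),
            fit_deflation.predicted_pressure(grid_step))


# ---------------------------------------------------------------------------
# Wald-Wolfowitz runs test
# ---------------------------------------------------------------------------

def _runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact distribution of the number of runs given n1 positive and n2
    negative signs, all arrangements equally likely."""
    total = math.comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for k in range(1, min(n1, n2) + 1):
        pmf[2 * k] = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1) / total
        odd = (math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k)
               + math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1))
        if odd:
            pmf[2 * k + 1] = odd / total
    return pmf


def runs_test(residuals, exact_max_n: int = 20) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs.

    Zero residuals are dropped. The exact conditional distribution of the run
    count is used for n <= ``exact_max_n``; beyond that a normal approximation
    with continuity correction. With all residuals of one sign the single-run
    arrangement is the only one possible conditional on the sign counts, so
    p = 1.
    """
    resid = np.asarray(residuals, dtype=float)
    # squash numerical dust from near-perfect fits before taking signs
    scale = np.max(np.abs(resid)) if resid.size else 0.0
    if scale > 0:
        resid = np.where(np.abs(resid) < 1e-10 * scale, 0.0, resid)
    signs = np.sign(resid)
    signs = signs[signs != 0]
    if signs.size < 2:
        raise ValidationError("need >= 2 non-zero residuals for a runs test")
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    if n1 == 0 or n2 == 0:
        return 1.0
    n = n1 + n2
    if n <= exact_max_n:
        pmf = _runs_pmf(n1, n2)
        p_low = sum(p for r, p in pmf.items() if r <= runs)
        p_high = sum(p for r, p in pmf.items() if r >= runs)
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n ** 2 * (n - 1))
    z = (abs(runs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))


# ---------------------------------------------------------------------------
# EIT-style calibration
# ---------------------------------------------------------------------------

REGIONS = ("ventral", "central", "dorsal")


@dataclass
class EITCalibration:
    """Affine impedance-to-volume calibration and regional partition.

    ``slope``/``intercept`` map the right-whole impedance channel to the
    super-syringe volume scale. ``weights`` are the regional shares obtained
    from the regression of each regional channel on the right-whole channel
    (constant offsets cancel, so the shares sum to one). ``volumes`` holds
    the calibrated whole-lung volume and its regional partition at every
    record sample; the regions sum to the whole by construction.
    """

    slope: float
    intercept: float
    weights: dict[str, float]
    volumes: dict[str, np.ndarray] = field(repr=False)


def calibrate_eit(record) -> EITCalibration:
    """Calibrate a relative-impedance record against super-syringe volumes.

    The whole-lung time course is mapped to volume by least-squares affine
    regression; each region's channel is regressed on the whole-lung channel
    to obtain its share of the calibrated volume. For a record that is affine
    in true volume (as the synthetic generator produces), the inversion is
    exact.
    """
    z = np.asarray(record.z_right_whole, dtype=float)
    v = np.asarray(record.syringe_volumes, dtype=float)
    if z.size < 2 or np.unique(v).size < 2:
        raise CalibrationError("need >= 2 distinct syringe volumes")
    if np.ptp(z) == 0:
        raise CalibrationError("zero-variance impedance signal")

    slope, intercept = np.polyfit(z, v, 1)
    whole = slope * z + intercept

    weights: dict[str, float] = {}
    volumes: dict[str, np.ndarray] = {"right_whole": whole}
    for region in REGIONS:
        zr = np.asarray(getattr(record, f"z_{region}"), dtype=float)
        w = float(np.polyfit(z, zr, 1)[0])
        weights[region] = w
        volumes[region] = w * whole
    return EITCalibration(slope=float(slope), intercept=float(intercept),
                          weights=weights, volumes=volumes)
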