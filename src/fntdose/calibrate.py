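"""Detector calibration: polar-angle intensity correction, inter-detector
sensitivity normalisation, and the intensity-to-LET conversion.

The central object is the logistic angular-response model

    y(theta) = a / (1 + exp(b * (theta - c))) + 1 - a / (1 + exp(-b * c))

which describes the relative track-spot intensity as a function of the track
polar angle theta (degrees).  The constant offset makes y(0) = 1 exactly, so
measured intensities divided by y(theta) are referred back to normal
incidence, where the intensity-to-LET calibration applies.

Sensitivity correction uses tracks from an alpha reference irradiation: the
mean track intensity of a constant-quality source is fitted per detector and
divided by a fleet reference, yielding a dimensionless factor ``s`` that all
intensities of that detector are divided by.

The LET calibration itself is pluggable (log-linear, power law or a table of
knots); any strictly monotone, invertible mapping between corrected intensity
(a.u.) and LET in water (keV/um) is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, signal, stats

from .errors import ConfigurationError, DataError, DomainError, FitError

__all__ = [
    "AngleCorrectionModel",
    "AngleCorrectionFit",
    "SensitivityFactor",
    "LETCalibration",
    "PeakFit",
    "eval_angle_correction",
    "correct_intensity",
    "fit_angle_histogram",
    "fit_intensity_peak",
    "fit_angle_correction",
    "compute_sensitivity",
    "intensity_to_let",
]


# --------------------------------------------------------------------------
# Angular intensity correction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleCorrectionModel:
    """Logistic angular-response model with parameters ``a`` (dimensionless
    amplitude), ``b`` (1/degree steepness) and ``c`` (degrees, inflection).

    For a, b, c > 0 the curve decreases strictly from y(0) = 1 towards the
    asymptote ``1 - a / (1 + exp(-b c))``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c >= 0):
            raise ConfigurationError(
                f"AngleCorrectionModel requires a, b > 0 and c >= 0, "
                f"got a={self.a}, b={self.b}, c={self.c}"
            )

    @property
    def y_infinity(self) -> float:
        """Large-angle limit of the relative intensity."""
        return 1.0 - self.a / (1.0 + np.exp(-self.b * self.c))

    @property
    def max_correction_factor(self) -> float:
        """Largest intensity correction the model can apply, 1 / y_inf."""
        return 1.0 / self.y_infinity

    def __call__(self, theta_deg):
        return eval_angle_correction(theta_deg, self)


def _logistic(theta, a, b, c):
    return a / (1.0 + np.exp(b * (theta - c))) + 1.0 - a / (1.0 + np.exp(-b * c))


def eval_angle_correction(theta_deg, model: AngleCorrectionModel):
    """Relative spot intensity y(theta) for polar angles in [0, 90) degrees.

    Raises :class:`DomainError` for angles outside the physical domain of
    surface-crossing tracks.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 90):
        raise DomainError(f"polar angle must lie in [0, 90), got {theta_deg!r}")
    out = _logistic(theta, model.a, model.b, model.c)
    return float(out) if np.isscalar(theta_deg) else out


def correct_intensity(intensity, theta_deg, model: AngleCorrectionModel):
    """Refer a measured intensity back to normal incidence: I / y(theta)."""
    i = np.asarray(intensity, dtype=float)
    if np.any(i < 0):
        raise DomainError("intensity must be non-negative")
    y = eval_angle_correction(theta_deg, model)
    if np.any(np.asarray(y) <= 0):
        raise DomainError(
            "angle-correction model evaluates to a non-positive relative "
            "intensity; the parameter set is outside its validity range"
        )
    out = i / y
    return float(out) if np.isscalar(intensity) else out


# --------------------------------------------------------------------------
# Histogram fits
# --------------------------------------------------------------------------

@dataclass
class PeakFit:
    mean: float
    sigma: float
    amplitude: float = float("nan")
    r_squared: float = float("nan")
    poor_fit: bool = False


def _gauss_sum(x, *p):
    """Sum of len(p)//3 Gaussians, parameters (amp, mean, sigma) each."""
    y = np.zeros_like(x, dtype=float)
    for amp, mu, sig in zip(p[0::3], p[1::3], p[2::3]):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def fit_angle_histogram(
    angles_deg: Sequence[float],
    n_components: int = 4,
    bin_deg: float = 1.0,
):
    """Fit a sum of ``n_components`` Gaussians to the track polar-angle
    histogram (1 degree bins by default) and return the component means and
    sigmas, sorted by mean.

    Used to locate the mean track angle of each exposure when a detector was
    irradiated at several nominal angles.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise DataError("fit_angle_histogram needs at least one angle")
    edges = np.arange(0.0, 90.0 + bin_deg, bin_deg)
    counts, edges = np.histogram(angles, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initial guesses from the largest local maxima of the histogram
    peaks, props = signal.find_peaks(counts, height=1)
    order = np.argsort(props["peak_heights"])[::-1]
    guesses = list(centers[peaks[order[:n_components]]])
    while len(guesses) < n_components:  # fall back to quantile spread
        q = (len(guesses) + 0.5) / n_components
        guesses.append(float(np.quantile(angles, q)))
    guesses = sorted(guesses)

    p0, lo, hi = [], [], []
    for mu in guesses:
        p0 += [max(counts.max(), 1.0), mu, 2.0]
        lo += [0.0, 0.0, bin_deg / 4]
        hi += [np.inf, 90.0, 45.0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_sum, centers, counts, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        resid = np.linalg.norm(counts - _gauss_sum(centers, *p0))
        raise FitError(
            f"angle-histogram fit did not converge: {exc}",
            p0=p0, residual_norm=float(resid),
        ) from exc
    means = np.asarray(popt[1::3])
    sigmas = np.abs(np.asarray(popt[2::3]))
    order = np.argsort(means)
    return means[order], sigmas[order]


def fit_intensity_peak(
    intensities: Sequence[float],
    bin_au: float = 100.0,
    min_count: int = 10,
) -> PeakFit:
    """Fit a single Gaussian to the binned track-intensity histogram
    (default bin width 100 a.u.) and return the peak position and width.

    Degenerate input (all values equal) returns ``(value, 0)`` with a
    warning; a poor fit (R^2 < 0.9, e.g. bimodal input) sets ``poor_fit``.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < min_count:
        raise DataError(
            f"fit_intensity_peak needs at least {min_count} values, got {x.size}"
        )
    if np.ptp(x) == 0:
        warnings.warn("all intensities identical; returning a zero-width peak")
        return PeakFit(mean=float(x[0]), sigma=0.0, amplitude=float(x.size), r_squared=1.0)

    lo = np.floor(x.min() / bin_au) * bin_au
    hi = np.ceil(x.max() / bin_au) * bin_au + bin_au
    edges = np.arange(lo, hi + bin_au, bin_au)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    p0 = [counts.max(), centers[np.argmax(counts)], max(x.std(), bin_au)]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_sum, centers, counts, p0=p0,
            bounds=([0, lo, bin_au / 10], [np.inf, hi, hi - lo]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"intensity-peak fit did not converge: {exc}", p0=p0) from exc

    fitted = _gauss_sum(centers, *popt)
    ss_res = float(np.sum((counts - fitted) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    poor = r2 < 0.9
    if poor:
        warnings.warn(f"intensity-peak fit is poor (R^2={r2:.3f}); "
                      "the distribution may be multimodal")
    return PeakFit(mean=float(popt[1]), sigma=float(abs(popt[2])),
                   amplitude=float(popt[0]), r_squared=r2, poor_fit=poor)


# --------------------------------------------------------------------------
# Fitting the angular model to normalised intensity points
# --------------------------------------------------------------------------

@dataclass
class AngleCorrectionFit:
    model: AngleCorrectionModel
    params: np.ndarray          # (a, b, c)
    stderr: np.ndarray          # 1-sigma parameter errors
    ci95: np.ndarray            # 95% CI half-widths
    r_squared: float
    residuals: np.ndarray
    covariance: np.ndarray
    dof: int
    residual_variance: float

    def prediction_band(self, theta_deg, level: float = 0.95):
        """(lower, upper) prediction band for a new observation at theta."""
        theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        yhat = _logistic(theta, *self.params)
        # numerical Jacobian of the model wrt parameters
        eps = 1e-6
        J = np.empty((theta.size, 3))
        for k in range(3):
            p_hi = self.params.copy(); p_hi[k] += eps
            p_lo = self.params.copy(); p_lo[k] -= eps
            J[:, k] = (_logistic(theta, *p_hi) - _logistic(theta, *p_lo)) / (2 * eps)
        var_fit = np.einsum("ij,jk,ik->i", J, self.covariance, J)
        se_pred = np.sqrt(var_fit + self.residual_variance)
        t = stats.t.ppf(0.5 + level / 2, self.dof)
        return yhat - t * se_pred, yhat + t * se_pred


def fit_angle_correction(
    theta_deg: Sequence[float],
    intensity_rel: Sequence[float],
    sigma_theta: Sequence[float] | None = None,
    sigma_intensity: Sequence[float] | None = None,
    p0: tuple[float, float, float] = (0.7, 0.1, 20.0),
) -> AngleCorrectionFit:
    """Nonlinear least-squares fit of the logistic angular model to
    (mean angle, normalised intensity) points.

    Points are inverse-variance weighted when ``sigma_intensity`` is given.
    Requires at least four distinct angles including (a point close to) zero,
    which anchors the normalisation y(0) = 1.
    """
    theta = np.asarray(theta_deg, dtype=float)
    y = np.asarray(intensity_rel, dtype=float)
    if theta.size != y.size or theta.size < 4:
        raise DataError("need >= 4 (theta, intensity) points")
    if np.unique(np.round(theta, 3)).size < 4:
        raise DataError("need >= 4 distinct angles")
    if theta.min() > 2.0:
        raise DataError(
            "points must include a near-zero angle anchoring y(0)=1"
        )
    if np.ptp(y) < 1e-12:
        raise FitError("all intensities equal: no angular decay to fit "
                       "(a -> 0 degenerate)", p0=list(p0))

    sig = None if sigma_intensity is None else np.asarray(sigma_intensity, float)
    bounds = ([1e-9, 1e-9, 0.0], [1.0, 1.0, 90.0])
    try:
        popt, pcov = optimize.curve_fit(
            _logistic, theta, y, p0=p0, sigma=sig, absolute_sigma=False,
            bounds=bounds, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = np.linalg.norm(y - _logistic(theta, *p0))
        raise FitError(f"angle-correction fit did not converge: {exc}",
                       p0=list(p0), residual_norm=float(resid)) from exc

    residuals = y - _logistic(theta, *popt)
    dof = max(theta.size - 3, 1)
    res_var = float(np.sum(residuals**2) / dof)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 1.0
    stderr = np.sqrt(np.diag(pcov))
    tval = stats.t.ppf(0.975, dof)
    return AngleCorrectionFit(
        model=AngleCorrectionModel(*popt),
        params=np.asarray(popt),
        stderr=stderr,
        ci95=tval * stderr,
        r_squared=r2,
        residuals=residuals,
        covariance=pcov,
        dof=dof,
        residual_variance=res_var,
    )


# --------------------------------------------------------------------------
# Inter-detector sensitivity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityFactor:
    """Dimensionless sensitivity ``s`` of one detector relative to the fleet
    reference; downstream intensities are divided by ``s``."""

    detector_id: str
    s: float
    n_alpha_tracks: int
    reference_intensity: float

    def __post_init__(self):
        if not self.s > 0:
            raise ConfigurationError(f"sensitivity must be > 0, got {self.s}")


def compute_sensitivity(
    alpha_intensities: Sequence[float],
    fleet_reference: float,
    detector_id: str = "",
    min_tracks: int = 200,
    bin_au: float = 100.0,
) -> SensitivityFactor:
    """Sensitivity factor from the alpha-reference region of one detector.

    The per-detector alpha intensity peak (single-Gaussian fit of the binned
    intensities) is divided by the fleet reference intensity.  The reference
    is conventionally the median of the per-detector alpha peak means.
    """
    x = np.asarray(alpha_intensities, dtype=float)
    if x.size < min_tracks:
        raise DataError(
            f"sensitivity estimate needs >= {min_tracks} alpha tracks, "
            f"got {x.size} for detector {detector_id!r}"
        )
    if not fleet_reference > 0:
        raise ConfigurationError("fleet_reference must be > 0")
    peak = fit_intensity_peak(x, bin_au=bin_au)
    return SensitivityFactor(
        detector_id=detector_id,
        s=peak.mean / fleet_reference,
        n_alpha_tracks=int(x.size),
        reference_intensity=float(fleet_reference),
    )


# --------------------------------------------------------------------------
# Intensity -> LET conversion
# --------------------------------------------------------------------------

@dataclass
class LETCalibration:
    """Invertible mapping between normal-incidence track intensity (a.u.)
    and LET in water (keV/um).

    Forms:
      * ``log_linear``:  ln LET = p0 + p1 * ln I   (params = (p0, p1), p1 > 0)
      * ``power_law``:   LET = k * I**g            (params = (k, g), both > 0)
      * ``table``:       monotone (intensity, LET) knots, log-log interpolated

    Intensities outside ``intensity_range`` are clamped to the range limits
    and flagged rather than silently extrapolated.
    """

    form: str = "log_linear"
    params: tuple = (-13.8155, 2.0)
    knots: np.ndarray | None = None
    intensity_range: tuple = (200.0, 30000.0)

    def __post_init__(self):
        if self.form not in ("log_linear", "power_law", "table"):
            raise ConfigurationError(f"unknown LET calibration form {self.form!r}")
        if self.form == "table":
            if self.knots is None:
                raise ConfigurationError("table calibration requires knots")
            k = np.asarray(self.knots, dtype=float)
            if k.ndim != 2 or k.shape[1] != 2 or k.shape[0] < 2:
                raise ConfigurationError("knots must be an (n, 2) array, n >= 2")
            if np.any(np.diff(k[:, 0]) <= 0) or np.any(np.diff(k[:, 1]) <= 0):
                raise ConfigurationError(
                    "LET calibration table must be strictly increasing in "
                    "both intensity and LET"
                )
            self.knots = k
            self.intensity_range = (float(k[0, 0]), float(k[-1, 0]))
        elif self.form == "log_linear":
            if self.params[1] <= 0:
                raise ConfigurationError("log_linear slope p1 must be > 0")
        elif self.form == "power_law":
            if self.params[0] <= 0 or self.params[1] <= 0:
                raise ConfigurationError("power_law parameters must be > 0")

    # -- forward / inverse -------------------------------------------------
    def let_from_intensity(self, intensity):
        i = np.asarray(intensity, dtype=float)
        if self.form == "log_linear":
            p0, p1 = self.params
            out = np.exp(p0 + p1 * np.log(i))
        elif self.form == "power_law":
            k, g = self.params
            out = k * i**g
        else:
            out = np.exp(np.interp(np.log(i), np.log(self.knots[:, 0]),
                                   np.log(self.knots[:, 1])))
        return float(out) if np.isscalar(intensity) else out

    def intensity_from_let(self, let):
        L = np.asarray(let, dtype=float)
        if self.form == "log_linear":
            p0, p1 = self.params
            out = np.exp((np.log(L) - p0) / p1)
        elif self.form == "power_law":
            k, g = self.params
            out = (L / k) ** (1.0 / g)
        else:
            out = np.exp(np.interp(np.log(L), np.log(self.knots[:, 1]),
                                   np.log(self.knots[:, 0])))
        return float(out) if np.isscalar(let) else out

    @classmethod
    def default(cls) -> "LETCalibration":
        """The package's default log-linear calibration, I = 1000 * sqrt(LET),
        i.e. ln LET = 2 ln I - 2 ln 1000.  Shared by the synthetic renderer so
        that generated stacks round-trip through the analysis."""
        return cls(form="log_linear", params=(-2.0 * np.log(1000.0), 2.0),
                   intensity_range=(200.0, 30000.0))


def intensity_to_let(intensity_i0, cal: LETCalibration):
    """Convert corrected (normal-incidence) intensities to LET in water.

    Returns ``(let, clamped)`` where ``clamped`` marks tracks whose intensity
    fell outside the calibration validity range and was clamped to its edge.
    """
    i = np.asarray(intensity_i0, dtype=float)
    lo, hi = cal.intensity_range
    clamped = (i < lo) | (i > hi)
    let = cal.let_from_intensity(np.clip(i, lo, hi))
    if np.isscalar(intensity_i0):
        return float(np.asarray(let)), bool(np.asarray(clamped))
    return np.asarray(let, dtype=float), clamped
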