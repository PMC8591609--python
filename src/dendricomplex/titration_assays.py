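"""Titration analytics for dendrimer:dye complexation.

Covers the spectroscopic and electrokinetic readouts used to characterise
binding of an anionic dye (rose bengal, RB) to cationic dendrimers:

* emission-spectrum reductions — the F564/F575 intensity ratio and the
  red-shifted peak position that signal the bound state;
* two-regime titration curves (F564/F575 or zeta potential versus molar
  ratio) analysed by a breakpoint method: least-squares lines are fitted to
  the two regimes over a grid of candidate breakpoints, and the binding
  stoichiometry n (dye per dendrimer at saturation) is the molar ratio where
  the two fitted lines intersect (the titration form of Job's method);
* the saturation zeta potential (the plateau the curve settles to once the
  polymer is fully coated, around -30 mV for these systems);
* the singlet-oxygen generation statistic: the slope of a reporter
  fluorescence time course, expressed as a percentage of the control slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class TitrationError(ValueError):
    pass


class DegenerateSeriesError(TitrationError):
    """No breakpoint structure in the series (e.g. strictly linear data)."""


class NoPlateauError(TitrationError):
    """The series never settles to a saturation plateau."""


@dataclass
class EmissionSpectrum:
    """One fluorescence emission spectrum of a titration point."""

    wavelengths: np.ndarray   # nm, strictly ascending
    intensities: np.ndarray   # arbitrary units, >= 0
    molar_ratio: float | None = None   # dye:dendrimer molar ratio of this point
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise TitrationError("wavelengths and intensities must be matching 1D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise TitrationError("wavelengths must be strictly ascending")
        if np.any(self.intensities < 0):
            raise TitrationError("intensities must be >= 0")

    def intensity_at(self, wavelength: float) -> float:
        """Linear interpolation between sampled wavelengths."""
        wl = self.wavelengths
        if not wl[0] <= wavelength <= wl[-1]:
            raise TitrationError(
                f"{wavelength} nm outside the recorded range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.intensities))


@dataclass
class TitrationSeries:
    """Monotone-in-x titration curve: response versus molar ratio."""

    x: np.ndarray            # molar ratios, strictly ascending
    y: np.ndarray            # response: F564/F575 (dimensionless) or zeta (mV)
    response_kind: str       # "fluorescence_ratio" | "zeta"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise TitrationError("x and y must be matching 1D arrays")
        if self.x.size < 5:
            raise TitrationError("a titration series needs at least 5 points")
        if np.any(np.diff(self.x) <= 0):
            raise TitrationError("molar ratios must be strictly ascending")
        if self.response_kind not in ("fluorescence_ratio", "zeta"):
            raise TitrationError(f"unknown response kind {self.response_kind!r}")


@dataclass
class StoichiometryEstimate:
    """Breakpoint-method stoichiometry with its fit diagnostics."""

    n: float                         # dye per dendrimer at saturation
    breakpoint: float                # SSE-optimal split location on the x grid
    slopes: tuple[float, float]
    intercepts: tuple[float, float]
    sse: float
    method: str                      # "fluorescence_job" | "zeta_job"
    flags: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def ratio_string(self) -> str:
        """Stoichiometry as a '1:n' string with half-up rounding."""
        return f"1:{int(np.floor(self.n + 0.5))}"


def fluorescence_ratio(spectrum: EmissionSpectrum,
                       num_nm: float = 564.0, den_nm: float = 575.0) -> float:
    """Intensity ratio F(564 nm)/F(575 nm) of one spectrum."""
    den = spectrum.intensity_at(den_nm)
    if den == 0:
        raise TitrationError(f"zero intensity at {den_nm} nm: ratio undefined")
    return spectrum.intensity_at(num_nm) / den


def peak_wavelength(spectrum: EmissionSpectrum, refine: bool = True) -> float:
    """Emission maximum in nm, optionally refined by a 3-point parabola.

    A plateaued maximum (several grid points tied at the top) returns the
    midpoint of the plateau with a warning.  A flat spectrum has no peak and
    raises.
    """
    y = spectrum.intensities
    if np.ptp(y) == 0:
        raise TitrationError("flat spectrum has no emission peak")
    top = np.flatnonzero(y == y.max())
    if top.size > 1:
        warnings.warn("plateaued maximum; returning the plateau midpoint")
        return float(spectrum.wavelengths[top].mean())
    i = int(top[0])
    wl = spectrum.wavelengths
    if not refine or i in (0, len(y) - 1):
        return float(wl[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(wl[i])
    # vertex of the parabola through the three top samples (uniform-grid form)
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    return float(wl[i] + 0.5 * (y0 - y2) / denom * step)


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return slope, intercept, float(resid @ resid)


def two_segment_fit(x: np.ndarray, y: np.ndarray, min_points: int = 3) -> dict:
    """SSE-optimal split of (x, y) into two least-squares lines.

    Candidate breakpoints are every interior x value and the midpoints
    between consecutive x values; points at the breakpoint belong to both
    segments.  Returns the best candidate's lines and SSE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cand = np.unique(np.concatenate([x[1:-1], 0.5 * (x[:-1] + x[1:])]))
    best = None
    for c in cand:
        left = x <= c
        right = x >= c
        if left.sum() < min_points or right.sum() < min_points:
            continue
        b1, a1, sse1 = _fit_line(x[left], y[left])
        b2, a2, sse2 = _fit_line(x[right], y[right])
        sse = sse1 + sse2
        if best is None or sse < best["sse"] - 1e-15:
            best = {"breakpoint": float(c), "slopes": (b1, b2),
                    "intercepts": (a1, a2), "sse": float(sse)}
        elif best is not None and abs(sse - best["sse"]) <= 1e-15:
            # tie: prefer the candidate whose line intersection is smaller
            def _ix(d):
                db = d["slopes"][0] - d["slopes"][1]
                return ((d["intercepts"][1] - d["intercepts"][0]) / db
                        if db != 0 else np.inf)
            if _ix({"slopes": (b1, b2), "intercepts": (a1, a2)}) < _ix(best):
                best = {"breakpoint": float(c), "slopes": (b1, b2),
                        "intercepts": (a1, a2), "sse": float(sse)}
    if best is None:
        raise TitrationError(
            f"series too short for two segments of >= {min_points} points"
        )
    return best


def job_stoichiometry(series: TitrationSeries) -> StoichiometryEstimate:
    """Binding stoichiometry from the intersection of two fitted regimes.

    The decreasing (binding) limb and the saturation limb are fitted over a
    breakpoint grid; n is the x-coordinate where the two SSE-optimal lines
    intersect.  Strictly linear series carry no breakpoint information and
    raise :class:`DegenerateSeriesError`; parallel-but-offset segments (a
    step) fall back to the plateau onset with a flag.
    """
    x, y = series.x, series.y
    best = two_segment_fit(x, y)
    b1, b2 = best["slopes"]
    a1, a2 = best["intercepts"]
    flags: list[str] = []

    # a single global line explaining the data as well as two segments means
    # there is no breakpoint to estimate
    _, _, sse_global = _fit_line(x, y)
    scale = float(y @ y) + 1e-30
    if sse_global - best["sse"] <= 1e-10 * scale:
        raise DegenerateSeriesError(
            "series is consistent with a single straight line; no breakpoint"
        )

    slope_scale = abs(b1) + abs(b2) + np.ptp(y) / np.ptp(x) + 1e-30
    if abs(b1 - b2) <= 1e-6 * slope_scale:
        # parallel segments: no intersection; report the plateau onset
        flags.append("parallel_segments_plateau_onset_fallback")
        n = best["breakpoint"]
    else:
        n = (a2 - a1) / (b1 - b2)
    if not x[0] <= n <= x[-1]:
        flags.append("intersection_outside_series_range")
        n = float(np.clip(n, x[0], x[-1]))
    method = ("zeta_job" if series.response_kind == "zeta" else "fluorescence_job")
    return StoichiometryEstimate(
        n=float(n), breakpoint=best["breakpoint"],
        slopes=(float(b1), float(b2)), intercepts=(float(a1), float(a2)),
        sse=best["sse"], method=method, flags=flags,
        diagnostics={"sse_global_line": sse_global, "n_points": int(x.size)},
    )


def zeta_saturation(series: TitrationSeries,
                    plateau_slope_ratio: float = 0.25) -> float:
    """Saturation (plateau) response of a titration series, in the series' units.

    Returns the mean of the post-breakpoint fitted line over its x-range.  A
    series that is flat throughout is its own plateau; a series that only
    decreases (plateau never reached) raises :class:`NoPlateauError`.
    ``plateau_slope_ratio`` is the maximum |plateau slope| / |binding slope|
    accepted as "flat".
    """
    x, y = series.x, series.y
    overall_slope, _, _ = _fit_line(x, y)
    if np.ptp(y) <= 1e-12 * max(1.0, abs(y[0])):
        return float(y.mean())
    try:
        est = job_stoichiometry(series)
    except DegenerateSeriesError:
        raise NoPlateauError("series has no two-regime structure; no plateau") from None
    b1, b2 = est.slopes
    if abs(b2) > plateau_slope_ratio * abs(b1):
        raise NoPlateauError(
            f"post-breakpoint slope {b2:.3g} is not flat relative to the "
            f"binding limb slope {b1:.3g}"
        )
    a2 = est.intercepts[1]
    x_lo = max(est.breakpoint, est.n)
    return float(a2 + b2 * 0.5 * (x_lo + x[-1]))


def singlet_oxygen_rate(
    time: np.ndarray, fluorescence: np.ndarray,
    control_time: np.ndarray, control_fluorescence: np.ndarray,
) -> float:
    """Singlet-oxygen generation as percent of control.

    Both series are reduced to their ordinary least-squares slope (reporter
    fluorescence per unit time); the statistic is 100 x sample slope /
    control slope.  Requires >= 3 points each and overlapping time ranges.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    tc = np.asarray(control_time, dtype=float)
    fc = np.asarray(control_fluorescence, dtype=float)
    for name, a in (("sample", t), ("control", tc)):
        if a.size < 3:
            raise TitrationError(f"{name} series needs >= 3 time points")
    if t.min() > tc.max() or tc.min() > t.max():
        warnings.warn("sample and control time ranges do not overlap")
    slope, _ = np.polyfit(t, f, 1)
    slope_c, _ = np.polyfit(tc, fc, 1)
    if abs(slope_c) <= 1e-12 * (np.ptp(fc) + 1.0) / np.ptp(tc):
        raise TitrationError("control slope is zero; percentage undefined")
    return 100.0 * slope / slope_c
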