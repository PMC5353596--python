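"""Single-cell oxygen consumption rate (OCR) extraction.

A single cell sealed inside a gas-impermeable picoliter well depletes the
dissolved oxygen trapped with it.  An intensity-based luminescent sensor in
the well is quenched by oxygen, so its emission rises as oxygen falls; a
rhodamine-123 reference channel makes the readout ratiometric and therefore
independent of deposited sensor volume.  The pipeline implemented here is:

1. ratiometric self-referencing (sensor / reference),
2. optional centered sliding-window smoothing,
3. Stern-Volmer inversion of the ratio to dissolved-oxygen concentration,
4. ordinary least-squares fit of concentration against time over the
   pre-depletion region,
5. conversion of the concentration slope (uM/min) to an absolute
   consumption rate in fmol/min using the sealed-well volume.

Units convention, fixed package-wide: OCR in fmol/min, volume in pL,
concentration in uM, time in minutes; ``K_U = 1e-3`` fmol per (pL * uM)
converts between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import CalibrationError, ConfigurationError, DataError, ExtractionError

#: fmol of solute per (pL of volume x uM of concentration)
K_U = 1e-3

#: default OCR (fmol/min) below which a cell is classed as non-respiring
DETECTION_FLOOR = 0.1

#: fraction of the initial concentration below which the trace is considered
#: to have reached the depletion floor (regression stops there)
FLOOR_FRACTION = 0.02

RESPIRING = "respiring"
NON_RESPIRING = "non-respiring"


@dataclass(frozen=True)
class WellGeometry:
    """Geometry and initial condition of one sealed microwell.

    Parameters
    ----------
    volume_pl
        Sealed chamber volume in picoliters.  Default 140 pL.
    initial_o2_um
        Dissolved oxygen concentration (uM) at seal time.  Default 200 uM,
        approximately air-saturated aqueous medium near 37 C.
    """

    volume_pl: float = 140.0
    initial_o2_um: float = 200.0

    def __post_init__(self) -> None:
        if not self.volume_pl > 0:
            raise ConfigurationError(f"well volume must be positive, got {self.volume_pl}")
        if self.initial_o2_um < 0:
            raise ConfigurationError(f"initial O2 must be >= 0, got {self.initial_o2_um}")

    @property
    def total_o2_fmol(self) -> float:
        """Total amount of oxygen sealed in the well, in fmol."""
        return self.volume_pl * self.initial_o2_um * K_U


@dataclass(frozen=True)
class CalibrationModel:
    """Stern-Volmer calibration of the ratiometric oxygen sensor.

    The sensor/reference intensity ratio rho relates to dissolved oxygen C
    through ``rho = i0 / (1 + ksv * C)``: ``i0`` is the unquenched (anoxic)
    ratio and ``ksv`` the quenching constant in 1/uM.
    """

    ksv: float
    i0: float
    provenance: str = "configured"

    def __post_init__(self) -> None:
        if not self.ksv > 0:
            raise CalibrationError(f"ksv must be positive, got {self.ksv}")
        if not self.i0 > 0:
            raise CalibrationError(f"i0 must be positive, got {self.i0}")

    def ratio_at(self, concentration_um):
        """Forward model: expected ratio at a given oxygen concentration."""
        return self.i0 / (1.0 + self.ksv * np.asarray(concentration_um, dtype=float))


@dataclass
class SensorTrace:
    """One well's two-channel intensity record.

    ``times`` are minutes and must be strictly increasing; ``sensor`` and
    ``reference`` are raw channel intensities of equal length.
    """

    cell_id: str
    times: np.ndarray
    sensor: np.ndarray
    reference: np.ndarray
    well: WellGeometry = field(default_factory=WellGeometry)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sensor = np.asarray(self.sensor, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        n = len(self.times)
        if n < 2:
            raise DataError(f"trace {self.cell_id!r}: need at least 2 time points, got {n}")
        if len(self.sensor) != n or len(self.reference) != n:
            raise DataError(
                f"trace {self.cell_id!r}: channel lengths "
                f"({len(self.sensor)}, {len(self.reference)}) do not match {n} time points"
            )
        if np.any(np.diff(self.times) <= 0):
            raise DataError(f"trace {self.cell_id!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class OCRResult:
    """Extracted respiration phenotype of one cell.

    ``slope_um_min`` keeps its sign (consumption gives a negative
    concentration slope); ``ocr_fmol_min`` is the non-negative rate.
    """

    cell_id: str
    ocr_fmol_min: float
    slope_um_min: float
    slope_stderr: float
    r_squared: float
    respirer_class: str
    sealed: bool
    n_points: int
    n_clamped: int


def ratiometric_normalize(trace: SensorTrace) -> np.ndarray:
    """Divide the oxygen-sensitive channel by the reference channel.

    Self-referencing removes dependence on deposited sensor volume; any
    multiplicative factor common to both channels cancels exactly.
    """
    bad = np.flatnonzero(trace.reference <= 0)
    if bad.size:
        raise DataError(
            f"trace {trace.cell_id!r}: non-positive reference intensity at index {bad[0]}"
        )
    return trace.sensor / trace.reference


def sliding_average(series, window: int = 5) -> np.ndarray:
    """Centered moving mean with symmetric shrink at the edges.

    At index ``i`` the half-window is clipped to ``min(window//2, i, n-1-i)``
    so the output has the same length as the input and stays centered.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    n = len(x)
    if window > n:
        raise ConfigurationError(f"window {window} exceeds series length {n}")
    out = np.empty(n)
    for i in range(n):
        h = min(window // 2, i, n - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


def _invert_stern_volmer(ratio: np.ndarray, cal: CalibrationModel):
    conc = (cal.i0 / ratio - 1.0) / cal.ksv
    # ratios above i0 imply (slightly) negative concentration: clamp and count
    tol = 1e-12 / cal.ksv
    n_clamped = int(np.sum(conc < -tol))
    return np.clip(conc, 0.0, None), n_clamped


def calibrate(ratio, cal: CalibrationModel) -> np.ndarray:
    """Convert a sensor/reference ratio series to oxygen concentration (uM).

    Inverts the Stern-Volmer relation ``C = (i0/ratio - 1)/ksv``, clamping
    at zero from below (a ratio above ``i0`` has no physical concentration;
    a warning reports how many samples were clamped).
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise DataError("ratio series must be strictly positive")
    conc, n_clamped = _invert_stern_volmer(ratio, cal)
    if n_clamped:
        warnings.warn(
            f"{n_clamped} ratio sample(s) exceeded i0; concentration clamped at 0",
            stacklevel=2,
        )
    return conc


def two_point_calibrate(
    ratio_at_anoxia: float, ratio_at_known_c: float, known_c: float
) -> CalibrationModel:
    """Fit a Stern-Volmer model from two anchor points.

    The anoxic ratio pins ``i0``; a second measurement at a known oxygen
    concentration (e.g. from gas-purged medium) solves for ``ksv``.
    """
    if ratio_at_anoxia <= 0 or ratio_at_known_c <= 0:
        raise CalibrationError("calibration ratios must be positive")
    if known_c <= 0:
        raise CalibrationError(f"known concentration must be positive, got {known_c}")
    if ratio_at_anoxia <= ratio_at_known_c:
        raise CalibrationError(
            "anoxic ratio must exceed the quenched ratio at the known concentration "
            f"({ratio_at_anoxia} <= {ratio_at_known_c})"
        )
    i0 = ratio_at_anoxia
    ksv = (i0 / ratio_at_known_c - 1.0) / known_c
    return CalibrationModel(ksv=ksv, i0=i0, provenance="two-point")


def _ols(t: np.ndarray, c: np.ndarray):
    """Unweighted OLS line fit; returns (slope, stderr, r_squared)."""
    if np.ptp(c) == 0.0:
        # exactly flat series: a zero-slope line fits perfectly
        return 0.0, 0.0, 1.0
    res = stats.linregress(t, c)
    r2 = float(res.rvalue) ** 2
    return float(res.slope), float(res.stderr), r2


def extract_ocr(
    trace: SensorTrace,
    cal: CalibrationModel,
    *,
    smooth: bool = True,
    window: int = 5,
    fit_window: tuple[float, float] | None = None,
    detection_floor: float = DETECTION_FLOOR,
    floor_fraction: float = FLOOR_FRACTION,
    sealed: bool = True,
) -> OCRResult:
    """Extract a cell's OCR (fmol/min) from its sealed-well trace.

    The normalized (and optionally smoothed) ratio is inverted to a
    concentration series; an OLS line is fitted over the region before the
    depletion floor (first sample below ``floor_fraction`` of the initial
    concentration) and the slope converted via
    ``OCR = max(0, -slope) * V * K_U``.

    Parameters
    ----------
    fit_window
        Optional ``(t_start, t_end)`` in minutes restricting the regression.
    sealed
        QC flag carried through to the result; determine it with
        :func:`qc_seal` on a dedicated post-drawdown perturbation trace.
    """
    ratio = ratiometric_normalize(trace)
    if smooth:
        ratio = sliding_average(ratio, window=window)
    conc, n_clamped = _invert_stern_volmer(ratio, cal)
    times = trace.times

    if fit_window is not None:
        t0, t1 = fit_window
        mask = (times >= t0) & (times <= t1)
        times, conc = times[mask], conc[mask]

    if len(conc) == 0 or conc[0] <= 0:
        raise ExtractionError(
            f"trace {trace.cell_id!r}: already at the depletion floor at fit start"
        )
    below = np.flatnonzero(conc < floor_fraction * conc[0])
    if below.size:
        times, conc = times[: below[0]], conc[: below[0]]
    if len(conc) < 5:
        raise ExtractionError(
            f"trace {trace.cell_id!r}: only {len(conc)} usable points before the "
            "depletion floor (need >= 5)"
        )

    slope, stderr, r2 = _ols(times, conc)
    ocr = max(0.0, -slope) * trace.well.volume_pl * K_U
    respirer = RESPIRING if ocr >= detection_floor else NON_RESPIRING
    return OCRResult(
        cell_id=trace.cell_id,
        ocr_fmol_min=ocr,
        slope_um_min=slope,
        slope_stderr=stderr,
        r_squared=r2,
        respirer_class=respirer,
        sealed=sealed,
        n_points=len(conc),
        n_clamped=n_clamped,
    )


def qc_seal(trace: SensorTrace, tolerance: float = 0.02, window: int | None = None) -> bool:
    """Seal QC: is the normalized ratio stable over the QC window?

    Run on a perturbation trace (exterior oxygen changed, e.g. a nitrogen
    purge): an intact hermetic seal leaves the interior, hence the ratio,
    unchanged, while a leak lets the interior track the exterior.  The
    relative change is measured between short medians at the window ends so
    single noisy samples do not flip the verdict.
    """
    ratio = ratiometric_normalize(trace)
    if window is not None:
        ratio = ratio[-window:]
    k = max(1, min(3, len(ratio) // 3))
    start = float(np.median(ratio[:k]))
    end = float(np.median(ratio[-k:]))
    return abs((end - start) / start) <= tolerance


class OCRModel:
    """Respiration-rate model for one sealed-well trace.

    Statsmodels-style front end over :func:`extract_ocr`: construct from a
    trace and calibration, then :meth:`fit` returns an :class:`OCRResults`
    carrying the estimate, its standard error, diagnostics and the fitted
    concentration series.
    """

    def __init__(
        self,
        trace: SensorTrace,
        calibration: CalibrationModel,
        *,
        smooth: bool = True,
        window: int = 5,
        detection_floor: float = DETECTION_FLOOR,
    ) -> None:
        self.trace = trace
        self.calibration = calibration
        self.smooth = smooth
        self.window = window
        self.detection_floor = detection_floor

    def fit(self, fit_window: tuple[float, float] | None = None) -> "OCRResults":
        result = extract_ocr(
            self.trace,
            self.calibration,
            smooth=self.smooth,
            window=self.window,
            fit_window=fit_window,
            detection_floor=self.detection_floor,
        )
        ratio = ratiometric_normalize(self.trace)
        if self.smooth:
            ratio = sliding_average(ratio, window=self.window)
        conc, _ = _invert_stern_volmer(ratio, self.calibration)
        return OCRResults(self, result, self.trace.times, conc)


class OCRResults:
    """Fit results for one well: point estimate, uncertainty, diagnostics."""

    def __init__(self, model: OCRModel, result: OCRResult, times, concentration) -> None:
        self.model = model
        self.result = result
        self.times = np.asarray(times)
        self.concentration = np.asarray(concentration)

    @property
    def ocr(self) -> float:
        return self.result.ocr_fmol_min

    @property
    def ocr_stderr(self) -> float:
        """Standard error of the OCR, propagated from the slope stderr."""
        return self.result.slope_stderr * self.model.trace.well.volume_pl * K_U

    @property
    def rsquared(self) -> float:
        return self.result.r_squared

    def summary(self) -> str:
        r = self.result
        well = self.model.trace.well
        lines = [
            "Single-cell OCR fit",
            "=" * 46,
            f"cell id:            {r.cell_id}",
            f"well volume:        {well.volume_pl:.1f} pL",
            f"points in fit:      {r.n_points}",
            f"slope:              {r.slope_um_min:.4f} uM/min (se {r.slope_stderr:.4f})",
            f"OCR:                {r.ocr_fmol_min:.4f} fmol/min (se {self.ocr_stderr:.4f})",
            f"R-squared:          {r.r_squared:.4f}",
            f"respirer class:     {r.respirer_class}",
            f"sealed (QC):        {r.sealed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Concentration vs time with the fitted regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.times, self.concentration, ".", ms=4, label="calibrated [O2]")
        r = self.result
        tt = self.times[: r.n_points]
        intercept = self.concentration[: r.n_points].mean() - r.slope_um_min * tt.mean()
        ax.plot(tt, intercept + r.slope_um_min * tt, "-", lw=1.5, label="OLS fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("dissolved O2 (uM)")
        ax.set_title(f"{r.cell_id}: OCR = {r.ocr_fmol_min:.2f} fmol/min")
        ax.legend(frameon=False)
        return ax
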