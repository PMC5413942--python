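"""Rupture-event detection, per-event WLC fitting, filtering, classification.

A specific tether rupture appears on a processed retraction as a sharp drop
in force: the smoothed first derivative of force with respect to separation
shows a strong negative excursion.  Candidates are detected on that
derivative, each rising edge is fitted with a fixed-persistence-length WLC
(contour length the only free mechanical parameter), the loading rate at
rupture is the WLC stiffness at the rupture point times the retraction
velocity, and candidates are then filtered:

* events at tip-sample separations below ~10 nm are non-specific
  tip-sample adhesion and are rejected;
* fitted contour lengths must exceed the PEG24 linker pair (19 nm);
* the edge must be WLC-like, i.e. visibly nonlinear, which rejects the
  linear force-distance profiles characteristic of adhesion.

Curves are classified by the number of surviving events (0 / 1 / 2 / 3+),
and the hit rate of a map is the fraction of cycles with at least one
accepted event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks, savgol_filter

from .curves import ProcessedCurve
from .polymer import WLCParams, wlc_force, wlc_stiffness

__all__ = [
    "DetectionConfig",
    "FilterCriteria",
    "RuptureEvent",
    "CurveClassification",
    "detect_events",
    "fit_event_wlc",
    "loading_rate_at_rupture",
    "apply_filters",
    "classify_curve",
    "hit_rate",
    "analyze_curve",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for rupture-candidate detection.

    smoothing_window
        Samples in the Savitzky-Golay window (odd); order 2.
    prominence_sigmas
        Peak prominence threshold on the negative force derivative, in
        multiples of its robust (MAD-based) noise sigma.
    min_force_drop_pN
        Minimum drop in smoothed force across the candidate, measured one
        window to either side; suppresses noise triggers.
    min_edge_samples
        Minimum rising-edge length for a candidate to be fittable.
    """

    smoothing_window: int = 11
    polyorder: int = 2
    prominence_sigmas: float = 3.0
    min_force_drop_pN: float = 20.0
    min_edge_samples: int = 8


@dataclass(frozen=True)
class FilterCriteria:
    """Acceptance filters applied to fitted rupture candidates."""

    min_separation_nm: float = 10.0
    min_Lc_nm: float = 19.0
    max_fit_residual_pN: float = 30.0
    nonlinearity_r2_margin: float = 0.01
    min_fractional_extension: float = 0.2
    persistence_length_nm: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "min_separation_nm",
            "min_Lc_nm",
            "max_fit_residual_pN",
            "nonlinearity_r2_margin",
            "min_fractional_extension",
            "persistence_length_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


REJECTION_REASONS = (
    "below_min_separation",
    "contour_below_linker",
    "linear_profile",
    "unfittable",
    "residual_too_large",
)


@dataclass
class RuptureEvent:
    """A fitted rupture candidate on one curve."""

    curve_id: str
    event_index: int
    peak_sample: int
    edge_start: int
    edge_end: int
    extension_at_rupture_nm: float
    rupture_force_pN: float
    fitted_Lc_nm: float | None
    fit_residual_rms_pN: float | None
    force_drop_pN: float
    loading_rate_pN_s: float | None = None
    wlc_slope_at_rupture_pN_nm: float | None = None
    r2_wlc: float | None = None
    r2_linear: float | None = None
    accepted: bool = False
    reason: str = ""


@dataclass
class CurveClassification:
    """Accept/reject outcome for one curve."""

    curve_id: str
    n_accepted_events: int
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accepted != (self.n_accepted_events >= 1):
            raise ValueError("accepted flag inconsistent with event count")


def _smoothed(curve: ProcessedCurve, config: DetectionConfig):
    w = config.smoothing_window
    if curve.n_samples <= w:
        raise ValueError(
            f"curve {curve.curve_id}: {curve.n_samples} samples is shorter than "
            f"the smoothing window ({w})"
        )
    return savgol_filter(curve.force_pN, w, config.polyorder)


def detect_events(
    curve: ProcessedCurve, config: DetectionConfig | None = None
) -> list[int]:
    """Detect candidate rupture positions (sample indices) on a curve.

    Candidates are prominent negative excursions of the smoothed force
    derivative that also drop the smoothed force by at least
    ``min_force_drop_pN``; they are returned ordered by separation.
    """
    cfg = config or DetectionConfig()
    w = cfg.smoothing_window
    smooth = _smoothed(curve, cfg)
    deriv = savgol_filter(curve.force_pN, w, cfg.polyorder, deriv=1)

    # robust noise scale of the derivative channel
    sigma = 1.4826 * np.median(np.abs(deriv - np.median(deriv)))
    if sigma <= 0:
        sigma = np.finfo(float).tiny
    peaks, _ = find_peaks(-deriv, prominence=cfg.prominence_sigmas * sigma)

    n = curve.n_samples
    candidates = []
    for p in peaks:
        before = smooth[max(p - w, 0)]
        after = smooth[min(p + w, n - 1)]
        if before - after >= cfg.min_force_drop_pN:
            candidates.append(int(p))
    # order by tip-sample separation
    candidates.sort(key=lambda p: curve.tip_sample_separation_nm[p])
    return candidates


def _rising_edge(
    curve: ProcessedCurve,
    peak: int,
    previous_peak: int | None,
    config: DetectionConfig,
) -> tuple[int, int]:
    """Locate the rising edge [start, end) feeding a rupture at ``peak``.

    The edge runs from the previous smoothed-force minimum (or baseline
    crossing) after the previous event up to the last pre-rupture sample;
    ties broken toward the longer window.
    """
    smooth = _smoothed(curve, config)
    w = config.smoothing_window
    lo = 0 if previous_peak is None else min(previous_peak + w, peak)
    end = max(peak - w // 2, lo + 1)
    if end <= lo + 1:
        return lo, end
    segment = smooth[lo:end]
    # first index attaining the minimum -> longer edge window
    start = lo + int(np.argmin(segment))
    # if the force crosses the baseline after the minimum, start at the
    # last upward zero-crossing instead (still >= the minimum position)
    seg = smooth[start:end]
    below = np.flatnonzero(seg <= 0)
    if below.size:
        start = start + int(below[-1])
    return start, end


def fit_event_wlc(
    curve: ProcessedCurve,
    peak: int,
    previous_peak: int | None = None,
    config: DetectionConfig | None = None,
    criteria: FilterCriteria | None = None,
    event_index: int = 0,
) -> RuptureEvent:
    """Fit one rising edge with a fixed-persistence WLC.

    The contour length is the only free mechanical parameter; the rupture
    force is read off the last pre-rupture sample and the rupture extension
    is the corresponding separation.  Edges that cannot be fitted (too few
    samples, no positive extension range, optimizer pinned at a bound) are
    flagged ``unfittable``.
    """
    cfg = config or DetectionConfig()
    crit = criteria or FilterCriteria()
    start, end = _rising_edge(curve, peak, previous_peak, cfg)

    smooth = _smoothed(curve, cfg)
    w = cfg.smoothing_window
    n = curve.n_samples
    drop = smooth[max(peak - w, 0)] - smooth[min(peak + w, n - 1)]

    x = curve.tip_sample_separation_nm[start:end]
    y = curve.force_pN[start:end]
    x_r = float(curve.tip_sample_separation_nm[end - 1])
    f_r = float(curve.force_pN[end - 1])

    event = RuptureEvent(
        curve_id=curve.curve_id,
        event_index=event_index,
        peak_sample=peak,
        edge_start=start,
        edge_end=end,
        extension_at_rupture_nm=x_r,
        rupture_force_pN=f_r,
        fitted_Lc_nm=None,
        fit_residual_rms_pN=None,
        force_drop_pN=float(drop),
    )

    # only the tensile part of the edge informs the WLC
    mask = x > 0
    if mask.sum() < cfg.min_edge_samples or x_r <= 0:
        event.reason = "unfittable"
        return event
    xf, yf = x[mask], y[mask]
    x_max = float(xf.max())

    p = crit.persistence_length_nm
    T = curve.temperature_K
    lo_Lc = x_max * (1.0 + 1e-6)
    hi_Lc = max(10.0 * x_max, lo_Lc * 2.0)

    def sse(Lc: float) -> float:
        params = WLCParams(p, Lc, T)
        resid = wlc_force(params, xf) - yf
        return float(resid @ resid)

    res = minimize_scalar(sse, bounds=(lo_Lc, hi_Lc), method="bounded")
    Lc = float(res.x)
    if not res.success or Lc >= hi_Lc * (1.0 - 1e-6):
        event.reason = "unfittable"
        return event

    params = WLCParams(p, Lc, T)
    resid = wlc_force(params, xf) - yf
    rms = float(np.sqrt(np.mean(resid**2)))

    # straight-line comparison for the nonlinearity criterion
    ss_tot = float(np.sum((yf - yf.mean()) ** 2))
    if ss_tot > 0:
        lin = np.polyval(np.polyfit(xf, yf, 1), xf)
        r2_linear = 1.0 - float(np.sum((yf - lin) ** 2)) / ss_tot
        r2_wlc = 1.0 - float(resid @ resid) / ss_tot
    else:
        r2_linear = r2_wlc = 0.0

    event.fitted_Lc_nm = Lc
    event.fit_residual_rms_pN = rms
    event.r2_wlc = r2_wlc
    event.r2_linear = r2_linear
    return event


def loading_rate_at_rupture(
    event: RuptureEvent,
    retraction_velocity_nm_s: float,
    persistence_length_nm: float = 0.4,
    temperature_K: float = 298.0,
) -> float:
    """Loading rate (pN/s) at rupture: WLC stiffness at x_r times velocity.

    The stiffness comes from the differentiated WLC evaluated at the fitted
    contour length and the extension at rupture.
    """
    if retraction_velocity_nm_s is None or retraction_velocity_nm_s <= 0:
        raise ValueError("retraction velocity metadata missing or non-positive")
    if event.fitted_Lc_nm is None:
        raise ValueError("event has no fitted contour length")
    params = WLCParams(persistence_length_nm, event.fitted_Lc_nm, temperature_K)
    slope = wlc_stiffness(params, event.extension_at_rupture_nm)
    return float(slope * retraction_velocity_nm_s)


def apply_filters(
    events: list[RuptureEvent], criteria: FilterCriteria | None = None
) -> list[RuptureEvent]:
    """Apply acceptance filters in place; every event ends accepted or
    rejected with a reason.  Returns the same list for convenience."""
    crit = criteria or FilterCriteria()
    for ev in events:
        if ev.reason == "unfittable" or ev.fitted_Lc_nm is None:
            ev.accepted = False
            ev.reason = "unfittable"
            continue
        if ev.extension_at_rupture_nm < crit.min_separation_nm:
            ev.accepted = False
            ev.reason = "below_min_separation"
            continue
        if ev.fitted_Lc_nm <= crit.min_Lc_nm:
            ev.accepted = False
            ev.reason = "contour_below_linker"
            continue
        frac = ev.extension_at_rupture_nm / ev.fitted_Lc_nm
        if (
            ev.r2_wlc is None
            or ev.r2_wlc - ev.r2_linear < crit.nonlinearity_r2_margin
            or frac < crit.min_fractional_extension
        ):
            ev.accepted = False
            ev.reason = "linear_profile"
            continue
        if ev.fit_residual_rms_pN > crit.max_fit_residual_pN:
            ev.accepted = False
            ev.reason = "residual_too_large"
            continue
        ev.accepted = True
        ev.reason = ""
    return events


def classify_curve(
    curve_id: str, events: list[RuptureEvent]
) -> CurveClassification:
    """Classify one curve by its number of accepted events."""
    accepted = [ev for ev in events if ev.accepted]
    reasons = sorted({ev.reason for ev in events if not ev.accepted and ev.reason})
    return CurveClassification(
        curve_id=curve_id,
        n_accepted_events=len(accepted),
        accepted=len(accepted) >= 1,
        rejection_reasons=reasons,
    )


def hit_rate(classifications: list[CurveClassification]) -> float:
    """Fraction of cycles with at least one accepted specific event."""
    if not classifications:
        raise ValueError("hit rate of an empty set of curves is undefined")
    return sum(c.accepted for c in classifications) / len(classifications)


def analyze_curve(
    curve: ProcessedCurve,
    detection: DetectionConfig | None = None,
    criteria: FilterCriteria | None = None,
) -> tuple[list[RuptureEvent], CurveClassification]:
    """Full per-curve chain: detect -> fit -> loading rate -> filter -> classify."""
    cfg = detection or DetectionConfig()
    crit = criteria or FilterCriteria()
    peaks = detect_events(curve, cfg)
    events: list[RuptureEvent] = []
    prev = None
    for i, p in enumerate(peaks):
        ev = fit_event_wlc(curve, p, prev, cfg, crit, event_index=i)
        if ev.fitted_Lc_nm is not None:
            ev.wlc_slope_at_rupture_pN_nm = wlc_stiffness(
                WLCParams(
                    crit.persistence_length_nm, ev.fitted_Lc_nm, curve.temperature_K
                ),
                ev.extension_at_rupture_nm,
            )
            ev.loading_rate_pN_s = (
                ev.wlc_slope_at_rupture_pN_nm * curve.retraction_velocity_nm_s
            )
        events.append(ev)
        prev = p
    apply_filters(events, crit)
    return events, classify_curve(curve.curve_id, events)
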