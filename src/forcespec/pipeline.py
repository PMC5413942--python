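"""End-to-end analysis over force maps.

The run chain is: instrument-frame conversion -> rupture detection ->
per-event WLC fit -> loading rates -> acceptance filters -> per-curve
classification -> ensemble statistics (modal FU/Lc, per-curve dLc, hit
rate).  Stage counts are logged so filter conservation can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .curves import (
    ConversionConfig,
    ProcessedCurve,
    RawForceCurve,
    convert_to_force_separation,
)
from .ensemble import (
    DeltaLcRecord,
    GaussianFit,
    compute_delta_lc,
    fit_gaussian_mode,
)
from .events import (
    CurveClassification,
    DetectionConfig,
    FilterCriteria,
    RuptureEvent,
    analyze_curve,
    hit_rate,
)

logger = logging.getLogger(__name__)

__all__ = ["MapAnalysis", "analyze_map", "summary_dict"]


@dataclass
class MapAnalysis:
    """Everything the pipeline measured on one map."""

    events_by_curve: dict[str, list[RuptureEvent]]
    classifications: list[CurveClassification]
    hit_rate: float
    delta_lc_records: list[DeltaLcRecord] = field(default_factory=list)
    delta_lc_mode: GaussianFit | None = None
    fu_mode: GaussianFit | None = None
    lc_mode: GaussianFit | None = None
    n_curves: int = 0
    n_detected: int = 0
    n_accepted: int = 0
    retraction_velocity_nm_s: float | None = None
    mean_loading_rate_pN_s: float | None = None

    @property
    def accepted_events(self) -> list[RuptureEvent]:
        return [
            ev for evs in self.events_by_curve.values() for ev in evs if ev.accepted
        ]


def analyze_map(
    curves: list[RawForceCurve],
    conversion: ConversionConfig | None = None,
    detection: DetectionConfig | None = None,
    criteria: FilterCriteria | None = None,
    fu_bin_pN: float = 10.0,
    lc_bin_nm: float = 2.0,
    dlc_bin_nm: float = 2.0,
    min_count: int = 30,
) -> MapAnalysis:
    """Run the full chain over a list of raw curves.

    Modal fits are attempted only where the event pool reaches
    ``min_count``; otherwise the corresponding mode is left unset.
    """
    if not curves:
        raise ValueError("no curves found")
    events_by_curve: dict[str, list[RuptureEvent]] = {}
    classifications: list[CurveClassification] = []
    n_detected = 0
    for raw in curves:
        processed: ProcessedCurve = convert_to_force_separation(raw, conversion)
        events, cls = analyze_curve(processed, detection, criteria)
        events_by_curve[raw.curve_id] = events
        classifications.append(cls)
        n_detected += len(events)

    rate = hit_rate(classifications)
    accepted = [
        ev for evs in events_by_curve.values() for ev in evs if ev.accepted
    ]
    logger.info(
        "map: %d curves, %d detected candidates, %d accepted events, hit rate %.3f",
        len(curves),
        n_detected,
        len(accepted),
        rate,
    )

    velocities = {c.retraction_velocity_nm_s for c in curves}
    rates = [ev.loading_rate_pN_s for ev in accepted if ev.loading_rate_pN_s]
    result = MapAnalysis(
        events_by_curve=events_by_curve,
        classifications=classifications,
        hit_rate=rate,
        n_curves=len(curves),
        n_detected=n_detected,
        n_accepted=len(accepted),
        retraction_velocity_nm_s=velocities.pop() if len(velocities) == 1 else None,
        mean_loading_rate_pN_s=float(np.mean(rates)) if rates else None,
    )

    if len(accepted) >= min_count:
        result.fu_mode = fit_gaussian_mode(
            [ev.rupture_force_pN for ev in accepted], fu_bin_pN, min_count
        )
        result.lc_mode = fit_gaussian_mode(
            [ev.fitted_Lc_nm for ev in accepted], lc_bin_nm, min_count
        )
    result.delta_lc_records, result.delta_lc_mode = compute_delta_lc(
        events_by_curve, dlc_bin_nm, min_count
    )
    return result


def summary_dict(analysis: MapAnalysis) -> dict:
    """JSON-ready ensemble summary of a map analysis."""
    def gf(fit: GaussianFit | None) -> dict | None:
        if fit is None:
            return None
        return {
            "mode": fit.mode,
            "sigma": fit.sigma,
            "bin_width": fit.bin_width,
            "n": fit.n,
        }

    counts = {}
    for cls in analysis.classifications:
        key = str(min(cls.n_accepted_events, 3)) + (
            "+" if cls.n_accepted_events >= 3 else ""
        )
        counts[key] = counts.get(key, 0) + 1

    dlc1 = [r.delta_Lc1_nm for r in analysis.delta_lc_records]
    return {
        "retraction_velocity_nm_s": analysis.retraction_velocity_nm_s,
        "mean_loading_rate_pN_s": analysis.mean_loading_rate_pN_s,
        "n_curves": analysis.n_curves,
        "n_detected_candidates": analysis.n_detected,
        "n_accepted_events": analysis.n_accepted,
        "hit_rate": analysis.hit_rate,
        "curves_by_event_count": counts,
        "modal_FU_pN": gf(analysis.fu_mode),
        "modal_Lc_nm": gf(analysis.lc_mode),
        "modal_delta_Lc_nm": gf(analysis.delta_lc_mode),
        "delta_Lc1_mean_nm": float(np.mean(dlc1)) if dlc1 else None,
        "n_delta_Lc_curves": len(analysis.delta_lc_records),
    }
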