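"""Study-level workflows: complete simulate-and-analyze measurements.

Each function runs one of the package's headline measurements end to end on
synthetic data with a single seed: contour-length predictions, the
wild-type dLc recovery, per-scenario dLc studies, the multi-velocity
dynamic force spectrum, the map hit rate, and the MST KD recovery.  The
analysis drivers and the acceptance checks are thin wrappers over these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import BellEvansFit, DFSPoint, build_dfs, fit_bell_evans
from .mst import BindingFit, fit_kd
from .pipeline import MapAnalysis, analyze_map
from .polymer import ConstructGeometry, predicted_detachment_length
from .simulate import (
    PullingConfig,
    scenario_presets,
    simulate_map,
    simulate_mst,
    simulate_pull,
)

__all__ = [
    "detachment_predictions",
    "scenario_study",
    "wildtype_delta_lc_study",
    "hit_rate_study",
    "dfs_study",
    "mst_kd_study",
    "MstStudyResult",
    "DfsStudyResult",
]


def detachment_predictions() -> dict[str, float]:
    """Predicted contour lengths at detachment for the two constructs:
    with the fully unstructured 118-residue linker domain and without it."""
    with_linker = predicted_detachment_length(
        ConstructGeometry(19.0, 5.5, 118, 0.4)
    )
    without_linker = predicted_detachment_length(ConstructGeometry(19.0, 5.5, 0, 0.4))
    return {
        "with_linker_domain_nm": with_linker,
        "without_linker_domain_nm": without_linker,
    }


def scenario_study(
    scenario: str,
    seed: int,
    n_curves: int = 200,
    velocity_nm_s: float = 1000.0,
    noise_sigma_pN: float = 5.0,
    min_count: int = 30,
) -> MapAnalysis:
    """Simulate ``n_curves`` specific pulls of a scenario and analyze them.

    Only specific (tether-bearing) curves are generated; mixtures are the
    business of :func:`hit_rate_study`.
    """
    cfg = PullingConfig(
        retraction_velocity_nm_s=velocity_nm_s,
        force_noise_sigma_pN=noise_sigma_pN,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    segments = scenario_presets(scenario)
    curves = [
        simulate_pull(cfg, segments, f"{scenario}-{i:04d}", rng=rng)[0]
        for i in range(n_curves)
    ]
    return analyze_map(curves, min_count=min_count)


def wildtype_delta_lc_study(seed: int, n_curves: int = 250) -> MapAnalysis:
    """The central round trip: wild-type double-rupture curves through the
    full pipeline to the modal dLc (expected 20 nm for 50 released
    residues at 0.4 nm each)."""
    return scenario_study("wild-type", seed=seed, n_curves=n_curves)


def hit_rate_study(
    seed: int,
    n_curves: int = 600,
    specific_fraction: float = 0.075,
    adhesion_fraction: float = 0.10,
) -> MapAnalysis:
    """Simulate a realistic mixed force map and measure the hit rate."""
    cfg = PullingConfig(seed=seed)
    dataset = simulate_map(
        cfg,
        "wild-type",
        n_curves=n_curves,
        fractions=(specific_fraction, adhesion_fraction),
        seed=seed,
    )
    return analyze_map(dataset.curves)


@dataclass(frozen=True)
class DfsStudyResult:
    points: list[DFSPoint]
    fit: BellEvansFit


def dfs_study(
    seed: int,
    velocities_nm_s: tuple[float, ...] = (200.0, 500.0, 1000.0, 5000.0),
    n_curves_each: int = 80,
    min_count: int = 30,
    scenario: str = "XL_barrel",
) -> DfsStudyResult:
    """Multi-velocity study: simulate single-rupture pulls across the
    experimental velocity range, pool unbinding events per velocity, and
    fit the Bell-Evans line to modal force vs ln(mean loading rate).

    The default scenario has no unfolding transition, matching the
    construct a dynamic force spectrum of pure complex unbinding is
    measured on.  Note the extracted x_beta is systematically larger than
    the generator's because the conventional loading-rate rule (WLC slope
    times velocity) neglects cantilever compliance; the constant-rate
    cross-check in :func:`forcespec.simulate.sample_rupture_forces` is the
    quantitative recovery route.
    """
    events_by_velocity = {}
    segments = scenario_presets(scenario)
    rng = np.random.default_rng(seed)
    for v in velocities_nm_s:
        cfg = PullingConfig(retraction_velocity_nm_s=v, seed=seed)
        curves = [
            simulate_pull(cfg, segments, f"v{v:g}-{i:03d}", rng=rng)[0]
            for i in range(n_curves_each)
        ]
        analysis = analyze_map(curves, min_count=min_count)
        # the unbinding event is the last accepted event on each curve
        unbinding = []
        for evs in analysis.events_by_curve.values():
            acc = [ev for ev in evs if ev.accepted]
            if acc:
                unbinding.append(max(acc, key=lambda ev: ev.extension_at_rupture_nm))
        events_by_velocity[v] = unbinding
    points = build_dfs(events_by_velocity, min_count=min_count)
    return DfsStudyResult(points=points, fit=fit_bell_evans(points))


@dataclass(frozen=True)
class MstStudyResult:
    replicate_fits: list[BindingFit]
    mean_KD_M: float
    half_range_M: float


def mst_kd_study(
    seed: int,
    true_KD_M: float = 9.4e-6,
    noise_fraction_of_amplitude: float = 0.02,
    n_replicates: int = 3,
) -> MstStudyResult:
    """Simulate replicate 16-point titrations at the stated noise level
    and fit each; the reported KD is the replicate mean (with half-range),
    mirroring standard replicate aggregation."""
    from .simulate import DEFAULT_SIGNAL

    amplitude = abs(DEFAULT_SIGNAL.fnorm_bound - DEFAULT_SIGNAL.fnorm_unbound)
    sigma = noise_fraction_of_amplitude * amplitude
    fits = []
    for r in range(n_replicates):
        sub_seed = (seed + 7919 * r) % (2**31 - 1)
        series = simulate_mst(
            true_KD_M, noise_sigma=sigma, seed=sub_seed, replicate_id=f"rep{r + 1}"
        )
        fits.append(fit_kd(series, seed=sub_seed))
    kds = np.array([f.KD_M for f in fits])
    return MstStudyResult(
        replicate_fits=fits,
        mean_KD_M=float(kds.mean()),
        half_range_M=float((kds.max() - kds.min()) / 2.0),
    )
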