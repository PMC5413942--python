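"""Ensemble statistics over accepted rupture events.

Covers the population-level summaries built from per-event fits:

* histograms of rupture force (FU), contour length (Lc) and contour-length
  increment (dLc) with single-Gaussian modal fits — the mode of the fitted
  Gaussian is the "most probable" value reported per condition;
* per-curve dLc records: the difference between successive fitted contour
  lengths on the same curve measures how many residues unfolded at each
  rupture (dLc / 0.4 nm per residue);
* triplicate aggregation as mean of replicate modes +/- half the range;
* the Lc-FU density scatter and its hotspot report, used to judge the
  specificity of an interaction (a specific complex ruptures at a
  reproducible, correlated force and length, producing a dense cluster);
* the dynamic force spectrum: modal FU against the natural log of the mean
  loading rate, linear under Bell-Evans kinetics with slope kB*T/x_beta,
  from which the distance to the transition state x_beta and the intrinsic
  off-rate k0 are extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .events import RuptureEvent
from .polymer import DEFAULT_TEMPERATURE_K, thermal_energy

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianFit",
    "DeltaLcRecord",
    "DFSPoint",
    "BellEvansFit",
    "HotspotReport",
    "fit_gaussian_mode",
    "compute_delta_lc",
    "aggregate_replicates",
    "density_scatter",
    "build_dfs",
    "fit_bell_evans",
]


@dataclass(frozen=True)
class GaussianFit:
    """Single-Gaussian fit to a histogram; ``mode`` is the fitted mean."""

    mode: float
    sigma: float
    amplitude: float
    bin_width: float
    n: int


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_mode(
    values, bin_width: float, min_count: int = 30
) -> GaussianFit:
    """Histogram ``values`` at ``bin_width`` and fit a single Gaussian.

    Returns the fitted mean as the modal (most probable) value.  Raw bin
    counts are fitted by unweighted least squares.

    Raises
    ------
    ValueError
        If fewer than ``min_count`` values are given or the sample is
        degenerate (all values equal).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_count:
        raise ValueError(
            f"need at least {min_count} values for a modal fit, got {v.size}"
        )
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: all values identical")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")

    # pad the range with empty bins so a narrow distribution still gives
    # the fit more points than parameters
    pad = 3 * bin_width
    lo = np.floor(v.min() / bin_width) * bin_width - pad
    hi = np.ceil(v.max() / bin_width) * bin_width + pad
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    amp0 = float(counts.max())
    mu0 = float(centers[np.argmax(counts)])
    sigma0 = max(float(v.std()), bin_width / 2.0)
    # sigma is bounded below at a quarter bin so a distribution narrower
    # than the binning cannot collapse the fit
    popt, _ = curve_fit(
        _gauss,
        centers,
        counts,
        p0=(amp0, mu0, sigma0),
        bounds=([0.0, lo, bin_width / 4.0], [np.inf, hi, hi - lo]),
        maxfev=10000,
    )
    amp, mu, sigma = popt
    return GaussianFit(
        mode=float(mu),
        sigma=abs(float(sigma)),
        amplitude=float(amp),
        bin_width=float(bin_width),
        n=int(v.size),
    )


@dataclass(frozen=True)
class DeltaLcRecord:
    """Successive contour-length increments on one multi-event curve."""

    curve_id: str
    Lc_values_nm: tuple[float, ...]
    delta_Lc1_nm: float
    delta_Lc2_nm: float | None
    delta_Lc_total_nm: float

    def __post_init__(self) -> None:
        if any(np.diff(self.Lc_values_nm) <= 0):
            raise ValueError("contour lengths must be strictly increasing")


def compute_delta_lc(
    events_by_curve: dict[str, list[RuptureEvent]],
    bin_width_nm: float = 2.0,
    min_count: int = 30,
) -> tuple[list[DeltaLcRecord], GaussianFit | None]:
    """Per-curve contour-length increments and their modal value.

    Only curves with >= 2 accepted events contribute; the increments are
    computed per curve (difference of that curve's fitted Lc values, ordered
    by separation) and then histogrammed — never as a difference of
    ensemble modal Lc values.  Curves with fewer than two events are
    skipped with a log entry.
    """
    records: list[DeltaLcRecord] = []
    for curve_id, events in events_by_curve.items():
        acc = sorted(
            (ev for ev in events if ev.accepted),
            key=lambda ev: ev.extension_at_rupture_nm,
        )
        if len(acc) < 2:
            logger.info(
                "curve %s: %d accepted event(s), skipped for dLc", curve_id, len(acc)
            )
            continue
        lcs = [ev.fitted_Lc_nm for ev in acc]
        if any(np.diff(lcs) <= 0):
            logger.warning(
                "curve %s: non-increasing fitted Lc sequence %s, skipped", curve_id, lcs
            )
            continue
        records.append(
            DeltaLcRecord(
                curve_id=curve_id,
                Lc_values_nm=tuple(lcs),
                delta_Lc1_nm=lcs[1] - lcs[0],
                delta_Lc2_nm=(lcs[2] - lcs[1]) if len(lcs) >= 3 else None,
                delta_Lc_total_nm=lcs[-1] - lcs[0],
            )
        )
    mode = None
    d1 = [r.delta_Lc1_nm for r in records]
    if len(d1) >= max(min_count, 4) and np.ptp(d1) > 0:
        mode = fit_gaussian_mode(d1, bin_width_nm, min_count=min_count)
    return records, mode


def aggregate_replicates(modes) -> tuple[float, float | None]:
    """Replicate aggregation: mean of modes +/- half the range.

    With a single replicate the error is undefined (returned as None).
    """
    m = np.asarray(modes, dtype=float)
    if m.size == 0:
        raise ValueError("no replicate modes given")
    if m.size == 1:
        logger.warning("single replicate: error term undefined")
        return float(m[0]), None
    return float(m.mean()), float((m.max() - m.min()) / 2.0)


@dataclass(frozen=True)
class HotspotReport:
    """Hotspots of the Lc-FU density scatter."""

    n_hotspots: int
    centroids: tuple[tuple[float, float], ...]  # (Lc_nm, FU_pN)
    grid: np.ndarray = field(repr=False, compare=False, default=None)
    lc_edges: np.ndarray = field(repr=False, compare=False, default=None)
    fu_edges: np.ndarray = field(repr=False, compare=False, default=None)


def density_scatter(
    Lc_nm,
    FU_pN,
    lc_bin_nm: float = 5.0,
    fu_bin_pN: float = 10.0,
    hotspot_factor: float = 5.0,
    min_fraction: float = 0.02,
    min_n: int = 30,
) -> HotspotReport:
    """2D density of the (Lc, FU) scatter and its hotspot report.

    A hotspot is a connected cluster of bins whose counts exceed both
    ``hotspot_factor`` times the spatial median density (median count over
    the whole grid, empty bins included) and ``min_fraction`` of the total
    number of points (the latter keeps Poisson fluctuations of a diffuse
    scatter from registering).  Cluster centroids are count-weighted
    bin-center means.
    """
    Lc = np.asarray(Lc_nm, dtype=float)
    FU = np.asarray(FU_pN, dtype=float)
    if Lc.size != FU.size:
        raise ValueError("Lc and FU arrays must be paired")
    if Lc.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {Lc.size}")

    lc_lo = np.floor(Lc.min() / lc_bin_nm) * lc_bin_nm
    lc_hi = np.ceil(Lc.max() / lc_bin_nm) * lc_bin_nm + lc_bin_nm
    fu_lo = np.floor(FU.min() / fu_bin_pN) * fu_bin_pN
    fu_hi = np.ceil(FU.max() / fu_bin_pN) * fu_bin_pN + fu_bin_pN
    lc_edges = np.arange(lc_lo, lc_hi + lc_bin_nm / 2, lc_bin_nm)
    fu_edges = np.arange(fu_lo, fu_hi + fu_bin_pN / 2, fu_bin_pN)
    grid, _, _ = np.histogram2d(Lc, FU, bins=(lc_edges, fu_edges))

    med = float(np.median(grid))
    threshold = max(hotspot_factor * med, min_fraction * Lc.size)
    hot = grid > threshold

    labels, n_clusters = ndimage.label(hot)
    centroids = []
    lc_centers = 0.5 * (lc_edges[:-1] + lc_edges[1:])
    fu_centers = 0.5 * (fu_edges[:-1] + fu_edges[1:])
    for k in range(1, n_clusters + 1):
        mask = labels == k
        wts = grid[mask]
        ii, jj = np.nonzero(mask)
        centroids.append(
            (
                float(np.average(lc_centers[ii], weights=wts)),
                float(np.average(fu_centers[jj], weights=wts)),
            )
        )
    centroids.sort()
    return HotspotReport(
        n_hotspots=n_clusters,
        centroids=tuple(centroids),
        grid=grid,
        lc_edges=lc_edges,
        fu_edges=fu_edges,
    )


@dataclass(frozen=True)
class DFSPoint:
    """One dynamic-force-spectrum point: a velocity condition's summary."""

    retraction_velocity_nm_s: float
    mean_ln_loading_rate: float
    modal_FU_pN: float
    error_pN: float | None = None


@dataclass(frozen=True)
class BellEvansFit:
    """Linear Bell-Evans fit of modal force vs ln(loading rate).

    slope = kB*T / x_beta; the intercept, together with the slope, yields
    the intrinsic (zero-force) off-rate k0 through the modal-force relation
    F* = (kB*T/x_beta) * ln(x_beta * r / (k0 * kB*T)).
    """

    slope: float
    intercept: float
    x_beta_nm: float
    k0_per_s: float
    r_squared: float
    temperature_K: float


def build_dfs(
    events_by_velocity: dict[float, list[RuptureEvent]],
    fu_bin_pN: float = 10.0,
    min_count: int = 30,
    replicate_modes: dict[float, list[float]] | None = None,
) -> list[DFSPoint]:
    """Build dynamic-force-spectrum points from per-velocity event pools.

    Each point takes the modal FU (Gaussian fit at ``fu_bin_pN``) and the
    natural log of the mean per-event loading rate at that velocity.
    Optional per-velocity replicate modes provide half-range error bars.
    """
    points = []
    for v in sorted(events_by_velocity):
        events = [ev for ev in events_by_velocity[v] if ev.accepted]
        if not events:
            raise ValueError(f"no accepted events at velocity {v}")
        rates = np.array([ev.loading_rate_pN_s for ev in events], dtype=float)
        if np.any(rates <= 0):
            raise ValueError(f"non-positive loading rate at velocity {v}")
        fu = [ev.rupture_force_pN for ev in events]
        modal = fit_gaussian_mode(fu, fu_bin_pN, min_count=min_count)
        err = None
        if replicate_modes and v in replicate_modes:
            _, err = aggregate_replicates(replicate_modes[v])
        points.append(
            DFSPoint(
                retraction_velocity_nm_s=float(v),
                mean_ln_loading_rate=float(np.log(rates.mean())),
                modal_FU_pN=modal.mode,
                error_pN=err,
            )
        )
    return points


def fit_bell_evans(
    points: list[DFSPoint], temperature_K: float = DEFAULT_TEMPERATURE_K
) -> BellEvansFit:
    """Fit the dynamic force spectrum with the Bell-Evans line.

    Linear regression of modal FU on ln(loading rate); a non-positive slope
    signals non-Bell behaviour and rejects the fit.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 velocities for a dynamic force spectrum")
    x = np.array([p.mean_ln_loading_rate for p in points])
    y = np.array([p.modal_FU_pN for p in points])
    reg = linregress(x, y)
    if reg.slope <= 0:
        raise ValueError(
            f"non-positive Bell-Evans slope ({reg.slope:.3g}); "
            "force does not increase with loading rate"
        )
    kBT = thermal_energy(temperature_K)
    x_beta = kBT / reg.slope
    # F* = slope*ln(r) + slope*ln(x_beta/(k0*kBT))  =>  intercept identifies k0
    k0 = (x_beta / kBT) * np.exp(-reg.intercept / reg.slope)
    return BellEvansFit(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        x_beta_nm=float(x_beta),
        k0_per_s=float(k0),
        r_squared=float(reg.rvalue**2),
        temperature_K=temperature_K,
    )
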