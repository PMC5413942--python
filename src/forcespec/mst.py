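"""Microscale-thermophoresis (MST) binding analysis.

An MST titration reports a normalized fluorescence (Fnorm) for each point
of a serial dilution of the unlabeled binding partner against a fixed
concentration of the fluorescently labeled species.  Fnorm is a linear
reporter of the fraction of labeled molecules bound, so the signal model is

    Fnorm(L) = Fnorm_unbound + FB(L) * (Fnorm_bound - Fnorm_unbound)

with FB the exact 1:1 law-of-mass-action fraction bound including
depletion of the labeled species A:

    FB = (A + L + KD - sqrt((A + L + KD)^2 - 4*A*L)) / (2*A)

The dissociation constant is fitted by nonlinear least squares over
(KD, Fnorm_unbound, Fnorm_bound) against the dilution series plotted on a
log10 concentration axis.  The physical decomposition of the MST signal
(temperature-jump sensitivity, Soret coefficient) is not separately
identifiable from a titration; only the composite bound/unbound amplitudes
enter the fit, while the signal synthesis in the simulator may populate
the physical fields.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "TitrationSeries",
    "MSTSignalModel",
    "BindingFit",
    "fraction_bound",
    "fnorm_model",
    "fit_kd",
]


@dataclass
class TitrationSeries:
    """A serial-dilution titration: in-capillary ligand concentrations (M)
    against normalized fluorescence readings."""

    ligand_concentrations_M: np.ndarray
    fnorm_values: np.ndarray
    labeled_concentration_M: float = 250e-9
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.ligand_concentrations_M = np.asarray(
            self.ligand_concentrations_M, dtype=float
        )
        self.fnorm_values = np.asarray(self.fnorm_values, dtype=float)
        c = self.ligand_concentrations_M
        if c.size != self.fnorm_values.size:
            raise ValueError("concentration and fnorm arrays must be paired")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.labeled_concentration_M <= 0:
            raise ValueError("labeled concentration must be positive")

    def __len__(self) -> int:
        return int(self.ligand_concentrations_M.size)


@dataclass(frozen=True)
class MSTSignalModel:
    """Two-state MST signal: composite amplitudes plus (optional) physical
    components of the thermophoretic signal used by the simulator."""

    fnorm_unbound: float
    fnorm_bound: float
    temperature_jump_sensitivity: float | None = None
    delta_T_K: float | None = None
    soret_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.fnorm_bound == self.fnorm_unbound:
            raise ValueError("bound and unbound Fnorm must differ for a fittable series")


@dataclass(frozen=True)
class BindingFit:
    """Result of a law-of-mass-action KD fit."""

    KD_M: float
    fnorm_unbound: float
    fnorm_bound: float
    residual_rms: float
    ci_low_M: float | None
    ci_high_M: float | None
    n_points: int

    def __post_init__(self) -> None:
        if self.KD_M <= 0:
            raise ValueError("KD must be positive")


def fraction_bound(A_total, L_total, KD):
    """Exact 1:1 fraction of A bound, with depletion of A.

    All arguments in molar; scalars or arrays (broadcast).  Monotone
    increasing in ``L_total`` and decreasing in ``KD``; approaches the
    hyperbola L/(L+KD) as A -> 0 and saturates at 1 for L >> A, KD.
    """
    A = np.asarray(A_total, dtype=float)
    L = np.asarray(L_total, dtype=float)
    K = np.asarray(KD, dtype=float)
    if np.any(A <= 0) or np.any(L <= 0) or np.any(K <= 0):
        raise ValueError("A_total, L_total and KD must all be positive")
    s = A + L + K
    disc = s * s - 4.0 * A * L
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * A)
    fb = np.clip(fb, 0.0, 1.0)
    return fb if fb.ndim else float(fb)


def fnorm_model(FB, signal: MSTSignalModel):
    """Linear two-state Fnorm: unbound amplitude plus FB times the span."""
    fb = np.asarray(FB, dtype=float)
    if np.any(fb < 0) or np.any(fb > 1):
        raise ValueError("fraction bound must lie in [0, 1]")
    out = signal.fnorm_unbound + fb * (signal.fnorm_bound - signal.fnorm_unbound)
    return out if out.ndim else float(out)


def fit_kd(
    series: TitrationSeries,
    n_bootstrap: int = 200,
    seed: int | None = 0,
    min_amplitude_sigmas: float = 3.0,
) -> BindingFit:
    """Fit KD, and the bound/unbound amplitudes, to a titration.

    Nonlinear least squares (unweighted) of the depletion-corrected 1:1
    binding model; KD is fitted on a log scale with the initial guess at
    the concentration of half signal amplitude.  A bootstrap (resampling
    residuals, ``n_bootstrap`` rounds, seeded) gives a 95% confidence
    interval on KD.

    Raises
    ------
    ValueError
        If fewer than 8 concentrations are given, the fit does not
        converge, or the fitted amplitude is indistinguishable from the
        residual noise (``min_amplitude_sigmas``).
    """
    c = series.ligand_concentrations_M
    y = series.fnorm_values
    A = series.labeled_concentration_M
    if len(series) < 8:
        raise ValueError(f"need >= 8 concentrations, got {len(series)}")

    span = y[-1] - y[0]
    if span == 0:
        raise ValueError("titration has zero signal amplitude")
    half = y[0] + span / 2.0
    # first concentration crossing half-amplitude -> initial KD
    crossing = np.flatnonzero(np.sign(y - half) != np.sign(y[0] - half))
    kd0 = c[crossing[0]] if crossing.size else float(np.sqrt(c[0] * c[-1]))

    def model(conc, log10_kd, f_ub, f_b):
        fb = fraction_bound(A, conc, 10.0**log10_kd)
        return f_ub + fb * (f_b - f_ub)

    p0 = (np.log10(kd0), float(y[0]), float(y[-1]))
    try:
        popt, _ = curve_fit(model, c, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"KD fit did not converge: {exc}") from exc
    log10_kd, f_ub, f_b = popt
    kd = float(10.0**log10_kd)

    resid = y - model(c, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if abs(f_b - f_ub) < min_amplitude_sigmas * rms:
        raise ValueError(
            f"fitted amplitude {abs(f_b - f_ub):.3g} indistinguishable from "
            f"noise (rms {rms:.3g})"
        )

    if not (c[0] * 10.0 <= kd <= c[-1] / 10.0):
        warnings.warn(
            "fitted KD is not bracketed by a decade of concentrations on "
            "both sides; estimate may be poorly constrained",
            stacklevel=2,
        )

    ci_low = ci_high = None
    if n_bootstrap and n_bootstrap > 1:
        rng = np.random.default_rng(seed)
        fitted = model(c, *popt)
        kds = []
        for _ in range(n_bootstrap):
            y_star = fitted + rng.choice(resid, size=resid.size, replace=True)
            try:
                p_star, _ = curve_fit(model, c, y_star, p0=popt, maxfev=5000)
                kds.append(10.0 ** p_star[0])
            except RuntimeError:  # pragma: no cover - rare non-convergence
                continue
        if len(kds) >= max(20, n_bootstrap // 4):
            ci_low, ci_high = (
                float(np.percentile(kds, 2.5)),
                float(np.percentile(kds, 97.5)),
            )
        else:
            logger.warning("bootstrap mostly failed; CI omitted")

    return BindingFit(
        KD_M=kd,
        fnorm_unbound=float(f_ub),
        fnorm_bound=float(f_b),
        residual_rms=rms,
        ci_low_M=ci_low,
        ci_high_M=ci_high,
        n_points=len(series),
    )
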