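"""Force-curve data model, file I/O, and instrument-to-analysis-frame conversion.

A raw constant-velocity retraction is recorded in the instrument frame:
piezo displacement and cantilever deflection (or pre-converted force)
against time, plus the metadata needed to interpret them (spring constant,
velocities, temperature).  Analysis happens in the tip-sample frame: force
versus tip-sample separation, with the force zeroed on the far-from-surface
baseline and the distance zeroed at the hard-contact point.

Sign convention: deflection and force are tensile-positive (a stretched
tether pulls the tip toward the surface and gives positive force); the
repulsive hard-contact wall is negative.  Tip-sample separation is
``piezo - deflection - contact_offset``.

Curves are stored one per file in a TSV dialect: ``#``-prefixed
``key<TAB>value`` metadata lines, then a column header line and the data
columns ``time_s``, ``piezo_nm``, and ``deflection_nm`` (or ``force_pN``
for pre-converted data).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawForceCurve",
    "ProcessedCurve",
    "ForceMap",
    "ConversionConfig",
    "CurveFormatError",
    "convert_to_force_separation",
    "read_curve",
    "write_curve",
    "read_map",
    "write_events_table",
    "read_events_table",
]

MIN_SAMPLES = 16


class CurveFormatError(ValueError):
    """Raised when a curve file violates the documented dialect."""


@dataclass
class RawForceCurve:
    """A single retraction trace in the instrument frame.

    Either ``deflection_nm`` or ``force_pN`` must be provided; with
    deflection, force is ``spring_constant * deflection``.
    """

    time_s: np.ndarray
    piezo_displacement_nm: np.ndarray
    deflection_nm: np.ndarray | None
    spring_constant_pN_per_nm: float
    retraction_velocity_nm_s: float
    curve_id: str
    force_pN: np.ndarray | None = None
    approach_velocity_nm_s: float = 1000.0
    temperature_K: float = 298.0
    segment: str = "retract"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.piezo_displacement_nm = np.asarray(
            self.piezo_displacement_nm, dtype=float
        )
        if self.deflection_nm is not None:
            self.deflection_nm = np.asarray(self.deflection_nm, dtype=float)
        if self.force_pN is not None:
            self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.deflection_nm is None and self.force_pN is None:
            raise ValueError("curve needs a deflection_nm or force_pN channel")
        n = self.time_s.size
        for name in ("piezo_displacement_nm", "deflection_nm", "force_pN"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValueError(f"channel {name} length {arr.size} != time length {n}")
        if n < MIN_SAMPLES:
            raise ValueError(f"curve has {n} samples; need >= {MIN_SAMPLES}")
        if self.spring_constant_pN_per_nm <= 0:
            raise ValueError("spring constant must be positive")
        if self.retraction_velocity_nm_s <= 0 or self.approach_velocity_nm_s <= 0:
            raise ValueError("velocities must be positive")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    def raw_force_pN(self) -> np.ndarray:
        """Force channel before zeroing (pN, tensile-positive)."""
        if self.force_pN is not None:
            return self.force_pN
        return self.spring_constant_pN_per_nm * self.deflection_nm


@dataclass
class ProcessedCurve:
    """A retraction in the analysis frame: force vs tip-sample separation."""

    tip_sample_separation_nm: np.ndarray
    force_pN: np.ndarray
    baseline_offset_pN: float
    contact_offset_nm: float
    curve_id: str
    retraction_velocity_nm_s: float
    spring_constant_pN_per_nm: float
    temperature_K: float = 298.0
    contact_found: bool = True
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.force_pN.size)


@dataclass
class ForceMap:
    """A collection of approach-retract cycles taken over a surface grid."""

    curves: list[RawForceCurve]
    map_area_um2: float | None = None
    cycles: int | None = None

    def __post_init__(self) -> None:
        if self.cycles is None:
            self.cycles = len(self.curves)
        if self.cycles != len(self.curves):
            raise ValueError(
                f"declared {self.cycles} cycles but map holds {len(self.curves)} curves"
            )

    def __len__(self) -> int:
        return len(self.curves)


@dataclass(frozen=True)
class ConversionConfig:
    """Tunables for instrument-to-analysis-frame conversion.

    baseline_fraction
        Fraction of the trace tail (far from the surface) averaged to zero
        the force.
    wall_fraction
        The most-repulsive fraction of the hard-contact wall used for the
        linear contact fit; the zero-force intercept of that line is the
        contact point.
    wall_threshold_pN
        Repulsive force beyond which a sample is considered part of the
        contact wall.
    """

    baseline_fraction: float = 0.2
    wall_fraction: float = 0.25
    wall_threshold_pN: float = 25.0


def convert_to_force_separation(
    raw: RawForceCurve, config: ConversionConfig | None = None
) -> ProcessedCurve:
    """Convert an instrument-frame retraction to force vs separation.

    The force is zeroed on the mean of the retraction baseline (the final
    ``baseline_fraction`` of the trace, far from the surface).  The zero of
    distance is the hard-contact point: a line fitted to the steepest
    (most repulsive) ``wall_fraction`` of the contact wall, taken at its
    zero-force intercept.  Curves with no detectable contact wall (e.g.
    pre-zeroed force input) keep a zero contact offset and are marked
    ``contact_found=False``.
    """
    cfg = config or ConversionConfig()
    if raw.segment != "retract":
        raise ValueError(
            f"curve {raw.curve_id}: conversion requires a retract segment, "
            f"got {raw.segment!r}"
        )
    n = raw.n_samples
    n_base = int(round(cfg.baseline_fraction * n))
    if n_base < 4:
        raise ValueError(
            f"curve {raw.curve_id}: baseline window of {n_base} samples is too "
            f"short (need >= 4; {n} samples at fraction {cfg.baseline_fraction})"
        )

    force = raw.raw_force_pN().astype(float)
    piezo = raw.piezo_displacement_nm

    baseline = float(np.mean(force[-n_base:]))
    force_zeroed = force - baseline
    deflection = force_zeroed / raw.spring_constant_pN_per_nm

    # Hard-contact wall: strongly repulsive (negative) samples near the start.
    wall = np.flatnonzero(force_zeroed < -cfg.wall_threshold_pN)
    contact_offset = 0.0
    contact_found = False
    if wall.size >= 4:
        wall_forces = force_zeroed[wall]
        cutoff = np.quantile(wall_forces, cfg.wall_fraction)
        steep = wall[wall_forces <= cutoff]
        if steep.size >= 2 and np.ptp(piezo[steep]) > 0:
            slope, intercept = np.polyfit(piezo[steep], force_zeroed[steep], 1)
            if slope > 0:  # wall force rises toward zero as the tip retracts
                contact_piezo = -intercept / slope
                # contact offset is in separation coordinates
                contact_offset = float(contact_piezo)
                contact_found = True

    separation = piezo - deflection - contact_offset
    return ProcessedCurve(
        tip_sample_separation_nm=separation,
        force_pN=force_zeroed,
        baseline_offset_pN=baseline,
        contact_offset_nm=contact_offset,
        curve_id=raw.curve_id,
        retraction_velocity_nm_s=raw.retraction_velocity_nm_s,
        spring_constant_pN_per_nm=raw.spring_constant_pN_per_nm,
        temperature_K=raw.temperature_K,
        contact_found=contact_found,
        provenance={
            "baseline_fraction": cfg.baseline_fraction,
            "wall_fraction": cfg.wall_fraction,
            "wall_threshold_pN": cfg.wall_threshold_pN,
        },
    )


# --- file dialect ---------------------------------------------------------

_MANDATORY_META = {
    "curve_id": str,
    "spring_constant_pN_per_nm": float,
    "retraction_velocity_nm_s": float,
}
_OPTIONAL_META = {
    "approach_velocity_nm_s": float,
    "temperature_K": float,
    "segment": str,
}
_CHANNEL_COLUMNS = ("time_s", "piezo_nm", "deflection_nm", "force_pN")


def write_curve(curve: RawForceCurve, path: str | Path) -> None:
    """Write a curve in the TSV dialect (metadata header + columns)."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "time_s": curve.time_s,
        "piezo_nm": curve.piezo_displacement_nm,
    }
    if curve.deflection_nm is not None:
        cols["deflection_nm"] = curve.deflection_nm
    if curve.force_pN is not None:
        cols["force_pN"] = curve.force_pN
    with path.open("w") as fh:
        fh.write(f"#curve_id\t{curve.curve_id}\n")
        fh.write(f"#spring_constant_pN_per_nm\t{curve.spring_constant_pN_per_nm!r}\n")
        fh.write(f"#retraction_velocity_nm_s\t{curve.retraction_velocity_nm_s!r}\n")
        fh.write(f"#approach_velocity_nm_s\t{curve.approach_velocity_nm_s!r}\n")
        fh.write(f"#temperature_K\t{curve.temperature_K!r}\n")
        fh.write(f"#segment\t{curve.segment}\n")
        fh.write("\t".join(cols) + "\n")
        arr = np.column_stack(list(cols.values()))
        np.savetxt(fh, arr, fmt="%.17g", delimiter="\t")


def read_curve(path: str | Path) -> RawForceCurve:
    """Read a curve written in the TSV dialect.

    Raises
    ------
    CurveFormatError
        On a malformed header, ragged columns, or missing mandatory
        metadata; the message names the offending field.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_cols: list[str] | None = None
    data_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        line = line.rstrip("\n")
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if len(parts) != 2:
                raise CurveFormatError(
                    f"{path}: malformed metadata line {i + 1}: {line!r}"
                )
            meta[parts[0]] = parts[1]
        else:
            header_cols = line.split("\t")
            data_start = i + 1
            break
    if header_cols is None:
        raise CurveFormatError(f"{path}: no column header found")
    unknown = set(header_cols) - set(_CHANNEL_COLUMNS)
    if unknown:
        raise CurveFormatError(f"{path}: unknown columns {sorted(unknown)}")

    kwargs: dict = {}
    for key, typ in _MANDATORY_META.items():
        if key not in meta:
            raise CurveFormatError(f"{path}: missing mandatory metadata {key!r}")
        try:
            kwargs[key] = typ(meta[key])
        except ValueError as exc:
            raise CurveFormatError(f"{path}: bad value for {key!r}") from exc
    for key, typ in _OPTIONAL_META.items():
        if key in meta:
            kwargs[key] = typ(meta[key])

    rows = []
    ncol = len(header_cols)
    for i, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise CurveFormatError(
                f"{path}: ragged row at line {i}: expected {ncol} columns, "
                f"got {len(parts)}"
            )
        rows.append([float(p) for p in parts])
    data = np.asarray(rows, dtype=float)
    cols = {name: data[:, j] for j, name in enumerate(header_cols)}
    if "time_s" not in cols or "piezo_nm" not in cols:
        raise CurveFormatError(f"{path}: missing time_s or piezo_nm column")
    return RawForceCurve(
        time_s=cols["time_s"],
        piezo_displacement_nm=cols["piezo_nm"],
        deflection_nm=cols.get("deflection_nm"),
        force_pN=cols.get("force_pN"),
        **kwargs,
    )


def read_map(
    directory: str | Path,
    pattern: str = "*.tsv",
    map_area_um2: float | None = None,
) -> ForceMap:
    """Read every curve file in a directory into a :class:`ForceMap`."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no curves found in {directory} ({pattern})")
    curves = [read_curve(p) for p in paths]
    return ForceMap(curves=curves, map_area_um2=map_area_um2)


EVENT_TABLE_COLUMNS = [
    "curve_id",
    "event_index",
    "x_r_nm",
    "FU_pN",
    "Lc_nm",
    "loading_rate_pN_s",
    "residual_pN",
    "accepted",
    "reason",
]


def write_events_table(events: Sequence, path: str | Path) -> pd.DataFrame:
    """Write fitted/filtered rupture events as a TSV with a fixed column set.

    ``events`` are :class:`~forcespec.events.RuptureEvent`-like records (any
    dataclass or mapping with the event fields).
    """
    records = []
    for ev in events:
        d = dataclasses.asdict(ev) if dataclasses.is_dataclass(ev) else dict(ev)
        records.append(
            {
                "curve_id": d.get("curve_id", ""),
                "event_index": d.get("event_index"),
                "x_r_nm": d.get("extension_at_rupture_nm"),
                "FU_pN": d.get("rupture_force_pN"),
                "Lc_nm": d.get("fitted_Lc_nm"),
                "loading_rate_pN_s": d.get("loading_rate_pN_s"),
                "residual_pN": d.get("fit_residual_rms_pN"),
                "accepted": d.get("accepted", True),
                "reason": d.get("reason", ""),
            }
        )
    df = pd.DataFrame.from_records(records, columns=EVENT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_events_table(path: str | Path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise CurveFormatError(f"{path}: events table missing columns {sorted(missing)}")
    return df
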