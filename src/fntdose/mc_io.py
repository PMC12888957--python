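"""Phase-space file I/O and the simulation-side dosimetry path.

Monte Carlo transport of the treatment field yields event-by-event records
of charged particles crossing a scoring plane coplanar with the detector
surface.  The exchange format is a TSV (optionally gzip-compressed) with the
fixed header

    z  a  kinetic_energy_mev  let_water_kev_um  polar_deg  azimuth_deg  weight

Records are mapped into the same dosimetry path as image-derived tracks:
the minimum-range filter (enough residual range to reach 10 um depth along
the slant path) and the 25 keV/um LET split are applied with the same
parameters as on the experimental side, so simulated and measured fluence,
D and H are directly comparable.  Per-species breakdowns quantify which ion
types carry the fluence, the absorbed dose and the dose equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosimetry import (
    RangeTable,
    compute_dose,
    compute_dose_equivalent,
    quality_factor,
    range_filter_phase_space,
    split_by_let,
)
from .errors import ConfigurationError, DataError

__all__ = [
    "PHASE_SPACE_COLUMNS",
    "PhaseSpaceRecord",
    "species_name",
    "read_phase_space",
    "write_phase_space",
    "records_to_tracks",
    "species_breakdown",
    "batch_uncertainty",
]

PHASE_SPACE_COLUMNS = ("z", "a", "kinetic_energy_mev", "let_water_kev_um",
                       "polar_deg", "azimuth_deg", "weight")


@dataclass(frozen=True)
class PhaseSpaceRecord:
    """One charged particle crossing the scoring plane."""

    z: int
    a: int
    kinetic_energy_mev: float
    let_water_kev_um: float
    polar_deg: float
    azimuth_deg: float
    weight: float = 1.0


_SPECIES_NAMES = {
    (1, 1): "proton",
    (1, 2): "deuteron",
    (1, 3): "triton",
    (2, 3): "helium-3",
    (2, 4): "helium-4",
}


def species_name(z, a) -> str:
    """Canonical species label for a (z, a) pair; ions heavier than helium
    are pooled into a single 'Z>2' bucket."""
    if z > 2:
        return "Z>2"
    return _SPECIES_NAMES.get((int(z), int(a)), f"z{int(z)}a{int(a)}")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _validate_rows(df: pd.DataFrame):
    """Boolean mask of valid rows plus a list of (line_number, reason)."""
    finite = np.ones(len(df), dtype=bool)
    for col in PHASE_SPACE_COLUMNS:
        finite &= np.isfinite(df[col].to_numpy(dtype=float, na_value=np.nan))
    checks = [
        (df["z"] >= 1, "z must be >= 1 for charged ions"),
        (df["a"] >= 1, "a must be >= 1"),
        (df["kinetic_energy_mev"] > 0, "energy must be > 0"),
        (df["let_water_kev_um"] > 0, "LET must be > 0"),
        (df["polar_deg"] >= 0, "polar_deg must be >= 0"),
        (df["polar_deg"] < 90, "polar_deg must be < 90"),
        (df["weight"] >= 0, "weight must be >= 0"),
    ]
    valid = finite.copy()
    report = []
    for i in np.flatnonzero(~finite):
        report.append((int(i) + 2, "non-numeric or missing value"))
    for mask, reason in checks:
        bad = finite & ~mask.to_numpy(dtype=bool)
        for i in np.flatnonzero(bad):
            report.append((int(i) + 2, reason))  # +2: header + 1-based
        valid &= ~bad
    report.sort()
    return valid, report


def read_phase_space(path, strict: bool = False):
    """Read a phase-space TSV (gzip accepted).

    Returns ``(records, rejected)`` where ``records`` is a validated
    DataFrame and ``rejected`` lists ``(line_number, reason)`` for malformed
    rows.  A missing column raises :class:`DataError` naming it; with
    ``strict=True`` any invalid row raises as well.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"phase-space file {path} is empty") from exc
    missing = [c for c in PHASE_SPACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(
            f"phase-space file {path} is missing column(s): {', '.join(missing)}")
    df = df[list(PHASE_SPACE_COLUMNS)]
    if len(df) == 0:
        return df, []
    df = df.apply(pd.to_numeric, errors="coerce")
    valid, report = _validate_rows(df)
    if report and strict:
        lines = "; ".join(f"line {ln}: {why}" for ln, why in report[:10])
        raise DataError(f"invalid phase-space rows in {path}: {lines}")
    out = df[valid].reset_index(drop=True)
    out["z"] = out["z"].astype(int)
    out["a"] = out["a"].astype(int)
    return out, report


def write_phase_space(records: pd.DataFrame, path):
    """Write records as TSV with the fixed header (gzip by file suffix).
    ``write o read`` and ``read o write`` are identities on valid data."""
    missing = [c for c in PHASE_SPACE_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"records are missing column(s): {', '.join(missing)}")
    records[list(PHASE_SPACE_COLUMNS)].to_csv(path, sep="\t", index=False,
                                              float_format="%.17g")


# --------------------------------------------------------------------------
# Mapping into the dosimetry path
# --------------------------------------------------------------------------

def records_to_tracks(
    records: pd.DataFrame,
    range_table: RangeTable | None = None,
    min_depth_um: float = 10.0,
    let_threshold: float = 25.0,
) -> pd.DataFrame:
    """Turn phase-space records into track-like entries for dosimetry.

    Adds ``species``, ``passes_range`` (enough range to reach
    ``min_depth_um`` of depth at the particle's polar angle) and
    ``let_class`` (low/high at the threshold, boundary low), using the same
    filter parameters as the experimental path.
    """
    table = range_table or RangeTable()
    df = records.copy()
    df["species"] = [species_name(z, a) for z, a in zip(df["z"], df["a"])]
    df["passes_range"] = range_filter_phase_space(
        df["z"].to_numpy(), df["a"].to_numpy(),
        df["kinetic_energy_mev"].to_numpy(), df["polar_deg"].to_numpy(),
        table, min_depth_um)
    low, _ = split_by_let(df["let_water_kev_um"].to_numpy(), let_threshold)
    df["let_class"] = np.where(low, "low", "high")
    return df


def species_breakdown(
    records: pd.DataFrame,
    rho_g_cm3: float = 1.0,
    area_cm2: float = 1.0,
) -> pd.DataFrame:
    """Per-species fractions of fluence, D and H, plus cumulative fractions
    over species ordered by decreasing fluence.

    Fractions are invariant under record reordering and uniform weight
    rescaling; each of the three fraction columns sums to 1.
    """
    df = records
    if "species" not in df.columns:
        df = df.copy()
        df["species"] = [species_name(z, a) for z, a in zip(df["z"], df["a"])]

    rows = []
    for name, grp in df.groupby("species", sort=True):
        L = grp["let_water_kev_um"].to_numpy(dtype=float)
        theta = grp["polar_deg"].to_numpy(dtype=float)
        w = grp["weight"].to_numpy(dtype=float)
        rows.append({
            "species": name,
            "fluence": float(w.sum()),
            "d_gy": compute_dose(L, theta, rho_g_cm3, area_cm2, w),
            "h_sv": compute_dose_equivalent(L, theta, rho_g_cm3, area_cm2, w),
        })
    out = pd.DataFrame(rows)
    for col, frac in (("fluence", "fluence_fraction"), ("d_gy", "d_fraction"),
                      ("h_sv", "h_fraction")):
        total = out[col].sum()
        out[frac] = out[col] / total if total > 0 else 0.0
    out = out.sort_values("fluence", ascending=False).reset_index(drop=True)
    out["cumulative_fluence"] = out["fluence_fraction"].cumsum()
    out["cumulative_d"] = out["d_fraction"].cumsum()
    out["cumulative_h"] = out["h_fraction"].cumsum()
    return out


def batch_uncertainty(values: np.ndarray, statistic, k: int = 10):
    """Batch-statistics standard error for simulated quantities: partition
    the records into ``k`` equal batches, evaluate ``statistic`` per batch,
    and return (mean, standard error of the mean across batches)."""
    values = np.asarray(values)
    n = len(values)
    if n < k:
        raise DataError(f"need at least k={k} records for batch statistics")
    edges = np.linspace(0, n, k + 1).astype(int)
    stats = np.array([statistic(values[edges[i]:edges[i + 1]])
                      for i in range(k)])
    return float(stats.mean()), float(stats.std(ddof=1) / np.sqrt(k))
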