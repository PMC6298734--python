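"""Reading survey tables, inclusion filters and size-adjusted CPUE.

Three plain-CSV dialects are used throughout (the public trawl-survey and
food-habits downloads are plain tables; missing values are empty fields):

haul table
    ``haul_id, year, lon, lat, depth_m, temp_c`` plus one ``cpue_<species>``
    column per species (total catch rate, number/ha).
specimen table
    ``haul_id, species, fork_length_cm`` -- one row per measured fish.
diet table
    ``stomach_id, haul_id, species, fork_length_cm, fullness_code,
    prey_taxon, prey_weight_g`` -- one row per prey item; an empty stomach
    (fullness code 1) is a single row with a blank prey taxon and weight.

The analyses are restricted to fish of 30--69 cm fork length, so haul-level
CPUE is adjusted by the subsample proportion of lengths inside that (closed)
interval, and presence for modelling means adjusted CPUE > 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "read_haul_table",
    "read_specimen_table",
    "read_diet_table",
    "write_haul_table",
    "write_specimen_table",
    "write_diet_table",
    "filter_complete_covariates",
    "adjusted_cpue",
    "assign_area",
    "FilterReport",
    "DEFAULT_BOUNDARIES",
    "DEFAULT_SIZE_RANGE",
]

logger = logging.getLogger("nichepart")

DEFAULT_SIZE_RANGE = (30.0, 69.0)

#: Longitude breakpoints (degrees, west to east) per area scheme.  Intervals
#: are half-open ``[west, east)``; a coordinate exactly on a breakpoint joins
#: the eastern interval.  These default bands approximate the INPFC
#: statistical areas and IPHC regulatory areas of the Gulf of Alaska and are
#: fully configurable.
DEFAULT_BOUNDARIES = {
    "inpfc": {
        "breaks": [-170.0, -159.0, -154.0, -147.0, -137.0, -130.0],
        "labels": ["Shumagin", "Chirikof", "Kodiak", "Yakutat", "Southeastern"],
    },
    "iphc": {
        "breaks": [-170.0, -164.0, -154.0, -137.0, -130.0],
        "labels": ["4A", "3B", "3A", "2C"],
    },
}

_HAUL_REQUIRED = ("haul_id", "year", "lon", "lat", "depth_m", "temp_c")
_SPECIMEN_REQUIRED = ("haul_id", "species", "fork_length_cm")
_DIET_REQUIRED = (
    "stomach_id", "haul_id", "species", "fork_length_cm",
    "fullness_code", "prey_taxon", "prey_weight_g",
)


@dataclass
class FilterReport:
    """Bookkeeping of the complete-covariate inclusion filter."""

    n_input: int
    n_excluded_missing_covariates: int
    n_retained: int
    n_positive: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_input != self.n_excluded_missing_covariates + self.n_retained:
            raise ValueError("filter report counts are inconsistent")
        for sp, n in self.n_positive.items():
            if n > self.n_retained:
                raise ValueError(f"n_positive[{sp}] exceeds n_retained")


def _read_csv(path, required, numeric, integer=()):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [
        c for c in df.columns
        if c not in required and not c.startswith("cpue_")
    ]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}")
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        df = df.drop(columns=extra)
    for col in df.columns:
        if col in numeric or col.startswith("cpue_"):
            vals = df[col].str.strip()
            blank = vals == ""
            try:
                converted = pd.to_numeric(vals.where(~blank, other=np.nan))
            except (ValueError, TypeError):
                as_num = pd.to_numeric(vals.where(~blank, other=np.nan),
                                       errors="coerce")
                bad = (~blank) & as_num.isna()
                row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
                raise ValueError(
                    f"{path}: malformed numeric value {vals[bad].iloc[0]!r} "
                    f"in column {col!r} at line {row}"
                ) from None
            df[col] = converted
        if col in integer:
            if df[col].isna().any():
                raise ValueError(f"{path}: blank value in column {col!r}")
            df[col] = df[col].astype(int)
    return df


def read_haul_table(path) -> pd.DataFrame:
    """Read a haul table; blank depth/temperature parse as missing."""
    df = _read_csv(
        path, _HAUL_REQUIRED,
        numeric={"year", "lon", "lat", "depth_m", "temp_c"},
        integer={"year"},
    )
    if df["haul_id"].duplicated().any():
        dup = df.loc[df["haul_id"].duplicated(), "haul_id"].iloc[0]
        raise ValueError(f"{path}: duplicate haul_id {dup!r}")
    cpue_cols = [c for c in df.columns if c.startswith("cpue_")]
    for c in cpue_cols:
        if df[c].isna().any():
            raise ValueError(f"{path}: blank CPUE in column {c!r}")
        if (df[c] < 0).any():
            raise ValueError(f"{path}: negative CPUE in column {c!r}")
    return df


def read_specimen_table(path) -> pd.DataFrame:
    df = _read_csv(path, _SPECIMEN_REQUIRED, numeric={"fork_length_cm"})
    if (df["fork_length_cm"] <= 0).any():
        raise ValueError(f"{path}: non-positive fork length")
    return df


def read_diet_table(path) -> pd.DataFrame:
    df = _read_csv(
        path, _DIET_REQUIRED,
        numeric={"fork_length_cm", "fullness_code", "prey_weight_g"},
        integer={"fullness_code"},
    )
    if not df["fullness_code"].isin(range(1, 8)).all():
        raise ValueError(f"{path}: fullness codes must be integers 1..7")
    has_prey = df["prey_taxon"].str.strip() != ""
    if (df.loc[has_prey, "prey_weight_g"] < 0).any():
        raise ValueError(f"{path}: negative prey weight")
    return df


def _write(df: pd.DataFrame, path):
    df.to_csv(path, index=False, na_rep="")


write_haul_table = _write
write_specimen_table = _write
write_diet_table = _write


def filter_complete_covariates(
    hauls: pd.DataFrame,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop tows with missing depth or bottom temperature.

    Returns the retained hauls and a :class:`FilterReport`; ``n_positive``
    counts retained tows with positive total CPUE per species.
    """
    ok = hauls["depth_m"].notna() & hauls["temp_c"].notna()
    retained = hauls[ok].copy()
    cpue_cols = [c for c in hauls.columns if c.startswith("cpue_")]
    report = FilterReport(
        n_input=len(hauls),
        n_excluded_missing_covariates=int((~ok).sum()),
        n_retained=len(retained),
        n_positive={
            c[len("cpue_"):]: int((retained[c] > 0).sum()) for c in cpue_cols
        },
    )
    logger.info(
        "covariate filter: %d of %d tows retained (%d excluded)",
        report.n_retained, report.n_input,
        report.n_excluded_missing_covariates,
    )
    return retained, report


def adjusted_cpue(
    hauls: pd.DataFrame,
    specimens: pd.DataFrame,
    species: str,
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE,
    on_missing_lengths: str = "zero",
) -> pd.Series:
    """Haul-level CPUE restricted to the analysis size range.

    Multiplies each haul's total CPUE by the proportion of its subsampled
    fork lengths inside the closed interval ``size_range``.  A haul with
    positive total CPUE but no measured lengths is treated as proportion 0
    (default) or raises (``on_missing_lengths='raise'``).  Presence for
    modelling is adjusted CPUE > 0.
    """
    if on_missing_lengths not in ("zero", "raise"):
        raise ValueError("on_missing_lengths must be 'zero' or 'raise'")
    lo, hi = size_range
    col = f"cpue_{species}"
    if col not in hauls.columns:
        raise ValueError(f"haul table has no column {col!r}")
    sub = specimens[specimens["species"] == species]
    n_total = sub.groupby("haul_id")["fork_length_cm"].size()
    n_in = (
        sub[(sub["fork_length_cm"] >= lo) & (sub["fork_length_cm"] <= hi)]
        .groupby("haul_id")["fork_length_cm"].size()
    )
    total = hauls.set_index("haul_id")[col]
    n_total = n_total.reindex(total.index, fill_value=0)
    n_in = n_in.reindex(total.index, fill_value=0)
    unmeasured = (total > 0) & (n_total == 0)
    if unmeasured.any():
        if on_missing_lengths == "raise":
            raise ValueError(
                f"{int(unmeasured.sum())} hauls have positive total CPUE for "
                f"{species!r} but no measured lengths"
            )
    prop = np.where(n_total > 0, n_in / n_total.replace(0, 1), 0.0)
    out = total * prop
    out.name = f"adjusted_cpue_{species}"
    return out.reindex(hauls["haul_id"]).set_axis(hauls.index)


def assign_area(lon, lat, boundaries=None, scheme: str = "inpfc"):
    """Label coordinates with statistical/regulatory areas.

    ``boundaries`` follows :data:`DEFAULT_BOUNDARIES`: per scheme, ordered
    longitude ``breaks`` (length ``len(labels) + 1``) delimiting half-open
    ``[west, east)`` bands.  Coordinates outside every band get
    ``"unassigned"``.
    """
    if boundaries is None:
        boundaries = DEFAULT_BOUNDARIES
    spec = boundaries[scheme]
    breaks = np.asarray(spec["breaks"], dtype=float)
    labels = list(spec["labels"])
    if len(breaks) != len(labels) + 1:
        raise ValueError("need len(breaks) == len(labels) + 1")
    if not np.all(np.diff(breaks) > 0):
        raise ValueError("breaks must be strictly increasing")
    lon = np.asarray(lon, dtype=float)
    idx = np.searchsorted(breaks, lon, side="right") - 1
    out = np.where(
        (idx >= 0) & (idx < len(labels)),
        np.asarray(labels + ["unassigned"], dtype=object)[
            np.clip(idx, 0, len(labels))
        ],
        "unassigned",
    )
    return out
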