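"""Uniform projected grid and the spatial-overlap index.

Predictions from the two single-species distribution models are combined on a
uniform grid built in a transverse-Mercator plane (100 km x 100 km cells by
default).  Per species the product of occurrence probability (PO) and positive
abundance (PA) gives an abundance surface A; A is standardized by a
species-level statistic (the maximum by default, so values fall in [0, 1]) and
the spatial-overlap index is the cell-year-wise product of the two species'
standardized abundances:

    S[i, j] = stdA_a[i, j] * stdA_b[i, j]      with S in [0, 1].

Cells where both species stay below a habitat-suitability threshold (0.25) in
every predicted year are excluded before S is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransverseMercator",
    "Grid",
    "build_grid",
    "locate",
    "cell_year_env",
    "combine_and_standardize",
    "exclude_low_habitat",
    "spatial_overlap",
    "cell_means",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563


@dataclass(frozen=True)
class TransverseMercator:
    """Ellipsoidal transverse-Mercator projection (USGS series form, WGS84).

    Parameters follow the UTM convention: scale factor 0.9996 on the central
    meridian and a 500 km false easting.  ``utm_zone`` builds the projection
    for a standard 6-degree zone.
    """

    lon0: float
    k0: float = 0.9996
    false_easting: float = 500_000.0
    false_northing: float = 0.0
    a: float = _A
    f: float = _F

    @classmethod
    def utm_zone(cls, zone: int, northern: bool = True) -> "TransverseMercator":
        if not 1 <= zone <= 60:
            raise ValueError(f"UTM zone must be in 1..60, got {zone}")
        lon0 = -183.0 + 6.0 * zone
        return cls(lon0=lon0, false_northing=0.0 if northern else 10_000_000.0)

    @classmethod
    def for_longitude(cls, lon: float, northern: bool = True) -> "TransverseMercator":
        zone = int((lon + 180.0) // 6.0) + 1
        return cls.utm_zone(min(max(zone, 1), 60), northern=northern)

    # -- series coefficients -------------------------------------------------
    @property
    def _e2(self) -> float:
        return self.f * (2.0 - self.f)

    def _meridian_arc(self, phi: np.ndarray) -> np.ndarray:
        e2 = self._e2
        e4, e6 = e2 * e2, e2 * e2 * e2
        return self.a * (
            (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256) * phi
            - (3 * e2 / 8 + 3 * e4 / 32 + 45 * e6 / 1024) * np.sin(2 * phi)
            + (15 * e4 / 256 + 45 * e6 / 1024) * np.sin(4 * phi)
            - (35 * e6 / 3072) * np.sin(6 * phi)
        )

    def forward(self, lon, lat):
        """Project geographic coordinates (degrees) to easting/northing (m)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        e2 = self._e2
        ep2 = e2 / (1.0 - e2)
        phi = np.radians(lat)
        dlam = np.radians(lon - self.lon0)
        sin_p, cos_p, tan_p = np.sin(phi), np.cos(phi), np.tan(phi)
        n = self.a / np.sqrt(1 - e2 * sin_p**2)
        t = tan_p**2
        c = ep2 * cos_p**2
        aa = dlam * cos_p
        m = self._meridian_arc(phi)
        x = self.k0 * n * (
            aa
            + (1 - t + c) * aa**3 / 6
            + (5 - 18 * t + t**2 + 72 * c - 58 * ep2) * aa**5 / 120
        ) + self.false_easting
        y = self.k0 * (
            m
            + n * tan_p * (
                aa**2 / 2
                + (5 - t + 9 * c + 4 * c**2) * aa**4 / 24
                + (61 - 58 * t + t**2 + 600 * c - 330 * ep2) * aa**6 / 720
            )
        ) + self.false_northing
        return x, y

    def inverse(self, x, y):
        """Map easting/northing (m) back to geographic coordinates (degrees)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        e2 = self._e2
        ep2 = e2 / (1.0 - e2)
        e4, e6 = e2 * e2, e2 * e2 * e2
        m = (y - self.false_northing) / self.k0
        mu = m / (self.a * (1 - e2 / 4 - 3 * e4 / 64 - 5 * e6 / 256))
        e1 = (1 - np.sqrt(1 - e2)) / (1 + np.sqrt(1 - e2))
        phi1 = (
            mu
            + (3 * e1 / 2 - 27 * e1**3 / 32) * np.sin(2 * mu)
            + (21 * e1**2 / 16 - 55 * e1**4 / 32) * np.sin(4 * mu)
            + (151 * e1**3 / 96) * np.sin(6 * mu)
            + (1097 * e1**4 / 512) * np.sin(8 * mu)
        )
        sin1, cos1, tan1 = np.sin(phi1), np.cos(phi1), np.tan(phi1)
        c1 = ep2 * cos1**2
        t1 = tan1**2
        n1 = self.a / np.sqrt(1 - e2 * sin1**2)
        r1 = self.a * (1 - e2) / (1 - e2 * sin1**2) ** 1.5
        d = (x - self.false_easting) / (n1 * self.k0)
        phi = phi1 - (n1 * tan1 / r1) * (
            d**2 / 2
            - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * ep2) * d**4 / 24
            + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * ep2 - 3 * c1**2)
            * d**6 / 720
        )
        lam = (
            d
            - (1 + 2 * t1 + c1) * d**3 / 6
            + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * ep2 + 24 * t1**2) * d**5 / 120
        ) / cos1
        return self.lon0 + np.degrees(lam), np.degrees(phi)


@dataclass
class Grid:
    """Uniform tiling of a projected plane with square cells.

    Cell membership uses half-open intervals ``[edge, edge + cell_size)`` in
    projected coordinates, so every in-extent point maps to exactly one cell.
    Cell ids are strings ``"c{col}_r{row}"`` with column/row counted from the
    grid origin (south-west corner).
    """

    projection: TransverseMercator
    x0: float
    y0: float
    n_cols: int
    n_rows: int
    cell_size: float = 100_000.0
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @staticmethod
    def cell_id(col, row):
        col = np.atleast_1d(np.asarray(col, dtype=int))
        row = np.atleast_1d(np.asarray(row, dtype=int))
        flat = np.char.add(
            np.char.add("c", col.astype(str)),
            np.char.add("_r", row.astype(str)),
        )
        return flat

    def locate(self, lon, lat):
        """Map coordinates to cell ids; points off the grid get 'unassigned'."""
        scalar = np.ndim(lon) == 0 and np.ndim(lat) == 0
        x, y = self.projection.forward(lon, lat)
        col = np.floor((np.atleast_1d(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.atleast_1d(y) - self.y0) / self.cell_size).astype(int)
        ids = self.cell_id(col, row).astype(object)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        ids = np.where(inside, ids, UNASSIGNED)
        return ids[0] if scalar else ids

    def cells(self) -> pd.DataFrame:
        """One row per cell: id, col, row, projected center, lon/lat center."""
        if self._frame is None:
            cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
            cols, rows = cols.ravel(), rows.ravel()
            xc = self.x0 + (cols + 0.5) * self.cell_size
            yc = self.y0 + (rows + 0.5) * self.cell_size
            lon, lat = self.projection.inverse(xc, yc)
            self._frame = pd.DataFrame(
                {
                    "cell_id": self.cell_id(cols, rows),
                    "col": cols,
                    "row": rows,
                    "x_center": xc,
                    "y_center": yc,
                    "center_lon": lon,
                    "center_lat": lat,
                }
            )
        return self._frame.copy()


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float = 100_000.0,
    projection: TransverseMercator | None = None,
) -> Grid:
    """Tile a lon/lat extent ``(lon_min, lon_max, lat_min, lat_max)``.

    The extent boundary is densified before projection so the grid covers the
    curved image of the rectangle.  One projection (one transverse-Mercator
    zone) is used for the whole extent.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError(f"empty extent: {extent}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if projection is None:
        projection = TransverseMercator.for_longitude(
            0.5 * (lon_min + lon_max), northern=lat_min + lat_max >= 0
        )
    lons = np.linspace(lon_min, lon_max, 50)
    lats = np.linspace(lat_min, lat_max, 50)
    blon = np.concatenate([lons, lons, np.full(50, lon_min), np.full(50, lon_max)])
    blat = np.concatenate([np.full(50, lat_min), np.full(50, lat_max), lats, lats])
    x, y = projection.forward(blon, blat)
    x0 = np.floor(x.min() / cell_size) * cell_size
    y0 = np.floor(y.min() / cell_size) * cell_size
    n_cols = int(np.ceil((x.max() - x0) / cell_size))
    n_rows = int(np.ceil((y.max() - y0) / cell_size))
    return Grid(projection, x0, y0, n_cols, n_rows, cell_size)


def locate(lon, lat, grid: Grid):
    """Functional alias for :meth:`Grid.locate`."""
    return grid.locate(lon, lat)


def cell_year_env(hauls: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Mean depth and bottom temperature per (survey year, grid cell).

    Hauls falling outside the grid are dropped; cell-years with no hauls are
    simply absent (no prediction is made there).  Input hauls must have
    complete covariates.
    """
    df = hauls.copy()
    df["cell_id"] = grid.locate(df["lon"].to_numpy(), df["lat"].to_numpy())
    df = df[df["cell_id"] != UNASSIGNED]
    out = (
        df.groupby(["year", "cell_id"], as_index=False)
        .agg(depth_m=("depth_m", "mean"), temp_c=("temp_c", "mean"),
             n_hauls=("haul_id", "size"))
    )
    return out


_STANDARDIZERS = ("max", "mean", "median")


def combine_and_standardize(pred: pd.DataFrame, method: str = "max") -> pd.DataFrame:
    """Combine PO and PA into abundance and standardize per species.

    ``pred`` is long format with columns ``species, year, cell_id, po, pa``.
    Adds ``abundance = po * pa`` and ``std_abundance = abundance / stat`` where
    ``stat`` is the per-species max/mean/median over all year-cells.
    """
    if method not in _STANDARDIZERS:
        raise ValueError(f"method must be one of {sorted(_STANDARDIZERS)}")
    out = pred.copy()
    out["abundance"] = out["po"].to_numpy() * out["pa"].to_numpy()
    if (out["abundance"] < 0).any():
        raise ValueError("negative abundance encountered")
    denom = out.groupby("species")["abundance"].transform(method)
    if (denom <= 0).any():
        bad = out.loc[denom <= 0, "species"].unique().tolist()
        raise ValueError(f"all-zero abundance field for species {bad}; "
                         "standardizer undefined")
    out["std_abundance"] = out["abundance"] / denom
    return out


def exclude_low_habitat(
    field: pd.DataFrame,
    species_pair: tuple[str, str],
    threshold: float = 0.25,
) -> tuple[list, list]:
    """Whole-cell habitat-suitability exclusion rule.

    A cell is excluded only when, in every year with predictions, the
    standardized abundance is below ``threshold`` for *both* species.  Returns
    ``(retained_cell_ids, excluded_cell_ids)``.
    """
    a, b = species_pair
    wide = field.pivot_table(
        index=["cell_id", "year"], columns="species", values="std_abundance"
    )
    for sp in (a, b):
        if sp not in wide.columns:
            raise ValueError(f"species {sp!r} absent from abundance field")
    low = (wide[a] < threshold) & (wide[b] < threshold)
    per_cell = low.groupby(level="cell_id").all()
    excluded = sorted(per_cell[per_cell].index.tolist())
    retained = sorted(per_cell[~per_cell].index.tolist())
    return retained, excluded


def spatial_overlap(
    field: pd.DataFrame,
    species_pair: tuple[str, str],
    cells: list | None = None,
) -> pd.DataFrame:
    """Per (year, cell) product of the two species' standardized abundances.

    Both species must be predicted on the same (year, cell) set; a mismatch is
    an error, not a silent inner join.  ``cells`` optionally restricts the
    computation to the habitat-retained cell set.
    """
    a, b = species_pair
    sub = field[field["species"].isin(species_pair)]
    if cells is not None:
        sub = sub[sub["cell_id"].isin(set(cells))]
    wide = sub.pivot_table(
        index=["year", "cell_id"], columns="species", values="std_abundance"
    )
    if wide[[a, b]].isna().any().any():
        raise ValueError("mismatched (year, cell) sets between species")
    out = wide.reset_index()[["year", "cell_id"]]
    out["s"] = (wide[a] * wide[b]).to_numpy()
    return out


def cell_means(overlap: pd.DataFrame, value: str = "s") -> pd.DataFrame:
    """Average year-specific overlap within each grid cell."""
    return (
        overlap.groupby("cell_id", as_index=False)
        .agg(**{f"mean_{value}": (value, "mean"), "n_years": (value, "size")})
    )
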