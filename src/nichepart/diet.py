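"""Diet compositions, Schoener's dietary overlap and diet-breadth summaries.

Stomachs are grouped by survey year and grid cell per predator.  Prey-weight
proportions W are pooled over the group's non-empty stomachs (sum weights per
taxon, then normalize by the group total), and dietary overlap between two
predators sharing a (year, cell) group is Schoener's similarity index

    D = 1 - 1/2 * sum_t | W_a[t] - W_b[t] |,

computed over the union of prey taxa at the raw taxonomic level; D ranges
from 0 (complete separation) to 1 (complete overlap).  Groups qualify only
when both predators have at least three non-empty stomachs of fish inside the
analysis size range.  Shannon diversity H', Pielou evenness J' (natural
logarithms) and resampling rarefaction curves summarize dietary niche
breadth; taxon folding below a display threshold is for presentation only and
never enters D.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import Grid
from .io import DEFAULT_SIZE_RANGE

__all__ = [
    "is_empty_stomach",
    "group_stomachs",
    "prey_proportions",
    "schoener",
    "shannon",
    "pielou",
    "rarefaction",
    "size_class_compositions",
    "aggregate_rare_taxa",
    "dietary_overlap_field",
    "DISPLAY_SIZE_BINS",
]

#: display size classes (cm fork length) inside the analysis range
DISPLAY_SIZE_BINS = ((30, 39), (40, 49), (50, 59), (60, 69))


def is_empty_stomach(diet: pd.DataFrame) -> pd.Series:
    """Per-row empty flag: fullness code 1 or no prey item."""
    no_prey = diet["prey_taxon"].astype(str).str.strip() == ""
    return (diet["fullness_code"] == 1) | no_prey


def group_stomachs(
    diet: pd.DataFrame,
    hauls: pd.DataFrame,
    grid: Grid,
    size_range: tuple[float, float] = DEFAULT_SIZE_RANGE,
    min_per_predator: int = 3,
    species_pair: tuple[str, str] = ("PH", "ATF"),
) -> tuple[pd.DataFrame, set]:
    """Pool stomach contents by (year, grid cell, species).

    Only non-empty stomachs of fish inside ``size_range`` count.  Returns a
    long table ``year, cell_id, species, prey_taxon, weight_g, n_stomachs``
    restricted to qualifying (year, cell) combinations -- those where *both*
    predators have at least ``min_per_predator`` non-empty stomachs -- plus
    the qualifying set itself.
    """
    lo, hi = size_range
    info = hauls.set_index("haul_id")[["year", "lon", "lat"]]
    df = diet.merge(info, left_on="haul_id", right_index=True, how="left")
    if df["year"].isna().any():
        missing = df.loc[df["year"].isna(), "haul_id"].unique()[:3]
        raise ValueError(f"stomach rows reference unknown hauls, e.g. {missing}")
    df["cell_id"] = grid.locate(df["lon"].to_numpy(), df["lat"].to_numpy())
    keep = (
        ~is_empty_stomach(df)
        & (df["fork_length_cm"] >= lo)
        & (df["fork_length_cm"] <= hi)
        & (df["cell_id"] != "unassigned")
        & df["species"].isin(species_pair)
    )
    df = df[keep]
    counts = (
        df.groupby(["year", "cell_id", "species"])["stomach_id"]
        .nunique()
        .unstack("species")
        .reindex(columns=list(species_pair))
        .fillna(0)
    )
    qualifying = set(
        counts.index[(counts >= min_per_predator).all(axis=1)].tolist()
    )
    df = df[
        pd.MultiIndex.from_frame(df[["year", "cell_id"]]).isin(qualifying)
    ]
    pooled = (
        df.groupby(["year", "cell_id", "species", "prey_taxon"], as_index=False)
        .agg(weight_g=("prey_weight_g", "sum"))
    )
    n_stomachs = (
        df.groupby(["year", "cell_id", "species"])["stomach_id"]
        .nunique()
        .rename("n_stomachs")
    )
    pooled = pooled.merge(
        n_stomachs, left_on=["year", "cell_id", "species"], right_index=True
    )
    return pooled, qualifying


def prey_proportions(weights: pd.Series) -> pd.Series:
    """Normalize pooled prey weights into a composition summing to 1."""
    w = weights.astype(float)
    if (w < 0).any():
        raise ValueError("negative prey weight")
    total = w.sum()
    if total <= 0:
        raise ValueError("total prey weight is zero; composition undefined")
    return w / total


def _check_composition(w: pd.Series, name: str):
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise ValueError(f"composition {name} sums to {w.sum():.12f}, not 1")
    if (w < 0).any():
        raise ValueError(f"composition {name} has negative entries")


def schoener(w_a: pd.Series, w_b: pd.Series) -> float:
    """Schoener's similarity between two prey-weight compositions.

    Inputs are taxon-indexed proportion vectors each summing to 1; they are
    aligned on the union of taxa with absent taxa counted as 0.
    """
    _check_composition(w_a, "a")
    _check_composition(w_b, "b")
    union = w_a.index.union(w_b.index)
    a = w_a.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    b = w_b.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    return float(1.0 - 0.5 * np.abs(a - b).sum())


def shannon(w: pd.Series) -> float:
    """Shannon-Weaver diversity H' = -sum W ln W over positive entries."""
    _check_composition(w, "w")
    p = w.to_numpy(dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def pielou(w: pd.Series) -> float:
    """Pielou evenness J' = H'/ln Q; undefined (NaN) for a single taxon."""
    q = int((w > 0).sum())
    if q < 2:
        return float("nan")
    return shannon(w) / np.log(q)


def rarefaction(
    diet: pd.DataFrame,
    species: str,
    n_points: int = 20,
    n_resamples: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected distinct prey taxa vs number of stomachs sampled.

    Resamples non-empty stomachs without replacement; returns one row per
    subsample size m with the mean taxon count and a 2.5/97.5 percentile
    band.  The curve is non-decreasing in expectation and ends exactly at the
    observed taxon richness.
    """
    sub = diet[(diet["species"] == species) & ~is_empty_stomach(diet)]
    if sub.empty:
        raise ValueError(f"no non-empty stomachs for species {species!r}")
    taxa_by_stomach = sub.groupby("stomach_id")["prey_taxon"].agg(set)
    sets = list(taxa_by_stomach)
    n = len(sets)
    sizes = np.unique(np.linspace(1, n, min(n_points, n)).round().astype(int))
    rng = np.random.default_rng(seed)
    rows = []
    for m in sizes:
        counts = np.empty(n_resamples)
        for r in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            counts[r] = len(set().union(*(sets[i] for i in idx)))
        rows.append(
            dict(
                n_stomachs=int(m),
                mean_taxa=counts.mean(),
                lo=np.percentile(counts, 2.5),
                hi=np.percentile(counts, 97.5),
            )
        )
    return pd.DataFrame(rows)


def size_class_compositions(
    diet: pd.DataFrame,
    hauls: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DISPLAY_SIZE_BINS,
    area_scheme: str = "inpfc",
    boundaries=None,
) -> pd.DataFrame:
    """Prey-weight compositions per (species, area, size class).

    ``bins`` are closed intervals in cm; stomachs outside every bin are
    dropped.  Returns long format ``species, area, size_class, prey_taxon,
    w`` with per-group proportions summing to 1.
    """
    from .io import assign_area

    info = hauls.set_index("haul_id")[["lon", "lat"]]
    df = diet[~is_empty_stomach(diet)].merge(
        info, left_on="haul_id", right_index=True, how="left"
    )
    df["area"] = assign_area(
        df["lon"].to_numpy(), df["lat"].to_numpy(),
        boundaries=boundaries, scheme=area_scheme,
    )
    labels = [f"{lo}-{hi}" for lo, hi in bins]
    size_class = pd.Series(pd.NA, index=df.index, dtype="object")
    for (lo, hi), lab in zip(bins, labels):
        inside = (df["fork_length_cm"] >= lo) & (df["fork_length_cm"] <= hi)
        size_class[inside] = lab
    df["size_class"] = size_class
    df = df[df["size_class"].notna()]
    pooled = (
        df.groupby(["species", "area", "size_class", "prey_taxon"],
                   as_index=False)
        .agg(weight_g=("prey_weight_g", "sum"))
    )
    pooled["w"] = pooled.groupby(["species", "area", "size_class"])[
        "weight_g"
    ].transform(lambda s: s / s.sum())
    return pooled.drop(columns="weight_g")


def aggregate_rare_taxa(
    compositions: pd.DataFrame,
    taxonomy: dict[str, str],
    threshold: float = 0.01,
    group_cols: tuple[str, ...] = ("species", "area", "size_class"),
) -> pd.DataFrame:
    """Fold taxa below an overall proportion threshold into broader groups.

    ``taxonomy`` maps taxon -> broader display group; a taxon absent from the
    map folds into ``"other"`` with a warning.  Folding is for display only
    and preserves total mass exactly.
    """
    import warnings

    df = compositions.copy()
    overall = df.groupby("prey_taxon")["w"].sum()
    overall = overall / overall.sum()
    rare = set(overall.index[overall < threshold])
    unknown = rare - set(taxonomy)
    if unknown:
        warnings.warn(
            f"taxa missing from taxonomy map folded into 'other': "
            f"{sorted(unknown)}"
        )
    df["display_taxon"] = [
        taxonomy.get(t, "other") if t in rare else t for t in df["prey_taxon"]
    ]
    out = (
        df.groupby([*group_cols, "display_taxon"], as_index=False)
        .agg(w=("w", "sum"))
    )
    return out


def dietary_overlap_field(
    pooled: pd.DataFrame,
    species_pair: tuple[str, str] = ("PH", "ATF"),
) -> pd.DataFrame:
    """Schoener's D per (year, cell) from pooled group weights."""
    a, b = species_pair
    rows = []
    for (year, cell), grp in pooled.groupby(["year", "cell_id"]):
        wa = grp[grp["species"] == a].set_index("prey_taxon")["weight_g"]
        wb = grp[grp["species"] == b].set_index("prey_taxon")["weight_g"]
        if wa.empty or wb.empty:
            continue
        d = schoener(prey_proportions(wa), prey_proportions(wb))
        rows.append(dict(year=year, cell_id=cell, d=d))
    return pd.DataFrame(rows, columns=["year", "cell_id", "d"])
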