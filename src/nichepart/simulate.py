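"""Synthetic trawl-survey and stomach-content data with known truth.

The generator emulates the statistical structure of Gulf-of-Alaska bottom
trawl survey and groundfish food-habits tables: zero-inflated catch rates whose
presence probability and positive CPUE vary smoothly with location, depth and
bottom temperature and shift by survey year; per-haul fork-length subsamples;
and stomach contents whose prey-weight compositions vary by predator species,
region and size class, with a realistic fraction of empty stomachs and of
hauls missing environmental covariates.

Every draw is governed by a scenario seed, and the scenario retains the exact
response surfaces used, so downstream model fits can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SpeciesParams",
    "SurveyScenario",
    "SurveyTruth",
    "DietScenario",
    "simulate_hauls",
    "simulate_lengths",
    "simulate_stomachs",
    "simulate_overlap_pairs",
    "default_scenario",
    "default_diet_scenario",
    "partitioning_diet_scenario",
    "PROTOCOL_SIZE_BINS",
]

# stomach-sampling protocol size categories (cm fork length)
PROTOCOL_SIZE_BINS = ("lt31", "31-50", "51-70", "gt70")

_GOA_EXTENT = (-170.0, -132.0, 52.0, 60.0)
_GOA_YEARS = (1990, 1993, 1996, 1999, 2001, 2003, 2005,
              2007, 2009, 2011, 2013, 2015, 2017)


@dataclass
class SpeciesParams:
    """Generative response surfaces for one species.

    ``year_effects`` maps survey year to a pair ``(logit_offset, log_offset)``:
    the year-specific intercepts of the presence linear predictor (logit
    scale) and of mean ln CPUE.  The three response functions are shared by
    both stages and added to those intercepts.
    """

    year_effects: Mapping[int, tuple[float, float]]
    spatial_surface: Callable[[np.ndarray, np.ndarray], np.ndarray]
    depth_response: Callable[[np.ndarray], np.ndarray]
    temp_response: Callable[[np.ndarray], np.ndarray]
    cpue_sd: float = 1.0
    length_median_cm: float = 45.0
    length_log_sd: float = 0.35
    mean_measured: float = 25.0

    def __post_init__(self):
        if self.cpue_sd <= 0:
            raise ValueError("cpue_sd must be positive")


@dataclass
class SurveyScenario:
    """Full description of a synthetic survey, including its truth surfaces."""

    years: tuple[int, ...]
    extent: tuple[float, float, float, float]
    hauls_per_year: int
    species_params: Mapping[str, SpeciesParams]
    depth_field: Callable[[np.ndarray, np.ndarray, int], np.ndarray]
    temp_field: Callable[[np.ndarray, np.ndarray, int], np.ndarray]
    missing_covariate_rate: float = 0.0766
    subsample_max: int = 200
    temp_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError(f"empty extent {self.extent}")
        if self.hauls_per_year < 1:
            raise ValueError("hauls_per_year must be >= 1")
        if not 0.0 <= self.missing_covariate_rate < 1.0:
            raise ValueError("missing_covariate_rate must be in [0, 1)")
        if self.subsample_max > 200:
            raise ValueError("subsample_max exceeds the 200-fish protocol cap")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.species_params)

    def truth(self) -> "SurveyTruth":
        return SurveyTruth(self)


class SurveyTruth:
    """Evaluator of the exact generative surfaces, for recovery scoring."""

    def __init__(self, scenario: SurveyScenario):
        self.scenario = scenario

    def _eta(self, species, year, lon, lat, which):
        sp = self.scenario.species_params[species]
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        depth = self.scenario.depth_field(lon, lat, year)
        temp = self.scenario.temp_field(lon, lat, year)
        idx = 0 if which == "logit" else 1
        return (
            sp.year_effects[year][idx]
            + sp.spatial_surface(lon, lat)
            + sp.depth_response(np.asarray(depth))
            + sp.temp_response(np.asarray(temp))
        )

    def presence_prob(self, species, year, lon, lat):
        """True probability of occurrence PO."""
        return expit(self._eta(species, year, lon, lat, "logit"))

    def mean_log_cpue(self, species, year, lon, lat):
        """True mean of ln CPUE given presence."""
        return self._eta(species, year, lon, lat, "log")

    def expected_abundance(self, species, year, lon, lat):
        """True PO x E[CPUE | present] (lognormal mean)."""
        sp = self.scenario.species_params[species]
        po = self.presence_prob(species, year, lon, lat)
        return po * np.exp(
            self.mean_log_cpue(species, year, lon, lat) + 0.5 * sp.cpue_sd**2
        )

    def inrange_proportion(self, species, size_range=(30, 69)) -> float:
        """Analytic probability that a recorded (whole-cm) length is in range."""
        sp = self.scenario.species_params[species]
        lo, hi = size_range
        mu = math.log(sp.length_median_cm)
        s = sp.length_log_sd
        z = lambda v: (math.log(v) - mu) / s
        return float(norm.cdf(z(hi + 0.5)) - norm.cdf(z(lo - 0.5)))


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(salt)]))


def _check_finite(values, name, lon, lat):
    values = np.asarray(values, dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"non-finite {name} at lon={float(np.asarray(lon)[i]):.4f}, "
            f"lat={float(np.asarray(lat)[i]):.4f}"
        )
    return values


def simulate_hauls(scenario: SurveyScenario) -> tuple[pd.DataFrame, SurveyTruth]:
    """Draw one survey of trawl hauls.

    Returns a haul table (one row per tow: ``haul_id, year, lon, lat, depth_m,
    temp_c`` and per-species ``cpue_<name>`` in number/ha) and the truth
    evaluator.  Presence is Bernoulli on the logistic linear predictor; CPUE
    where present is lognormal around the log-scale mean; CPUE > 0 iff
    present.  A ``missing_covariate_rate`` fraction of hauls has depth and/or
    temperature blanked (the catch still responds to the true environment).
    """
    sc = scenario
    rng = _rng(sc.seed, 1)
    lon_min, lon_max, lat_min, lat_max = sc.extent
    frames = []
    for year in sc.years:
        n = sc.hauls_per_year
        lon = rng.uniform(lon_min, lon_max, n)
        lat = rng.uniform(lat_min, lat_max, n)
        depth = _check_finite(sc.depth_field(lon, lat, year), "depth", lon, lat)
        temp = _check_finite(sc.temp_field(lon, lat, year), "temperature", lon, lat)
        if sc.temp_noise_sd > 0:
            # local/interannual variability around the mean temperature field;
            # the catch responds to the realized (recorded) temperature
            temp = temp + rng.normal(0.0, sc.temp_noise_sd, size=n)
        row = {
            "haul_id": [f"{year}-{i:05d}" for i in range(n)],
            "year": np.full(n, year, dtype=int),
            "lon": lon,
            "lat": lat,
            "depth_m": depth,
            "temp_c": temp,
        }
        for name, sp in sc.species_params.items():
            base = (
                sp.spatial_surface(lon, lat)
                + sp.depth_response(depth)
                + sp.temp_response(temp)
            )
            eta = sp.year_effects[year][0] + base
            _check_finite(eta, f"presence predictor for {name}", lon, lat)
            present = rng.binomial(1, expit(eta))
            log_mu = sp.year_effects[year][1] + base
            cpue = present * np.exp(rng.normal(log_mu, sp.cpue_sd))
            row[f"cpue_{name}"] = cpue
        frames.append(pd.DataFrame(row))
    hauls = pd.concat(frames, ignore_index=True)
    if sc.missing_covariate_rate > 0:
        n_total = len(hauls)
        n_missing = int(round(sc.missing_covariate_rate * n_total))
        idx = rng.choice(n_total, size=n_missing, replace=False)
        which = rng.choice(3, size=n_missing, p=[0.4, 0.4, 0.2])
        hauls.loc[hauls.index[idx[which != 1]], "depth_m"] = np.nan
        hauls.loc[hauls.index[idx[which != 0]], "temp_c"] = np.nan
    return hauls, sc.truth()


def simulate_lengths(hauls: pd.DataFrame, scenario: SurveyScenario) -> pd.DataFrame:
    """Fork-length subsamples: up to ``subsample_max`` fish per positive haul.

    Lengths are lognormal per species (scenario median and log-SD), recorded
    to the whole centimeter.  Hauls where a species is absent contribute no
    rows for it.
    """
    sc = scenario
    rng = _rng(sc.seed, 2)
    out = {"haul_id": [], "species": [], "fork_length_cm": []}
    for name, sp in sc.species_params.items():
        col = f"cpue_{name}"
        positive = hauls.loc[hauls[col] > 0, "haul_id"].to_numpy()
        if positive.size == 0:
            continue
        counts = np.minimum(
            sc.subsample_max, 1 + rng.poisson(sp.mean_measured, size=positive.size)
        )
        total = int(counts.sum())
        lengths = np.maximum(
            1,
            np.round(
                np.exp(rng.normal(math.log(sp.length_median_cm),
                                  sp.length_log_sd, size=total))
            ).astype(int),
        )
        out["haul_id"].extend(np.repeat(positive, counts))
        out["species"].extend([name] * total)
        out["fork_length_cm"].extend(lengths)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# diets


@dataclass
class DietScenario:
    """Generative description of stomach contents.

    ``composition`` maps ``(species, region, size_bin)`` -- size bin one of
    :data:`PROTOCOL_SIZE_BINS` -- to a probability vector over ``taxa``.  A
    sampled stomach is empty with probability ``empty_prob`` (per species or
    global); otherwise its items' taxa follow a Dirichlet perturbation of the
    group composition with the given ``concentration``, so the expected pooled
    prey-weight composition equals the group composition while individual
    stomachs vary and contain only a few taxa.
    """

    taxa: tuple[str, ...]
    composition: Mapping[tuple[str, str, str], np.ndarray]
    region_of: Callable[[np.ndarray, np.ndarray], np.ndarray]
    empty_prob: Mapping[str, float] | float = 0.3
    stomachs_per_haul_cap: int = 5
    weight_scale: float = 20.0
    concentration: float = 30.0
    items_mean: float = 2.0
    haul_sampling_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for key, w in self.composition.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(self.taxa),) or (w < 0).any():
                raise ValueError(f"invalid composition vector for {key}")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"composition for {key} sums to {w.sum():.12f}, not 1"
                )
        probs = (
            self.empty_prob.values()
            if isinstance(self.empty_prob, Mapping)
            else [self.empty_prob]
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError("empty_prob must be in [0, 1]")

    def empty_prob_for(self, species: str) -> float:
        if isinstance(self.empty_prob, Mapping):
            return float(self.empty_prob[species])
        return float(self.empty_prob)


def _protocol_bin(length_cm: int) -> str:
    if length_cm < 31:
        return PROTOCOL_SIZE_BINS[0]
    if length_cm <= 50:
        return PROTOCOL_SIZE_BINS[1]
    if length_cm <= 70:
        return PROTOCOL_SIZE_BINS[2]
    return PROTOCOL_SIZE_BINS[3]


_FULLNESS_CODES = np.array([2, 3, 4, 5, 6, 7])
_FULLNESS_PROBS = np.array([0.14, 0.20, 0.22, 0.18, 0.16, 0.10])


def simulate_stomachs(
    hauls: pd.DataFrame,
    specimens: pd.DataFrame,
    diet: DietScenario,
) -> pd.DataFrame:
    """Stomach samples: up to the cap per haul, species and protocol size bin.

    Output is one row per prey item (``stomach_id, haul_id, species,
    fork_length_cm, fullness_code, prey_taxon, prey_weight_g``); an empty
    stomach (fullness code 1) contributes a single row with no prey taxon.
    """
    if specimens.empty:
        return pd.DataFrame(
            columns=["stomach_id", "haul_id", "species", "fork_length_cm",
                     "fullness_code", "prey_taxon", "prey_weight_g"]
        )
    rng = _rng(diet.seed, 3)
    taxa = np.asarray(diet.taxa)
    haul_info = hauls.set_index("haul_id")[["lon", "lat"]]
    merged = specimens.merge(
        haul_info, left_on="haul_id", right_index=True, how="left", sort=False
    )
    merged["size_bin"] = [
        _protocol_bin(int(v)) for v in merged["fork_length_cm"]
    ]
    merged["region"] = diet.region_of(
        merged["lon"].to_numpy(), merged["lat"].to_numpy()
    )
    rows = {k: [] for k in ("stomach_id", "haul_id", "species", "fork_length_cm",
                            "fullness_code", "prey_taxon", "prey_weight_g")}

    def emit(sid, hid, species, length, code, taxon, weight):
        rows["stomach_id"].append(sid)
        rows["haul_id"].append(hid)
        rows["species"].append(species)
        rows["fork_length_cm"].append(length)
        rows["fullness_code"].append(code)
        rows["prey_taxon"].append(taxon)
        rows["prey_weight_g"].append(weight)

    sampled: dict[tuple[str, str], bool] = {}
    grouped = merged.groupby(["haul_id", "species", "size_bin"], sort=True)
    for (haul_id, species, size_bin), grp in grouped:
        # food-habits collections visit only a subset of haul/species combos
        key = (haul_id, species)
        if key not in sampled:
            sampled[key] = rng.random() < diet.haul_sampling_prob
        if not sampled[key]:
            continue
        lengths = grp["fork_length_cm"].to_numpy()
        take = min(diet.stomachs_per_haul_cap, len(lengths))
        chosen = rng.permutation(len(lengths))[:take]
        region = grp["region"].iloc[0]
        try:
            comp = np.asarray(
                diet.composition[(species, region, size_bin)], dtype=float
            )
        except KeyError as exc:
            raise KeyError(
                f"no diet composition for {(species, region, size_bin)}"
            ) from exc
        pos = comp > 0
        p_empty = diet.empty_prob_for(species)
        for k, ci in enumerate(chosen):
            sid = f"{haul_id}-{species}-{size_bin}-{k}"
            length = int(lengths[ci])
            if rng.random() < p_empty:
                emit(sid, haul_id, species, length, 1, "", np.nan)
                continue
            code = int(rng.choice(_FULLNESS_CODES, p=_FULLNESS_PROBS))
            q = np.zeros(len(comp))
            q[pos] = rng.dirichlet(diet.concentration * comp[pos])
            m = 1 + rng.poisson(diet.items_mean)
            item_taxa = rng.choice(len(comp), size=m, p=q)
            item_w = diet.weight_scale * np.exp(rng.normal(0.0, 0.7, size=m))
            w_by_taxon = np.bincount(item_taxa, weights=item_w,
                                     minlength=len(comp))
            for t in np.flatnonzero(w_by_taxon):
                emit(sid, haul_id, species, length, code,
                     taxa[t], float(w_by_taxon[t]))
    return pd.DataFrame(rows)


def simulate_overlap_pairs(
    n_pairs: int, r: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Paired (S, D) overlap values with a chosen latent correlation.

    A Gaussian copula with correlation ``r`` is mapped through the normal CDF
    so both indices lie in (0, 1); used for calibration of the
    resource-partitioning correlation test (``r = 0`` gives independent
    overlap dimensions, negative ``r`` a built-in partitioning signal).
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must be in (-1, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    cov = np.array([[1.0, r], [r, 1.0]])
    zz = rng.multivariate_normal([0.0, 0.0], cov, size=n_pairs,
                                 method="cholesky")
    u = norm.cdf(zz)
    return pd.DataFrame({"s": u[:, 0], "d": u[:, 1]})


# ---------------------------------------------------------------------------
# default Gulf-of-Alaska-like scenarios


def _goa_depth_field(lon, lat, year):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    # shelf shallowing northward and westward, deepening steeply offshore
    shelf = (np.clip(60.0 - lat, 0.0, None) / 8.0) ** 1.8
    ridge = 0.15 * np.sin((lon + 170.0) / 6.0)
    return 40.0 + 520.0 * np.clip(shelf + ridge, 0.0, 1.2)


def _goa_temp_field(lon, lat, year):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    depth = _goa_depth_field(lon, lat, year)
    east = (lon + 170.0) / 38.0
    return 3.0 + 3.0 * east + 2.0 * np.exp(-depth / 250.0) + 0.02 * (year - 2000)


def default_scenario(
    seed: int = 0,
    years: tuple[int, ...] = _GOA_YEARS,
    hauls_per_year: int = 720,
    temp_effect: bool = True,
) -> SurveyScenario:
    """Two-species Gulf-of-Alaska-like survey scenario.

    Species ``PH`` (halibut-like) favors shallow, cold, western habitat and is
    present in roughly 60% of tows; ``ATF`` (arrowtooth-like) is nearly
    ubiquitous (~85% of tows) with peak catch rates at intermediate depths and
    a positive temperature response.  ``temp_effect=False`` removes the
    temperature response of both species (used to test whether all-subsets
    selection drops a covariate with no effect).
    """
    years = tuple(int(y) for y in years)
    t_scale = 1.0 if temp_effect else 0.0

    ph = SpeciesParams(
        year_effects={
            y: (1.32 - 0.04 * abs(y - 2001) / 3.0 + 0.02 * max(y - 2001, 0) / 2.0,
                0.8 + 0.015 * (y - 1990))
            for y in years
        },
        spatial_surface=lambda lon, lat: (
            0.9 * np.cos((np.asarray(lon) + 170.0) / 38.0 * np.pi * 0.85)
            + 0.35 * np.sin((np.asarray(lat) - 52.0) / 8.0 * np.pi)
        ),
        depth_response=lambda d: -((np.asarray(d) - 80.0) / 180.0) ** 2,
        temp_response=lambda t: t_scale * (-0.12) * (np.asarray(t) - 5.0),
        cpue_sd=1.0,
        length_median_cm=52.0,
        length_log_sd=0.411,
    )
    atf = SpeciesParams(
        year_effects={
            y: (1.95 + 0.01 * (y - 1990), 1.6 - 0.01 * (y - 1990)) for y in years
        },
        spatial_surface=lambda lon, lat: (
            0.3 * np.cos((np.asarray(lon) + 170.0) / 38.0 * np.pi * 0.6)
            - 0.1 * np.sin((np.asarray(lat) - 52.0) / 8.0 * np.pi)
        ),
        depth_response=lambda d: -((np.asarray(d) - 220.0) / 260.0) ** 2,
        temp_response=lambda t: t_scale * 0.10 * (np.asarray(t) - 5.0),
        cpue_sd=1.1,
        length_median_cm=42.0,
        length_log_sd=0.359,
    )
    return SurveyScenario(
        years=years,
        extent=_GOA_EXTENT,
        hauls_per_year=hauls_per_year,
        species_params={"PH": ph, "ATF": atf},
        depth_field=_goa_depth_field,
        temp_field=_goa_temp_field,
        seed=seed,
    )


_DEFAULT_TAXA = (
    "walleye_pollock", "pacific_herring", "capelin", "eulachon",
    "other_fish", "tanner_crab", "pandalid_shrimp", "hermit_crab",
    "octopus", "squid", "polychaete", "other_invert",
)

_DEFAULT_REGIONS = ("Shumagin", "Chirikof", "Kodiak", "Yakutat", "Southeastern")


def _normalize(v):
    v = np.asarray(v, dtype=float)
    return v / v.sum()


# taxon order: pollock, herring, capelin, eulachon, other_fish,
#              tanner, shrimp, hermit, octopus, squid, polychaete, other_inv
_FISH_BASE = {
    "PH": _normalize([0.18, 0.10, 0.10, 0.07, 0.55, 0, 0, 0, 0, 0, 0, 0]),
    "ATF": _normalize([0.78, 0.07, 0.10, 0.04, 0.01, 0, 0, 0, 0, 0, 0, 0]),
}
_INVERT_BASE = {
    "PH": _normalize([0, 0, 0, 0, 0, 0.45, 0.25, 0.10, 0.07, 0.03, 0.04,
                      0.06]),
    "ATF": _normalize([0, 0, 0, 0, 0, 0, 0.80, 0, 0, 0.15, 0, 0.05]),
}
_HERRING = np.eye(12)[1]


def _mix(species, fish_frac, herring_boost=0.0):
    """Species-typical 12-taxon vector with a given fish fraction by weight."""
    base = _normalize(
        fish_frac * _FISH_BASE[species]
        + (1.0 - fish_frac) * _INVERT_BASE[species]
    )
    if herring_boost > 0:
        base = _normalize(base + herring_boost * _HERRING)
    return base


def _default_region_of(lon, lat):
    # INPFC-style longitude bands, west to east
    breaks = np.array([-159.0, -154.0, -147.0, -137.0])
    idx = np.searchsorted(breaks, np.asarray(lon, dtype=float), side="right")
    return np.asarray(_DEFAULT_REGIONS, dtype=object)[idx]


def default_diet_scenario(seed: int = 0) -> DietScenario:
    """Diet scenario emulating the two predators' contrast in piscivory.

    PH-like diets shift from invertebrate-dominated at small sizes to
    fish-dominated at large sizes; ATF-like diets are fish-dominated
    throughout.  Eastern regions carry a herring boost for both predators.
    """
    comp = {}
    east = {"Yakutat", "Southeastern"}
    for region in _DEFAULT_REGIONS:
        hb = 0.25 if region in east else 0.0
        for b, ph_fish in zip(PROTOCOL_SIZE_BINS, (0.25, 0.45, 0.60, 0.75)):
            comp[("PH", region, b)] = _mix("PH", ph_fish, hb)
        for b in PROTOCOL_SIZE_BINS:
            comp[("ATF", region, b)] = _mix("ATF", 0.93, hb)
    return DietScenario(
        taxa=_DEFAULT_TAXA,
        composition=comp,
        region_of=_default_region_of,
        empty_prob={"PH": 0.21, "ATF": 0.43},
        seed=seed,
    )


def partitioning_diet_scenario(seed: int = 0) -> DietScenario:
    """Diet scenario with built-in resource partitioning.

    Where the default survey scenario puts high spatial overlap (the western
    regions) the two predators' compositions are made nearly disjoint; in the
    low-spatial-overlap east both converge on the same herring-dominated diet.
    End to end this yields a negative correlation between spatial and dietary
    overlap.
    """
    comp = {}
    west = {"Shumagin", "Chirikof"}
    for region in _DEFAULT_REGIONS:
        if region in west:
            ph_mix = _mix("PH", 0.05)          # inverts only
            atf_mix = _mix("ATF", 1.0)         # fish only
        elif region == "Kodiak":
            ph_mix = _mix("PH", 0.30)
            atf_mix = _mix("ATF", 0.90)
        else:                                  # east: convergent herring diet
            herring = _normalize(0.2 * _FISH_BASE["ATF"] + 2.0 * _HERRING)
            ph_mix = atf_mix = herring
        for b in PROTOCOL_SIZE_BINS:
            comp[("PH", region, b)] = ph_mix
            comp[("ATF", region, b)] = atf_mix
    return DietScenario(
        taxa=_DEFAULT_TAXA,
        composition=comp,
        region_of=_default_region_of,
        empty_prob={"PH": 0.21, "ATF": 0.43},
        seed=seed,
    )
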