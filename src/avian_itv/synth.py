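"""Synthetic data generator: the generative inverse of the full pipeline.

Produces complete datasets — capture records, productivity raster, range
polygons, species trait table, phylogeny — from known parameters, so that
every downstream stage has a ground-truth recovery target:

* individual log traits are drawn from the group/species/global hierarchy
  the CV model assumes;
* each group's true CV follows the within-species regression structure
  (species-specific coefficient vectors around global effects) applied to
  covariates *computed from the generated landscape* with the same code the
  pipeline uses;
* species intercepts follow the among-species regression structure with
  phylogenetically correlated deviations drawn on a simulated Yule tree;
* configurable contaminants (gross outliers at +-8 group SDs, repeat
  captures within a season, non-adult-male records) are injected and their
  band ids recorded, so filter recall is measurable.

Geometry is planar in kilometres; station latitude is y_km / 111.32.
Trait magnitudes default to song-bird-like values (log body mass around
log 30 g) so that group CVs sit near 0.02-0.03, the magnitude typical of
avian body-mass data.  All randomness flows from ``SimConfig.seed``; the
same config yields a byte-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape

from .among_model import phylo_correlation
from .covariates import KM_PER_DEGREE, distance_to_edge, spatial_cv, temporal_cv

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_tree",
    "star_tree",
    "simulate_captures",
    "load_dataset_dir",
]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters and layout of a synthetic study.

    ``true_global_effects`` are the cross-species effects of (latitude,
    log distance-to-edge, log spatial CV, log temporal CV) on the CV x 1000
    scale; ``true_species_effect_sd`` the SDs of species deviations around
    them; ``true_zeta`` the among-species effects of the centered-scaled
    (log generation time, log hand-wing index, log range size, migratory
    status) covariates; ``kappa`` the grand mean CV x 1000.
    """

    n_species: int = 8
    n_locations_per_species: int = 8
    n_individuals_range: tuple[int, int] = (20, 40)
    true_global_effects: tuple[float, float, float, float] = (-0.15, 0.15, 0.28, 0.07)
    true_species_effect_sd: tuple[float, float, float, float] = (0.05, 0.08, 0.15, 0.04)
    true_zeta: tuple[float, float, float, float] = (-2.0, 0.0, 0.5, 1.0)
    sigma_theta: float = 1.0
    sigma_xi: float = 1.5
    sigma_phylo: float = 2.0
    tree_depth: float = 1.0
    seed: int = 0
    # magnitude and layout knobs
    kappa: float = 25.0
    mean_log_mass: float = 3.4  # log grams, ~30 g
    sd_log_mass_species: float = 0.5
    sd_log_mass_location: float = 0.04
    mean_log_wing: float = 4.25  # log millimetres, ~70 mm
    lat_range: tuple[float, float] = (30.0, 60.0)
    x_range_km: tuple[float, float] = (0.0, 3000.0)
    raster_resolution_km: float = 4.0
    raster_years: int = 8
    buffer_radius_km: float = 10.0
    outlier_frac: float = 0.02
    duplicate_frac: float = 0.05
    non_adult_male_frac: float = 0.10
    mig_prob: float = 0.88
    theta_floor: float = 2.0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.n_individuals_range[0] < 2:
            raise ValueError("n_individuals_range minimum must be >= 2")
        if self.sigma_theta <= 0 or self.sigma_xi <= 0 or self.tree_depth <= 0:
            raise ValueError("sigma_theta, sigma_xi and tree_depth must be > 0")
        if self.sigma_phylo < 0 or min(self.true_species_effect_sd) < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated study: pipeline inputs plus the truth that produced them."""

    captures: pd.DataFrame
    stations: pd.DataFrame
    raster: pd.DataFrame
    ranges: dict[str, object]  # species -> shapely polygon
    traits: pd.DataFrame
    tree: str  # newick
    truth: dict
    config: SimConfig

    def to_dir(self, path: str | Path) -> Path:
        """Write the standard input files consumed by the pipeline."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.captures.to_csv(path / "captures.csv", index=False)
        self.stations.to_csv(path / "stations.csv", index=False)
        self.raster.to_csv(path / "raster.csv", index=False)
        self.traits.to_csv(path / "traits.csv", index=False)
        (path / "tree.nwk").write_text(self.tree)
        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"species": sp},
                    "geometry": mapping(poly),
                }
                for sp, poly in self.ranges.items()
            ],
        }
        (path / "ranges.geojson").write_text(json.dumps(fc))
        (path / "truth.json").write_text(json.dumps(_jsonable(self.truth), indent=1))
        return path

    # ---- truth-side views used by tests and recovery experiments ----

    def truth_groups(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth["groups"])

    def truth_species(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth["species"])

    #: ratio of the hierarchical CV model's posterior SD to the naive
    #: frequentist SE cv/sqrt(2n) at group sizes of 20-40 individuals;
    #: partial pooling across a species' stations buys roughly this factor
    TAU_POOLING_FACTOR = 0.67

    def make_group_cv_observations(self, seed: int = 0) -> pd.DataFrame:
        """Synthesize stage-1 output directly from the truth.

        Emulates the CV-model posterior summaries without running MCMC:
        tau_hat is the large-sample SE of a CV estimated from n log values
        (cv / sqrt(2 n)) scaled by :data:`TAU_POOLING_FACTOR`, and cv_hat is
        drawn from Normal(true CV, tau_hat).  Exercises the regression
        stages in isolation, with exactly the observation model they assume
        (unlike real stage-1 posterior means, which are slightly shrunk
        toward the species mean).
        """
        rng = np.random.default_rng(seed)
        g = self.truth_groups()
        tau = self.TAU_POOLING_FACTOR * g["cv_mass"] / np.sqrt(2.0 * g["n_clean"])
        out = g[["species", "location_id"]].copy()
        out["n"] = g["n_clean"]
        out["tau_hat"] = tau
        out["cv_hat"] = rng.normal(g["cv_mass"], tau)
        return out

    def make_species_cv_observations(self, seed: int = 0) -> pd.DataFrame:
        """Synthesize species-average CV summaries from the truth."""
        rng = np.random.default_rng(seed)
        g = self.truth_groups()
        tau2 = (
            self.TAU_POOLING_FACTOR * g["cv_mass"] / np.sqrt(2.0 * g["n_clean"])
        ) ** 2
        agg = g.assign(tau2=tau2).groupby("species", sort=True).agg(
            cv_true=("cv_mass", "mean"), tau2=("tau2", "mean"), J=("cv_mass", "size")
        )
        tausp = np.sqrt(agg["tau2"] / agg["J"])
        out = pd.DataFrame(
            {
                "species": agg.index,
                "cvsp_hat": rng.normal(agg["cv_true"], tausp),
                "tausp_hat": tausp,
            }
        ).reset_index(drop=True)
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def simulate_tree(n_species: int, depth: float, seed: int) -> str:
    """Pure-birth (Yule) ultrametric tree, rescaled to the given depth.

    Returns a newick string with tips sp01..spNN, all at root-to-tip
    distance ``depth``.  Branch lengths are strictly positive.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    root = {"birth": 0.0, "children": []}
    a, b = {"birth": 0.0, "children": []}, {"birth": 0.0, "children": []}
    root["children"] = [a, b]
    root["split"] = 0.0
    active = [a, b]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node["split"] = t
        c1, c2 = {"birth": t, "children": []}, {"birth": t, "children": []}
        node["children"] = [c1, c2]
        active.extend([c1, c2])
    total = t + rng.exponential(1.0 / n_species) + 0.05 / n_species
    scale = depth / total
    names = iter(f"sp{i + 1:02d}" for i in range(n_species))

    def newick(node) -> str:
        end = node["split"] if node["children"] else total
        length = (end - node["birth"]) * scale
        if node["children"]:
            inner = ",".join(newick(c) for c in node["children"])
            return f"({inner}):{length:.10f}"
        return f"{next(names)}:{length:.10f}"

    inner = ",".join(newick(c) for c in root["children"])
    return f"({inner});"


def star_tree(n_species: int, depth: float = 1.0) -> str:
    """Star phylogeny: every tip attached directly to the root."""
    tips = ",".join(f"sp{i + 1:02d}:{depth}" for i in range(n_species))
    return f"({tips});"


def _simulate_stations(cfg: SimConfig, species: list[str], rng) -> pd.DataFrame:
    rows = []
    lo, hi = cfg.lat_range
    for k, sp in enumerate(species):
        while True:
            lats = rng.uniform(lo, hi, cfg.n_locations_per_species)
            if np.ptp(lats) >= 5.5:
                break
        xs = rng.uniform(*cfg.x_range_km, cfg.n_locations_per_species)
        for j in range(cfg.n_locations_per_species):
            rows.append(
                {
                    "location_id": f"{sp}_L{j + 1:02d}",
                    "species": sp,
                    "latitude": lats[j],
                    "longitude": xs[j] / KM_PER_DEGREE,
                    "x_km": xs[j],
                    "y_km": lats[j] * KM_PER_DEGREE,
                }
            )
    return pd.DataFrame(rows)


def _simulate_raster(cfg: SimConfig, stations: pd.DataFrame, rng) -> pd.DataFrame:
    """Productivity values around each station with station-specific
    spatial and temporal heterogeneity targets (lognormal multipliers)."""
    res = cfg.raster_resolution_km
    r = cfg.buffer_radius_km
    years = list(range(2001, 2001 + cfg.raster_years))
    cells: dict[tuple[int, int], np.ndarray] = {}
    for st in stations.itertuples(index=False):
        spat = float(np.exp(rng.normal(np.log(0.15), 0.35)))
        temp = float(np.exp(rng.normal(np.log(0.08), 0.35)))
        v = np.log1p(spat**2)
        w = np.log1p(temp**2)
        ix0, ix1 = int(np.floor((st.x_km - r) / res)), int(np.ceil((st.x_km + r) / res))
        iy0, iy1 = int(np.floor((st.y_km - r) / res)), int(np.ceil((st.y_km + r) / res))
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                cx, cy = (ix + 0.5) * res, (iy + 0.5) * res
                if (cx - st.x_km) ** 2 + (cy - st.y_km) ** 2 > r * r:
                    continue
                if (ix, iy) in cells:
                    continue
                m = 0.5 * np.exp(rng.normal(-v / 2, np.sqrt(v)))
                cells[(ix, iy)] = m * np.exp(
                    rng.normal(-w / 2, np.sqrt(w), len(years))
                )
    recs = []
    for (ix, iy), vals in cells.items():
        cx, cy = (ix + 0.5) * res, (iy + 0.5) * res
        for yr, val in zip(years, vals):
            recs.append((cx, cy, yr, val))
    return pd.DataFrame(recs, columns=["x", "y", "year", "value"])


def simulate_captures(cfg: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic study from the configured ground truth."""
    ss = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_tree, rng_land, rng_sp, rng_grp, rng_ind, rng_cont = (
        np.random.default_rng(s) for s in ss
    )
    species = [f"sp{i + 1:02d}" for i in range(cfg.n_species)]

    tree = simulate_tree(cfg.n_species, cfg.tree_depth, int(rng_tree.integers(2**31)))
    stations = _simulate_stations(cfg, species, rng_land)
    raster = _simulate_raster(cfg, stations, rng_land)

    # range polygons: station bounding box expanded by random margins
    ranges: dict[str, object] = {}
    for sp in species:
        st = stations[stations["species"] == sp]
        margins = rng_land.uniform(5.0, 400.0, 4)
        ranges[sp] = box(
            st["x_km"].min() - margins[0],
            st["y_km"].min() - margins[1],
            st["x_km"].max() + margins[2],
            st["y_km"].max() + margins[3],
        )

    # species-level covariates and regression structure
    gen_time = np.exp(rng_sp.uniform(np.log(1.8), np.log(4.3), cfg.n_species))
    hwi = np.exp(rng_sp.uniform(np.log(11.4), np.log(53.0), cfg.n_species))
    mig = (rng_sp.uniform(size=cfg.n_species) < cfg.mig_prob).astype(int)
    range_size = np.array([ranges[sp].area for sp in species])
    traits = pd.DataFrame(
        {
            "species": species,
            "gen_time_yr": gen_time,
            "hwi": hwi,
            "range_size_km2": range_size,
            "mig_status": mig,
        }
    )
    raw_z = np.column_stack(
        [np.log(gen_time), np.log(hwi), np.log(range_size), mig.astype(float)]
    )
    sd_z = raw_z.std(axis=0, ddof=1)
    # a degenerate column (e.g. every species a migrant at small n_species)
    # carries no among-species signal; its standardized value is zero
    z = np.where(
        sd_z > 0, (raw_z - raw_z.mean(axis=0)) / np.where(sd_z > 0, sd_z, 1.0), 0.0
    )

    P = phylo_correlation(tree, species).P
    chol = np.linalg.cholesky(P + 1e-10 * np.eye(cfg.n_species))
    eta = cfg.sigma_phylo * (chol @ rng_sp.standard_normal(cfg.n_species))
    zeta = np.asarray(cfg.true_zeta, dtype=float)
    alpha = cfg.kappa + eta + z @ zeta + rng_sp.normal(0, cfg.sigma_xi, cfg.n_species)
    beta = np.asarray(cfg.true_global_effects) + rng_sp.normal(
        0, cfg.true_species_effect_sd, (cfg.n_species, 4)
    )

    # per-group covariates computed from the generated landscape
    group_rows = []
    for k, sp in enumerate(species):
        st = stations[stations["species"] == sp]
        for srow in st.itertuples(index=False):
            pt = (srow.x_km, srow.y_km)
            group_rows.append(
                {
                    "species": sp,
                    "location_id": srow.location_id,
                    "latitude": srow.latitude,
                    "Lat_raw": srow.latitude,
                    "DistEdge_raw": distance_to_edge(pt, ranges[sp], cfg.buffer_radius_km),
                    "SpatVar_raw": spatial_cv(raster, pt, cfg.buffer_radius_km),
                    "TempVar_raw": temporal_cv(raster, pt, cfg.buffer_radius_km),
                }
            )
    groups = pd.DataFrame(group_rows)
    groups["Lat"] = groups["Lat_raw"]
    groups["DistEdge"] = np.log(groups["DistEdge_raw"] + 1.0)
    groups["SpatVar"] = np.log(groups["SpatVar_raw"])
    groups["TempVar"] = np.log(groups["TempVar_raw"])
    for col in ["Lat", "DistEdge", "SpatVar", "TempVar"]:
        groups[col] -= groups.groupby("species")[col].transform("mean")

    sp_idx = groups["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    Xc = groups[["Lat", "DistEdge", "SpatVar", "TempVar"]].to_numpy()
    theta = (
        alpha[sp_idx]
        + (Xc * beta[sp_idx]).sum(axis=1)
        + rng_grp.normal(0, cfg.sigma_theta, len(groups))
    )
    n_clipped = int((theta < cfg.theta_floor).sum())
    theta = np.maximum(theta, cfg.theta_floor)
    groups["theta"] = theta
    cv = theta / 1000.0

    mu_mean = rng_grp.normal(cfg.mean_log_mass, cfg.sd_log_mass_species, cfg.n_species)
    mu_w_mean = rng_grp.normal(cfg.mean_log_wing, 0.3, cfg.n_species)
    mu_jk = rng_grp.normal(mu_mean[sp_idx], cfg.sd_log_mass_location)
    mu_w_jk = rng_grp.normal(mu_w_mean[sp_idx], cfg.sd_log_mass_location)
    sigma_jk = cv * mu_jk
    cv_w = cv / 3.0
    sigma_w_jk = cv_w * mu_w_jk
    groups["cv_mass"] = cv
    groups["mu_log_mass"] = mu_jk
    groups["sigma_log_mass"] = sigma_jk
    groups["cv_wing"] = cv_w
    groups["mu_log_wing"] = mu_w_jk
    groups["sigma_log_wing"] = sigma_w_jk

    # individuals + contaminants
    lat_by_loc = stations.set_index("location_id")[["latitude", "longitude"]]
    band_counter = 0

    def next_band() -> str:
        nonlocal band_counter
        band_counter += 1
        return f"B{band_counter:06d}"

    cap_rows: list[dict] = []
    contaminants = {"outliers": [], "duplicates": [], "non_adult_male": []}
    n_per_group = []
    for g_i, grp in enumerate(groups.itertuples(index=False)):
        n = int(rng_ind.integers(cfg.n_individuals_range[0], cfg.n_individuals_range[1] + 1))
        n_per_group.append(n)
        lat = float(lat_by_loc.loc[grp.location_id, "latitude"])
        lon = float(lat_by_loc.loc[grp.location_id, "longitude"])
        y_mass = rng_ind.normal(grp.mu_log_mass, grp.sigma_log_mass, n)
        y_wing = rng_ind.normal(grp.mu_log_wing, grp.sigma_log_wing, n)
        years = rng_ind.integers(2005, 2013, n)
        months = rng_ind.integers(5, 8, n)
        days = rng_ind.integers(1, 29, n)
        group_bands = []
        for i in range(n):
            band = next_band()
            group_bands.append((band, years[i], months[i], days[i]))
            cap_rows.append(
                {
                    "band_id": band,
                    "species": grp.species,
                    "location_id": grp.location_id,
                    "latitude": lat,
                    "longitude": lon,
                    "date": f"{years[i]}-{months[i]:02d}-{days[i]:02d}",
                    "age_class": "adult",
                    "sex": "M",
                    "mass": float(np.exp(y_mass[i])),
                    "wing": float(np.exp(y_wing[i])),
                }
            )
        # repeat captures later in the same season
        n_dup = int(round(cfg.duplicate_frac * n))
        for i in rng_cont.choice(n, size=n_dup, replace=False):
            band, yr, mo, dy = group_bands[i]
            contaminants["duplicates"].append(band)
            cap_rows.append(
                {
                    "band_id": band,
                    "species": grp.species,
                    "location_id": grp.location_id,
                    "latitude": lat,
                    "longitude": lon,
                    "date": f"{yr}-{mo + 1:02d}-{dy:02d}",
                    "age_class": "adult",
                    "sex": "M",
                    "mass": float(np.exp(rng_cont.normal(grp.mu_log_mass, grp.sigma_log_mass))),
                    "wing": float(np.exp(rng_cont.normal(grp.mu_log_wing, grp.sigma_log_wing))),
                }
            )
        # non-adult-male records
        n_nam = int(round(cfg.non_adult_male_frac * n))
        combos = [("juvenile", "M"), ("adult", "F"), ("unknown", "U")]
        for i in range(n_nam):
            band = next_band()
            contaminants["non_adult_male"].append(band)
            age, sex = combos[int(rng_cont.integers(len(combos)))]
            cap_rows.append(
                {
                    "band_id": band,
                    "species": grp.species,
                    "location_id": grp.location_id,
                    "latitude": lat,
                    "longitude": lon,
                    "date": f"{int(rng_cont.integers(2005, 2013))}-"
                    f"{int(rng_cont.integers(5, 9)):02d}-"
                    f"{int(rng_cont.integers(1, 29)):02d}",
                    "age_class": age,
                    "sex": sex,
                    "mass": float(np.exp(rng_cont.normal(grp.mu_log_mass, grp.sigma_log_mass))),
                    "wing": float(np.exp(rng_cont.normal(grp.mu_log_wing, grp.sigma_log_wing))),
                }
            )
        # gross outliers at +-8 group SDs
        n_out = int(round(cfg.outlier_frac * n))
        for i in range(n_out):
            band = next_band()
            contaminants["outliers"].append(band)
            sign = 1.0 if rng_cont.uniform() < 0.5 else -1.0
            cap_rows.append(
                {
                    "band_id": band,
                    "species": grp.species,
                    "location_id": grp.location_id,
                    "latitude": lat,
                    "longitude": lon,
                    "date": f"{int(rng_cont.integers(2005, 2013))}-"
                    f"{int(rng_cont.integers(5, 8)):02d}-"
                    f"{int(rng_cont.integers(1, 29)):02d}",
                    "age_class": "adult",
                    "sex": "M",
                    "mass": float(np.exp(grp.mu_log_mass + sign * 8 * grp.sigma_log_mass)),
                    "wing": float(np.exp(grp.mu_log_wing + sign * 8 * grp.sigma_log_wing)),
                }
            )
    groups["n_clean"] = n_per_group
    captures = pd.DataFrame(cap_rows)

    truth = {
        "config": asdict(cfg),
        "species": {
            "species": species,
            "alpha": alpha,
            "beta1": beta[:, 0],
            "beta2": beta[:, 1],
            "beta3": beta[:, 2],
            "beta4": beta[:, 3],
            "eta": eta,
            "z_GenTime": z[:, 0],
            "z_HWI": z[:, 1],
            "z_RangeSize": z[:, 2],
            "z_MigStatus": z[:, 3],
            "mu_mean_log_mass": mu_mean,
            "mu_mean_log_wing": mu_w_mean,
        },
        "groups": {c: groups[c].tolist() for c in groups.columns},
        "contaminants": contaminants,
        "n_theta_clipped": n_clipped,
    }
    return SyntheticDataset(
        captures=captures,
        stations=stations,
        raster=raster,
        ranges=ranges,
        traits=traits,
        tree=tree,
        truth=truth,
        config=cfg,
    )


def load_dataset_dir(path: str | Path) -> dict:
    """Read back the files written by :meth:`SyntheticDataset.to_dir`."""
    path = Path(path)
    fc = json.loads((path / "ranges.geojson").read_text())
    ranges = {
        f["properties"]["species"]: shape(f["geometry"]) for f in fc["features"]
    }
    out = {
        "captures": pd.read_csv(path / "captures.csv"),
        "stations": pd.read_csv(path / "stations.csv"),
        "raster": pd.read_csv(path / "raster.csv"),
        "traits": pd.read_csv(path / "traits.csv"),
        "ranges": ranges,
        "tree": (path / "tree.nwk").read_text(),
    }
    truth_file = path / "truth.json"
    if truth_file.exists():
        out["truth"] = json.loads(truth_file.read_text())
    return out
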