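"""Synthetic leaf-trait datasets with the statistical structure the
analysis assumes.

The generator emulates a global multi-site, multi-species Vcmax25
compilation: per-site growing-season climate drawn over realistic
ranges, ln Vcmax25 generated from the optimality theory plus Gaussian
site, species and residual effects on the log scale (species are drawn
from a shared pool so some occur at several sites — the crossed design),
leaf nitrogen coupled to photosynthetic capacity (metabolic component)
plus a structural intercept, leaf phosphorus coupled to total soil P,
and an optional phosphorus-limitation cap applied through the
smooth-minimum used by :mod:`leafopt.minfunc`.

Monthly climate tables are emitted by *inverting* the growing-season
aggregation: twelve identical above-freezing months at latitude 0 whose
daytime temperature, PPFD and vapour pressure deficit reproduce the
target aggregates exactly (the generator's contract is the aggregate,
not weather realism).

Every random draw comes from a per-field substream spawned from the one
seed, so adding a field never silently shifts existing draws, and the
output is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate import patm_from_elevation, saturation_vapour_pressure, R_DRY, R_VAP
from .minfunc import smooth_min
from .theory import BERNACCHI, EnvConditions, KineticParams, arrhenius_factor, \
    gamma_star, michaelis_k, vcmax_opt

__all__ = ["GeneratorConfig", "SimulatedData", "generate", "make_fixture"]

_FIELDS = ("climate", "soil", "species", "effects", "nutrients", "measurement")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    The default log-scale effect standard deviations put 50 %, 22 % and
    28 % of the variance unexplained by climate on site, species and
    residual terms respectively, with a total unexplained variance
    (~2.5 on ln Vcmax25) that leaves climate explaining a realistically
    small share (~0.2) of all-species variation.
    """

    n_sites: int = 200
    species_range: tuple = (4, 12)      # species per site, inclusive
    species_pool: int = 250             # size of the global species pool
    individuals_range: tuple = (1, 3)   # individuals per species-at-site
    ppfd_range: tuple = (100.0, 800.0)  # umol m-2 s-1, log-uniform
    tg_range: tuple = (0.0, 30.0)       # degC, uniform
    d_range_kpa: tuple = (0.1, 3.0)     # kPa, log-uniform (capped below es)
    elev_range: tuple = (0.0, 4500.0)   # m, uniform
    ca_ppm: float = 400.0
    sigma_site: float = 1.12            # sd of site intercepts, ln Vcmax25
    sigma_species: float = 0.74         # sd of species intercepts
    sigma_resid: float = 0.84           # residual sd (species-at-site level)
    # leaf N = structural intercept + metabolic slope * Vcmax25 + noise (g m-2)
    narea_intercept: float = 0.6
    narea_slope: float = 0.02
    narea_sd: float = 0.25
    narea_ph_slope: float = 0.0   # g m-2 per pH unit (soil-acidity coupling)
    # ln(leaf P) = intercept + slope * ln(total soil P) + noise
    parea_ln_intercept: float = -4.4
    parea_soilp_slope: float = 0.4
    parea_sd: float = 0.3
    # optional P-limitation cap on ln Vcmax25 via the smooth minimum
    p_cap_enabled: bool = False
    p_cap_limb: tuple = (5.5, 0.8)      # (intercept, slope) on ln Parea
    p_cap_k: float = 20.0
    # soils
    ph_range: tuple = (3.5, 8.5)
    c_to_n_range: tuple = (5.0, 40.0)
    total_p_range: tuple = (50.0, 2000.0)  # mg kg-1, log-uniform
    one_point_fraction: float = 0.06
    diurnal_range: float = 8.0          # degC, shrunk near freezing
    params: KineticParams = field(default_factory=lambda: BERNACCHI)

    def __post_init__(self):
        for name in ("sigma_site", "sigma_species", "sigma_resid",
                     "narea_sd", "parea_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("species_range", "ppfd_range", "tg_range", "d_range_kpa",
                     "elev_range", "ph_range", "c_to_n_range", "total_p_range",
                     "individuals_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if not 0 <= self.one_point_fraction <= 1:
            raise ValueError("one_point_fraction must be in [0, 1]")


@dataclass
class SimulatedData:
    """Emitted tables plus the generating truth."""

    leaf_obs: pd.DataFrame
    soil: pd.DataFrame
    climate_monthly: pd.DataFrame
    truth_records: pd.DataFrame   # per species-at-site generating values
    truth_sites: pd.DataFrame     # per-site generating climate and soil
    config: GeneratorConfig
    seed: int

    def records_with_climate(self) -> pd.DataFrame:
        """Species-at-site records joined to generating site climate."""
        cols = ["site_id", "species", "vcmax25", "narea", "parea"]
        rec = self.truth_records[cols]
        clim = self.truth_sites[["site_id", "tg_c", "ppfd", "d_kpa",
                                 "elevation_m", "patm_pa"]]
        return rec.merge(clim, on="site_id")


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_FIELDS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_FIELDS, children)}


def _log_uniform(rng, lo, hi, size):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


def _invert_q_air(ea_kpa: float, patm: float) -> float:
    """Specific humidity giving actual vapour pressure ``ea_kpa`` at ``patm``."""
    ea = ea_kpa * 1000.0
    if not 0.0 <= ea < patm:
        raise ValueError("ea must be in [0, patm)")
    w_air = ea * R_DRY / (R_VAP * (patm - ea))
    return w_air / (1.0 + w_air)


def _draw_site_climate(cfg: GeneratorConfig, rng) -> pd.DataFrame:
    n = cfg.n_sites
    ppfd = _log_uniform(rng, *cfg.ppfd_range, n)
    tg = rng.uniform(*cfg.tg_range, n)
    elev = rng.uniform(*cfg.elev_range, n)
    # daytime Tg exceeds the diurnal mean; keep the mean above freezing so
    # all twelve emitted months belong to the thermal growing season
    tmean = np.maximum(0.5 * tg, tg - cfg.diurnal_range / math.pi)
    es = saturation_vapour_pressure(tmean)
    d_hi = np.minimum(cfg.d_range_kpa[1], 0.95 * es)
    d_lo = np.where(d_hi > cfg.d_range_kpa[0], cfg.d_range_kpa[0], 0.5 * d_hi)
    u = rng.uniform(0.0, 1.0, n)
    d = np.exp(np.log(d_lo) + u * (np.log(d_hi) - np.log(d_lo)))
    return pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(n)],
        "lat": 0.0, "elevation_m": elev, "tg_c": tg, "tmean_c": tmean,
        "ppfd": ppfd, "d_kpa": d,
        "patm_pa": patm_from_elevation(elev)})


def _monthly_from_sites(sites: pd.DataFrame, cfg: GeneratorConfig) -> pd.DataFrame:
    """Twelve identical months per site that aggregate back exactly."""
    rows = []
    for s in sites.itertuples(index=False):
        delta = math.pi * (s.tg_c - s.tmean_c)  # diurnal range implied by Tg
        tmax = s.tmean_c + delta / 2.0
        tmin = s.tmean_c - delta / 2.0
        es = saturation_vapour_pressure(s.tmean_c)
        q = _invert_q_air(es - s.d_kpa, s.patm_pa)
        for month in range(1, 13):
            rows.append({"site_id": s.site_id, "lat": s.lat,
                         "elevation_m": s.elevation_m, "month": month,
                         "tmax_c": tmax, "tmin_c": tmin,
                         "sw_wm2": s.ppfd / cfg.params.e2f, "q_air": q})
    return pd.DataFrame(rows)


def _draw_soil(cfg: GeneratorConfig, sites: pd.DataFrame, rng) -> pd.DataFrame:
    n = len(sites)
    return pd.DataFrame({
        "site_id": sites["site_id"].to_numpy(),
        "ph": rng.uniform(*cfg.ph_range, n),
        "c_to_n": rng.uniform(*cfg.c_to_n_range, n),
        "total_p": _log_uniform(rng, *cfg.total_p_range, n)})


def generate(config: GeneratorConfig, seed: int) -> SimulatedData:
    """Draw one full synthetic dataset (leaf, soil, monthly climate, truth)."""
    rngs = _streams(seed)
    cfg = config

    sites = _draw_site_climate(cfg, rngs["climate"])
    soil = _draw_soil(cfg, sites, rngs["soil"])

    # theory ln Vcmax25 and optimal Ci per site
    lnv_theory = np.empty(len(sites))
    ci_pa = np.empty(len(sites))
    for i, s in enumerate(sites.itertuples(index=False)):
        env = EnvConditions.from_climate(s.tg_c, s.d_kpa, s.ppfd,
                                         s.elevation_m, cfg.ca_ppm)
        pred = vcmax_opt(env, cfg.params)
        lnv_theory[i] = math.log(pred.vcmax25)
        ci_pa[i] = pred.ci
    sites = sites.assign(lnv_theory=lnv_theory, ci_pa=ci_pa)

    # species-at-site structure: species drawn from a common pool (crossed)
    rs = rngs["species"]
    pool = [f"sp{j:04d}" for j in range(cfg.species_pool)]
    site_ids, species_ids = [], []
    for s in sites.itertuples(index=False):
        k = int(rs.integers(cfg.species_range[0], cfg.species_range[1] + 1))
        chosen = rs.choice(cfg.species_pool, size=min(k, cfg.species_pool),
                           replace=False)
        site_ids.extend([s.site_id] * len(chosen))
        species_ids.extend(pool[j] for j in chosen)
    rec = pd.DataFrame({"site_id": site_ids, "species": species_ids})

    # random effects on ln Vcmax25
    re = rngs["effects"]
    site_eff = dict(zip(sites["site_id"],
                        re.normal(0.0, cfg.sigma_site, len(sites))))
    sp_eff = dict(zip(pool, re.normal(0.0, cfg.sigma_species, cfg.species_pool)))
    resid = re.normal(0.0, cfg.sigma_resid, len(rec))
    rec = rec.merge(sites[["site_id", "lnv_theory", "ci_pa", "tg_c",
                           "patm_pa"]], on="site_id")
    rec["site_effect"] = rec["site_id"].map(site_eff)
    rec["species_effect"] = rec["species"].map(sp_eff)
    rec["resid"] = resid
    rec["lnv_uncapped"] = (rec["lnv_theory"] + rec["site_effect"]
                           + rec["species_effect"] + rec["resid"])

    # nutrients: P from soil, N from capacity; optional P cap on capacity
    rn = rngs["nutrients"]
    rec = rec.merge(soil[["site_id", "total_p"]], on="site_id")
    rec["parea"] = np.exp(cfg.parea_ln_intercept
                          + cfg.parea_soilp_slope * np.log(rec["total_p"])
                          + rn.normal(0.0, cfg.parea_sd, len(rec)))
    if cfg.p_cap_enabled:
        cap = cfg.p_cap_limb[0] + cfg.p_cap_limb[1] * np.log(rec["parea"])
        rec["lnv_final"] = smooth_min(rec["lnv_uncapped"].to_numpy(),
                                      cap.to_numpy(), cfg.p_cap_k)
        rec["limitation"] = np.where(cap.to_numpy()
                                     < rec["lnv_uncapped"].to_numpy(), "P", "N")
    else:
        rec["lnv_final"] = rec["lnv_uncapped"]
        rec["limitation"] = "none"
    rec["vcmax25"] = np.exp(rec["lnv_final"])
    rec = rec.merge(soil[["site_id", "ph"]], on="site_id")
    rec["narea"] = np.maximum(
        cfg.narea_intercept + cfg.narea_slope * rec["vcmax25"]
        + cfg.narea_ph_slope * (rec["ph"] - 6.0)
        + rn.normal(0.0, cfg.narea_sd, len(rec)), 0.05)

    # leaf observations: individuals at leaf temperature, mostly A-Ci
    rm = rngs["measurement"]
    obs_rows = []
    p = cfg.params
    for r in rec.itertuples(index=False):
        n_ind = int(rm.integers(cfg.individuals_range[0],
                                cfg.individuals_range[1] + 1))
        one_point = rm.random() < cfg.one_point_fraction
        for ind in range(n_ind):
            t_leaf = float(np.clip(r.tg_c + rm.normal(2.0, 3.0), 5.0, 40.0))
            v_at_t = r.vcmax25 * arrhenius_factor(p.dha_vcmax, t_leaf)
            j_at_t = 1.67 * r.vcmax25 * arrhenius_factor(p.dha_jmax, t_leaf)
            row = {"site_id": r.site_id, "species": r.species,
                   "individual": ind + 1, "t_leaf_c": t_leaf,
                   "narea_g_m2": r.narea, "parea_g_m2": r.parea,
                   "asat": np.nan, "rd": np.nan, "ci_pa": np.nan,
                   "vcmax_at_tleaf": np.nan, "jmax_at_tleaf": j_at_t}
            if one_point:
                gs = gamma_star(t_leaf, r.patm_pa, p)
                kk = michaelis_k(t_leaf, r.patm_pa, p)
                frac = (r.ci_pa - gs) / (r.ci_pa + kk)
                if ind % 2 == 0:
                    rd = p.rd_frac * v_at_t
                    row.update(method="one_point", asat=v_at_t * frac - rd,
                               rd=rd, ci_pa=r.ci_pa)
                else:
                    row.update(method="one_point_no_rd",
                               asat=v_at_t * (frac - p.rd_frac), ci_pa=r.ci_pa)
            else:
                row.update(method="aci", vcmax_at_tleaf=v_at_t)
            obs_rows.append(row)
    leaf_obs = pd.DataFrame(obs_rows)

    truth_records = rec[["site_id", "species", "lnv_theory", "site_effect",
                         "species_effect", "resid", "lnv_uncapped",
                         "lnv_final", "vcmax25", "narea", "parea",
                         "limitation"]]
    truth_sites = sites.merge(soil, on="site_id")
    return SimulatedData(leaf_obs=leaf_obs, soil=soil,
                         climate_monthly=_monthly_from_sites(sites, cfg),
                         truth_records=truth_records, truth_sites=truth_sites,
                         config=cfg, seed=seed)


def make_fixture(name: str):
    """Small deterministic fixtures for tests and demos.

    * ``tiny`` — 3 sites x 2 species, modest noise; hand-checkable.
    * ``median_climate`` — a single environment row at the dataset's
      median climate (PPFD 400, Tg 25 degC, D 0.60 kPa, sea level).
    * ``minfunc_demo`` — 40 records generated exactly from two known
      limbs through a sharp smooth minimum.
    """
    if name == "tiny":
        cfg = GeneratorConfig(n_sites=3, species_range=(2, 2), species_pool=4,
                              individuals_range=(1, 1), sigma_site=0.1,
                              sigma_species=0.1, sigma_resid=0.05,
                              one_point_fraction=0.0)
        return generate(cfg, seed=12345)
    if name == "median_climate":
        return pd.DataFrame([{"site_id": "median", "tg_c": 25.0,
                              "d_kpa": 0.60, "ppfd": 400.0,
                              "elevation_m": 0.0}])
    if name == "minfunc_demo":
        rng = np.random.default_rng(20210412)
        narea = np.exp(rng.uniform(math.log(0.5), math.log(3.0), 40))
        parea = np.exp(rng.uniform(math.log(0.03), math.log(0.3), 40))
        limb_n = 3.0 + 0.8 * np.log(narea)
        limb_p = 4.6 + 0.7 * np.log(parea)
        lnv = smooth_min(limb_n, limb_p, 50.0)
        return pd.DataFrame({"site_id": [f"S{i:02d}" for i in range(40)],
                             "species": [f"sp{i:02d}" for i in range(40)],
                             "narea": narea, "parea": parea,
                             "vcmax25": np.exp(lnv)})
    raise ValueError(f"unknown fixture {name!r}")
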