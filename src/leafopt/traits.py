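"""Analysis-ready leaf records: one-point Vcmax, 25 degC standardization,
site-mean aggregation.

Vcmax for records lacking a full A-Ci curve is estimated from a single
light-saturated assimilation measurement (the one-point method):

    Vcmax ~= (Asat + Rd) (Ci + K) / (Ci - G*)

or, without a respiration measurement, with Rd taken as a fixed fraction
(default 1.5 %) of Vcmax:

    Vcmax ~= Asat / [(Ci - G*) / (Ci + K) - 0.015]

Values measured away from 25 degC are standardized with the Arrhenius
equation (activation energies from the configured kinetic constant set).

Site aggregation is two-stage: individuals are averaged to a
species-at-site record, then species-at-site records are averaged to a
site (community) mean — matching the convention that an "all-species"
data point is one species at one site and a "site-mean" data point is
one site.  Means are taken on the natural scale; log-transformation for
regression happens downstream (mean-of-logs != log-of-means).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .theory import BERNACCHI, KineticParams, arrhenius_factor, gamma_star, michaelis_k
from .theory import P_SEALEVEL

__all__ = [
    "vcmax_one_point",
    "vcmax_one_point_no_rd",
    "standardize_to_25",
    "aggregate_site_means",
    "build_leaf_records",
]

log = logging.getLogger(__name__)


def vcmax_one_point(asat, rd, ci_pa, t_leaf_c, patm=P_SEALEVEL,
                    params: KineticParams = BERNACCHI):
    """One-point Vcmax estimate at leaf temperature from Asat and Rd.

    All rates umol m-2 s-1, Ci in Pa.  Requires Ci above the
    compensation point at (t_leaf_c, patm).
    """
    asat = np.asarray(asat, dtype=float)
    rd = np.asarray(rd, dtype=float)
    if np.any(asat <= 0):
        raise ValueError("asat must be positive")
    if np.any(rd < 0):
        raise ValueError("rd must be >= 0")
    gs = gamma_star(t_leaf_c, patm, params)
    if np.any(np.asarray(ci_pa) <= gs):
        raise ValueError(f"Ci = {ci_pa} Pa at or below compensation point "
                         f"{gs:.3f} Pa")
    k = michaelis_k(t_leaf_c, patm, params)
    out = (asat + rd) * (ci_pa + k) / (ci_pa - gs)
    return float(out) if out.ndim == 0 else out


def vcmax_one_point_no_rd(asat, ci_pa, t_leaf_c, patm=P_SEALEVEL,
                          params: KineticParams = BERNACCHI):
    """One-point Vcmax with day respiration taken as ``rd_frac`` of Vcmax.

    Vcmax = Asat / [(Ci - G*)/(Ci + K) - rd_frac]; the denominator must
    be positive (otherwise assumed respiration exceeds gross
    assimilation and no finite estimate exists).
    """
    asat = np.asarray(asat, dtype=float)
    if np.any(asat <= 0):
        raise ValueError("asat must be positive")
    gs = gamma_star(t_leaf_c, patm, params)
    if np.any(np.asarray(ci_pa) <= gs):
        raise ValueError(f"Ci = {ci_pa} Pa at or below compensation point "
                         f"{gs:.3f} Pa")
    k = michaelis_k(t_leaf_c, patm, params)
    denom = (ci_pa - gs) / (ci_pa + k) - params.rd_frac
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("assumed respiration exceeds gross assimilation "
                         "((Ci - G*)/(Ci + K) <= rd_frac)")
    out = asat / denom
    return float(out) if out.ndim == 0 else out


def standardize_to_25(v_at_t, t_c, which: str = "vcmax",
                      params: KineticParams = BERNACCHI):
    """Standardize a Vcmax or Jmax value from ``t_c`` to 25 degC (Arrhenius)."""
    t = np.asarray(t_c, dtype=float)
    if np.any(t < 0) or np.any(t > 50):
        raise ValueError("measurement temperature outside 0-50 degC")
    try:
        dha = {"vcmax": params.dha_vcmax, "jmax": params.dha_jmax}[which]
    except KeyError:
        raise ValueError(f"which must be 'vcmax' or 'jmax', got {which!r}") from None
    return np.asarray(v_at_t, dtype=float) / arrhenius_factor(dha, t_c) \
        if np.ndim(v_at_t) else v_at_t / arrhenius_factor(dha, t_c)


def build_leaf_records(leaf_obs: pd.DataFrame, patm=P_SEALEVEL,
                       params: KineticParams = BERNACCHI) -> pd.DataFrame:
    """Turn raw observations into species-at-site records with vcmax25.

    ``leaf_obs`` columns (blank-tolerant): site_id, species, individual,
    method ('aci' | 'one_point' | 'one_point_no_rd'), asat, rd, ci_pa,
    t_leaf_c, vcmax_at_tleaf, jmax_at_tleaf, narea_g_m2, parea_g_m2.
    ``patm`` may be a scalar or a per-row array (site pressure).

    A-Ci records take vcmax_at_tleaf as given; one-point records compute
    it from Asat (records lacking Ci are dropped with a logged count).
    Everything is standardized to 25 degC, then individuals are averaged
    within species-at-site.
    """
    df = leaf_obs.copy()
    patm_col = np.broadcast_to(np.asarray(patm, dtype=float), (len(df),))

    vc25 = np.full(len(df), np.nan)
    jx25 = np.full(len(df), np.nan)
    n_dropped = 0
    for i, (row, p) in enumerate(zip(df.itertuples(index=False), patm_col)):
        method = row.method
        t = row.t_leaf_c
        if method == "aci":
            v = row.vcmax_at_tleaf
        elif method in ("one_point", "one_point_no_rd"):
            if pd.isna(row.ci_pa):
                n_dropped += 1
                continue
            if method == "one_point":
                v = vcmax_one_point(row.asat, row.rd, row.ci_pa, t, p, params)
            else:
                v = vcmax_one_point_no_rd(row.asat, row.ci_pa, t, p, params)
        else:
            raise ValueError(f"unknown method {method!r}")
        if pd.isna(v):
            n_dropped += 1
            continue
        vc25[i] = standardize_to_25(v, t, "vcmax", params)
        if hasattr(row, "jmax_at_tleaf") and not pd.isna(row.jmax_at_tleaf):
            jx25[i] = standardize_to_25(row.jmax_at_tleaf, t, "jmax", params)
    if n_dropped:
        log.info("dropped %d records lacking Ci or Vcmax", n_dropped)
    df["vcmax25"] = vc25
    df["jmax25"] = jx25
    df = df[np.isfinite(df["vcmax25"])]

    agg = {"vcmax25": "mean", "jmax25": "mean",
           "narea_g_m2": "mean", "parea_g_m2": "mean"}
    agg = {k: v for k, v in agg.items() if k in df.columns}
    out = (df.groupby(["site_id", "species"], sort=True)
             .agg(agg).reset_index()
             .rename(columns={"narea_g_m2": "narea", "parea_g_m2": "parea"}))
    out["method"] = (df.groupby(["site_id", "species"], sort=True)["method"]
                       .agg(lambda s: s.iloc[0]).values)
    return out


def aggregate_site_means(records: pd.DataFrame,
                         soil: pd.DataFrame | None = None,
                         two_stage: bool = True) -> pd.DataFrame:
    """Community (site) means of traits from species-at-site records.

    ``records`` needs site_id, species, vcmax25 and optionally narea,
    parea.  With ``two_stage`` (default) duplicate rows for a species at
    a site are first averaged so each species contributes once;
    ``two_stage=False`` pools all rows directly.  Trait means use only
    present values; per-trait counts are tracked.  Soil properties
    (columns ph, c_to_n, total_p) join on site_id; soil rows without
    trait data are logged, not fatal.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    df = records.copy()
    traits = [c for c in ("vcmax25", "narea", "parea") if c in df.columns]
    if two_stage:
        df = df.groupby(["site_id", "species"], sort=True)[traits].mean().reset_index()

    g = df.groupby("site_id", sort=True)
    out = g[traits].mean()
    for t in traits:
        out[f"n_{t}"] = g[t].count()
    out["n_species"] = g["species"].nunique()
    out["n_records"] = g.size()
    out = out.reset_index()

    if soil is not None:
        orphans = set(soil["site_id"]) - set(out["site_id"])
        if orphans:
            log.warning("%d soil rows without trait data (ignored)", len(orphans))
        out = out.merge(soil, on="site_id", how="left")
    return out
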