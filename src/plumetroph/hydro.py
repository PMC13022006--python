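"""Station-level hydrographic and nutrient habitat features.

Derives the environmental predictors used to explain the dominant trophic
mode: Brunt–Väisälä buoyancy frequency N² and the mixed-layer depth (depth
of its primary maximum), nutricline depths by linear interpolation
(nitracline 1 µM, phosphocline 0.1 µM, silicacline 2 µM), the nitrate
availability index (NAI), oxygen solubility at saturation, plume thickness
from the halocline, and surface scalars.

CTD casts are plain DataFrames with columns ``depth`` (m, positive down,
strictly increasing), ``temperature`` (°C), ``salinity`` (practical),
optionally ``sigma_theta`` (kg m⁻³), ``oxygen`` (mM) and ``fluorescence``.
Nutrient casts carry ``depth``, ``nox`` (NO₃+NO₂, µM), ``po4``, ``si``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

G = 9.81  # m s-2
RHO0 = 1025.0  # kg m-3 reference density

#: Published cline thresholds (µM).
NITRACLINE_UM = 1.0
PHOSPHOCLINE_UM = 0.1
SILICACLINE_UM = 2.0


def sigma_theta(temperature, salinity):
    """Potential density anomaly σθ (kg m⁻³) at surface reference pressure.

    One-atmosphere seawater density polynomial (EOS-80 / Millero–Poisson);
    in-situ temperature stands in for potential temperature, adequate for
    the near-surface casts this package targets.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    rho = rho_w + a * s + b * s**1.5 + c * s**2
    out = rho - 1000.0
    return float(out) if out.ndim == 0 else out


def _cast_sigma(profile: pd.DataFrame) -> np.ndarray:
    if "sigma_theta" in profile.columns and profile["sigma_theta"].notna().all():
        return profile["sigma_theta"].to_numpy(float)
    return sigma_theta(profile["temperature"], profile["salinity"])


def buoyancy_frequency(profile: pd.DataFrame) -> pd.DataFrame:
    """N²(z) = (g/ρ₀)·dσθ/dz on the midpoints between cast levels.

    Returns a DataFrame with ``depth`` (midpoints, m) and ``n2`` (s⁻²);
    positive where density increases downward.  Requires ≥ 3 levels.
    """
    z = profile["depth"].to_numpy(float)
    if len(z) < 3:
        raise ValueError("buoyancy frequency needs at least 3 cast levels")
    if not np.all(np.diff(z) > 0):
        raise ValueError("depth must be strictly increasing")
    sig = _cast_sigma(profile)
    n2 = (G / RHO0) * np.diff(sig) / np.diff(z)
    return pd.DataFrame({"depth": 0.5 * (z[:-1] + z[1:]), "n2": n2})


def mixed_layer_depth(
    n2: pd.DataFrame | np.ndarray,
    depths: np.ndarray | None = None,
    method: str = "global",
) -> float:
    """Depth (m) of the primary N² maximum — the mixed-layer base.

    ``method='global'`` takes the global maximum (shallowest within 1e-12 on
    ties); ``'first_local'`` the shallowest local maximum.  All-zero (or
    non-positive) N² yields NaN.
    """
    if isinstance(n2, pd.DataFrame):
        depths = n2["depth"].to_numpy(float)
        vals = n2["n2"].to_numpy(float)
    else:
        vals = np.asarray(n2, dtype=float)
        depths = np.asarray(depths, dtype=float)
    if not np.any(vals > 0):
        return math.nan
    if method == "first_local":
        for i in range(len(vals)):
            left = vals[i - 1] if i > 0 else -math.inf
            right = vals[i + 1] if i < len(vals) - 1 else -math.inf
            if vals[i] > 0 and vals[i] >= left and vals[i] >= right:
                return float(depths[i])
    if method not in ("global", "first_local"):
        raise ValueError("method must be 'global' or 'first_local'")
    vmax = vals.max()
    idx = np.nonzero(vals >= vmax - 1e-12)[0][0]
    return float(depths[idx])


def _first_crossing(depth: np.ndarray, value: np.ndarray, threshold: float,
                    rising: bool) -> float:
    """Interpolated depth of the first downward crossing of ``threshold``.

    ``rising=True`` looks for value increasing past the threshold with
    depth (nutriclines, haloclines); NaN when never crossed.
    """
    v = value if rising else -np.asarray(value, dtype=float)
    thr = threshold if rising else -threshold
    for i in range(1, len(depth)):
        if v[i] >= thr:
            v0, v1 = v[i - 1], v[i]
            if v1 == v0:
                return float(depth[i])
            frac = (thr - v0) / (v1 - v0)
            return float(depth[i - 1] + frac * (depth[i] - depth[i - 1]))
    return math.nan


def cline_depth(depth, conc, threshold: float) -> float:
    """Depth (m) where a nutrient first reaches ``threshold`` (µM).

    Zero when the surface concentration already meets the threshold;
    otherwise the linearly interpolated depth of the first downward
    crossing; NaN when the threshold is never reached.  Missing levels are
    dropped.
    """
    z = np.asarray(depth, dtype=float)
    c = np.asarray(conc, dtype=float)
    ok = np.isfinite(z) & np.isfinite(c)
    z, c = z[ok], c[ok]
    if len(z) == 0:
        return math.nan
    if c[0] >= threshold:
        return 0.0
    return _first_crossing(z, c, threshold, rising=True)


def nai(nutrients: pd.DataFrame, bottom_depth: float | None = None) -> float:
    """Nitrate availability index.

    Piecewise: the surface NO₃+NO₂ concentration (µM) when ≥ 0.5 µM;
    otherwise minus the (interpolated) depth where NOₓ reaches 2 µM;
    otherwise minus the bottom depth of the cast.  The sign thus separates
    nitrate-replete surface waters (positive, µM) from stratified ones
    (negative, metres to nitrate).
    """
    z = nutrients["depth"].to_numpy(float)
    c = nutrients["nox"].to_numpy(float)
    ok = np.isfinite(z) & np.isfinite(c)
    z, c = z[ok], c[ok]
    if len(z) == 0:
        return math.nan
    surface = c[0]
    if surface >= 0.5:
        return float(surface)
    z2 = _first_crossing(z, c, 2.0, rising=True)
    if not math.isnan(z2):
        return -z2
    if bottom_depth is None:
        bottom_depth = (
            float(nutrients["bottom_depth"].iloc[0])
            if "bottom_depth" in nutrients.columns
            else float(z[-1])
        )
    return -float(bottom_depth)


# Oxygen solubility at one atmosphere (Garcia & Gordon combined fit to the
# Benson & Krause data), µmol kg-1.
_O2_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_O2_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_O2_C0 = -2.75915e-7


def o2_saturation(temperature: float, salinity: float) -> float:
    """O₂ solubility at atmospheric equilibrium (mM) from T (°C) and S.

    Garcia–Gordon combined-fit polynomial in the scaled temperature
    Ts = ln[(298.15 − T)/(273.15 + T)], evaluated in µmol kg⁻¹ and
    converted to mM with the local surface density.
    """
    t = float(temperature)
    s = float(salinity)
    if not (-2.0 <= t <= 40.0 and 0.0 <= s <= 42.0):
        warnings.warn(
            f"T={t}, S={s} outside the solubility fit range", stacklevel=2
        )
    ts = math.log((298.15 - t) / (273.15 + t))
    ln_c = sum(a * ts**i for i, a in enumerate(_O2_A))
    ln_c += s * sum(b * ts**i for i, b in enumerate(_O2_B))
    ln_c += _O2_C0 * s**2
    umol_kg = math.exp(ln_c)
    rho = 1000.0 + sigma_theta(t, s)  # kg m-3
    return umol_kg * rho / 1e6  # µmol/kg * kg/m3 = µmol/m3; /1e6 -> mmol/L


def plume_thickness(profile: pd.DataFrame, threshold_salinity: float = 35.0) -> float:
    """Thickness (m) of the low-salinity surface plume.

    Interpolated depth where salinity first reaches ``threshold_salinity``;
    NaN when the surface is already at/above the threshold (no plume); the
    bottom depth of the cast when the whole cast stays fresher.
    """
    z = profile["depth"].to_numpy(float)
    s = profile["salinity"].to_numpy(float)
    ok = np.isfinite(z) & np.isfinite(s)
    z, s = z[ok], s[ok]
    if len(z) == 0:
        return math.nan
    if s[0] >= threshold_salinity:
        return math.nan
    zc = _first_crossing(z, s, threshold_salinity, rising=True)
    if math.isnan(zc):
        return float(z[-1])
    return zc


def station_features(
    ctd: pd.DataFrame,
    nutrients: pd.DataFrame | None = None,
    surface_chla: float | None = None,
    mld_method: str = "global",
) -> pd.Series:
    """Assemble the per-station predictor vector.

    Missing inputs (no nutrient cast, no oxygen sensor…) leave the
    corresponding features as NaN; downstream consumers must tolerate
    missing values.
    """
    feats: dict[str, float] = {}
    bv = buoyancy_frequency(ctd)
    n2_vals = bv["n2"].to_numpy(float)
    if np.any(n2_vals > 0):
        imax = int(np.nanargmax(n2_vals))
        feats["n2_max"] = float(n2_vals[imax])
        feats["n2_max_depth"] = float(bv["depth"].iloc[imax])
    else:
        feats["n2_max"] = math.nan
        feats["n2_max_depth"] = math.nan
    feats["mld"] = mixed_layer_depth(bv, method=mld_method)
    feats["plume_thickness"] = plume_thickness(ctd)
    feats["surface_temperature"] = float(ctd["temperature"].iloc[0])
    feats["surface_salinity"] = float(ctd["salinity"].iloc[0])
    if "oxygen" in ctd.columns and np.isfinite(ctd["oxygen"].iloc[0]):
        feats["surface_oxygen"] = float(ctd["oxygen"].iloc[0])
    else:
        feats["surface_oxygen"] = math.nan
    feats["o2_saturation"] = o2_saturation(
        feats["surface_temperature"], feats["surface_salinity"]
    )
    if "fluorescence" in ctd.columns and ctd["fluorescence"].notna().any():
        fl = ctd["fluorescence"].to_numpy(float)
        feats["dcm_depth"] = float(ctd["depth"].iloc[int(np.nanargmax(fl))])
    else:
        feats["dcm_depth"] = math.nan
    feats["surface_chla"] = math.nan if surface_chla is None else float(surface_chla)

    if nutrients is not None and len(nutrients) > 0:
        z = nutrients["depth"]
        feats["nitracline"] = cline_depth(z, nutrients["nox"], NITRACLINE_UM)
        feats["phosphocline"] = (
            cline_depth(z, nutrients["po4"], PHOSPHOCLINE_UM)
            if "po4" in nutrients.columns
            else math.nan
        )
        feats["silicacline"] = (
            cline_depth(z, nutrients["si"], SILICACLINE_UM)
            if "si" in nutrients.columns
            else math.nan
        )
        feats["nai"] = nai(nutrients)
        surf = nutrients.iloc[0]
        nox0 = float(surf["nox"]) if np.isfinite(surf.get("nox", math.nan)) else math.nan
        for name, col in (("no3_po4", "po4"), ("no3_si", "si"), ("no3_no2", "no2")):
            denom = float(surf[col]) if col in nutrients.columns and np.isfinite(surf.get(col, math.nan)) else math.nan
            feats[name] = nox0 / denom if denom and denom > 0 else math.nan
    else:
        for name in ("nitracline", "phosphocline", "silicacline", "nai",
                     "no3_po4", "no3_si", "no3_no2"):
            feats[name] = math.nan
    return pd.Series(feats)
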