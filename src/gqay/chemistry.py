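"""Forage nutritive-value estimation from raw laboratory measurements.

Implements the standard in-vitro gas-test estimation equations for
metabolizable energy (ME) and net energy for lactation (NEL), the Kjeldahl
crude-protein factor, the ammonia-balance equation for utilizable crude
protein (uCP), organic matter as dry matter minus ash, and the NEL-based
milk production potential.  All contents are per kg dry matter.

ME (MJ kg^-1) = 3.16 + 0.0695 g + 0.000730 g^2 + 0.00732 CP + 0.02052 EE
NEL (MJ kg^-1) = 1.64 + 0.0269 g + 0.00078 g^2 + 0.0051 CP + 0.01325 EE

with g the 24 h fermentation gas production (mL day^-1), CP crude protein
and EE ether extract (both g kg^-1 DM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RawChemistry",
    "QualityProfile",
    "crude_protein",
    "metabolizable_energy",
    "net_energy_lactation",
    "milk_production_potential",
    "utilizable_crude_protein",
    "organic_matter",
    "quality_profile",
    "add_quality_columns",
    "QUALITY_VARIABLES",
    "DEFAULT_NEL_PER_KG_MILK",
]

#: NEL requirement per kg of milk (MJ NEL per kg). The energy system behind
#: the printed yield magnitudes does not publish this constant alongside the
#: equations; 3.2 MJ kg^-1 is a standard feed-evaluation value and is
#: consistent with an ME yield of ~9.6 MJ m^-2 corresponding to a milk
#: potential yield of ~1.8 kg m^-2.  Treat as a calibration constant.
DEFAULT_NEL_PER_KG_MILK = 3.2

ME_COEF = (3.16, 0.0695, 0.000730, 0.00732, 0.02052)
NEL_COEF = (1.64, 0.0269, 0.00078, 0.0051, 0.01325)

#: quality variables carried through annual aggregation
QUALITY_VARIABLES = ("me", "nel", "milk_potential", "cp", "ucp", "om", "ndf")


def _check_nonneg(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def crude_protein(n_content):
    """Crude protein (g kg^-1) from nitrogen content (g N kg^-1): 6.25 x N."""
    _check_nonneg(n_content=n_content)
    return 6.25 * np.asarray(n_content, dtype=float)[()]


def _energy(coef, gas, cp, ee):
    gas = np.asarray(gas, dtype=float)
    cp = np.asarray(cp, dtype=float)
    ee = np.asarray(ee, dtype=float)
    a, b1, b2, b3, b4 = coef
    return (a + b1 * gas + b2 * gas**2 + b3 * cp + b4 * ee)[()]


def metabolizable_energy(gas, cp, ee):
    """Metabolizable energy (MJ kg^-1 DM) from gas production, CP and EE."""
    _check_nonneg(gas=gas, cp=cp, ee=ee)
    return _energy(ME_COEF, gas, cp, ee)


def net_energy_lactation(gas, cp, ee):
    """Net energy for lactation (MJ kg^-1 DM) from gas production, CP and EE."""
    _check_nonneg(gas=gas, cp=cp, ee=ee)
    return _energy(NEL_COEF, gas, cp, ee)


def milk_production_potential(nel, nel_per_kg_milk: float = DEFAULT_NEL_PER_KG_MILK):
    """Milk production potential (kg milk per kg DM) = NEL / (MJ NEL per kg milk)."""
    _check_nonneg(nel=nel)
    if nel_per_kg_milk <= 0:
        raise ValueError("nel_per_kg_milk must be > 0")
    return (np.asarray(nel, dtype=float) / nel_per_kg_milk)[()]


def utilizable_crude_protein(nh3_n_blank, n_sample, nh3_n_sample, dm_mg):
    """Utilizable crude protein (g kg^-1 DM) from the incubation ammonia balance.

    uCP = (NH3-N_blank + N_sample - NH3-N_sample) / DM(mg) x 6.25 x 1000.

    A negative result is physically impossible and indicates a measurement
    error; it is returned as computed but flagged with a warning so that
    table validation can report it, rather than being silently clipped.
    """
    dm = np.asarray(dm_mg, dtype=float)
    if np.any(dm <= 0):
        raise ValueError("dm_mg must be > 0")
    num = (
        np.asarray(nh3_n_blank, dtype=float)
        + np.asarray(n_sample, dtype=float)
        - np.asarray(nh3_n_sample, dtype=float)
    )
    ucp = (num / dm * 6.25 * 1000.0)[()]
    if np.any(np.asarray(ucp) < 0):
        warnings.warn(
            "negative utilizable crude protein: ammonia balance exceeds blank + "
            "sample N (measurement error); value reported unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return ucp


def organic_matter(ash):
    """Organic matter (g kg^-1 DM) = 1000 - total ash (g kg^-1 DM)."""
    ash_arr = np.asarray(ash, dtype=float)
    if np.any(ash_arr < 0) or np.any(ash_arr > 1000):
        raise ValueError("ash must lie in [0, 1000] g kg^-1")
    return (1000.0 - ash_arr)[()]


@dataclass(frozen=True)
class RawChemistry:
    """Raw per-cut laboratory measurements for one sample.

    gas: fermentation gas, mL day^-1; cp/ee/ndf/ash: g kg^-1 DM.  The
    incubation fields (mg) are optional and only needed for uCP.
    """

    gas: float
    cp: float
    ee: float
    ndf: float
    ash: float
    nh3_n_blank: float | None = None
    nh3_n_sample: float | None = None
    n_sample: float | None = None
    dm_mg: float | None = None

    def has_ucp_inputs(self) -> bool:
        return not any(
            v is None or (isinstance(v, float) and np.isnan(v))
            for v in (self.nh3_n_blank, self.nh3_n_sample, self.n_sample, self.dm_mg)
        )


@dataclass(frozen=True)
class QualityProfile:
    """Derived nutritive values per kg DM for one cut."""

    me: float
    nel: float
    milk_potential: float
    cp: float
    om: float
    ndf: float
    ucp: float | None = None


def quality_profile(raw: RawChemistry,
                    nel_per_kg_milk: float = DEFAULT_NEL_PER_KG_MILK) -> QualityProfile:
    """Full nutritive-value profile for one raw-chemistry record.

    uCP is populated only when all four incubation inputs are present.
    """
    nel = net_energy_lactation(raw.gas, raw.cp, raw.ee)
    return QualityProfile(
        me=metabolizable_energy(raw.gas, raw.cp, raw.ee),
        nel=nel,
        milk_potential=milk_production_potential(nel, nel_per_kg_milk),
        cp=float(raw.cp),
        om=organic_matter(raw.ash),
        ndf=float(raw.ndf),
        ucp=(
            utilizable_crude_protein(
                raw.nh3_n_blank, raw.n_sample, raw.nh3_n_sample, raw.dm_mg
            )
            if raw.has_ucp_inputs()
            else None
        ),
    )


def add_quality_columns(cuts: pd.DataFrame,
                        nel_per_kg_milk: float = DEFAULT_NEL_PER_KG_MILK) -> pd.DataFrame:
    """Append derived quality columns (me, nel, milk_potential, om, ucp) to a cut table.

    Expects the raw-chemistry columns gas, cp, ee, ndf, ash and, where uCP
    is to be computed (normally the first cut only), nh3_n_blank, n_sample,
    nh3_n_sample and dm_mg.  Rows with missing incubation inputs get NaN uCP.
    """
    out = cuts.copy()
    out["me"] = metabolizable_energy(out["gas"], out["cp"], out["ee"])
    out["nel"] = net_energy_lactation(out["gas"], out["cp"], out["ee"])
    out["milk_potential"] = milk_production_potential(out["nel"], nel_per_kg_milk)
    out["om"] = organic_matter(out["ash"])
    ucp = np.full(len(out), np.nan)
    have = (
        out[["nh3_n_blank", "n_sample", "nh3_n_sample", "dm_mg"]].notna().all(axis=1)
        if {"nh3_n_blank", "n_sample", "nh3_n_sample", "dm_mg"} <= set(out.columns)
        else pd.Series(False, index=out.index)
    )
    if have.any():
        sub = out.loc[have]
        ucp_vals = utilizable_crude_protein(
            sub["nh3_n_blank"].to_numpy(),
            sub["n_sample"].to_numpy(),
            sub["nh3_n_sample"].to_numpy(),
            sub["dm_mg"].to_numpy(),
        )
        ucp[np.flatnonzero(have.to_numpy())] = ucp_vals
    out["ucp"] = ucp
    return out
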