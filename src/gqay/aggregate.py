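"""Annual aggregation: sward filtering, within-year quality interpolation,
and biomass-weighted quality-adjusted yields.

For each sward and year the three annual quantities are

    biomass_yield = sum_cut biomass_cut                       (g DM m^-2 a^-1)
    quality       = sum_cut quality_cut * biomass_cut / biomass_yield
    qa_yield      = sum_cut biomass_cut * quality_cut / 1000

per quality variable, the division by 1000 converting the per-kg-DM quality
basis to the g-DM biomass basis so that, e.g., metabolizable-energy yield
comes out in MJ m^-2 a^-1.  Chemistry is measured at the first and last cut
of the year; interior cuts of four-cut regimes get linearly interpolated
quality, which is justified by the monotone within-year quality trends.
Utilizable crude protein is measured at the first cut only: its annual
"quality" is the first-cut value and its yield uses first-cut biomass only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chemistry import QUALITY_VARIABLES

__all__ = ["interpolate_quality", "filter_swards", "aggregate_annual", "DEFAULT_MIN_BIOMASS"]

#: threshold below which a cut's biomass counts as "very small" (g DM m^-2)
DEFAULT_MIN_BIOMASS = 1.0

#: variables aggregated over all cuts (uCP is handled separately, first cut only)
_INTERP_VARS = tuple(v for v in QUALITY_VARIABLES if v != "ucp")

#: plot/design columns carried through to the annual table
_DESIGN_COLS = (
    "plot_id", "block", "management", "cuts_per_year", "n_fert", "richness",
    "n_functional_groups", "legume_present", "legume_share", "grass_present",
    "tall_herb_present",
)


def interpolate_quality(q_first, q_last, h: int) -> np.ndarray:
    """Per-cut quality series by linear interpolation between first and last cut.

    Cut c (1-based) receives q_first + (q_last - q_first) * (c - 1) / (h - 1);
    a single-cut year returns just the first-cut value.  Works elementwise on
    scalars or arrays of quality values (returns shape (h,) + shape(q)).
    """
    if h < 1:
        raise ValueError(f"cut count must be >= 1, got {h}")
    q_first = np.asarray(q_first, dtype=float)
    if h == 1:
        return q_first[np.newaxis, ...]
    q_last = np.asarray(q_last, dtype=float)
    frac = np.arange(h, dtype=float) / (h - 1)
    frac = frac.reshape((h,) + (1,) * q_first.ndim)
    return q_first + (q_last - q_first) * frac


def filter_swards(cuts: pd.DataFrame,
                  min_biomass: float = DEFAULT_MIN_BIOMASS
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop swards with any missing cut or any cut below ``min_biomass``.

    A sward is excluded when (a) a cut's biomass is missing or an expected
    cut row is absent entirely, or (b) any cut's biomass falls below the
    threshold.  Returns the retained cut table and a dropped-sward report
    with one row per dropped sward (sward_id, richness, management, reason);
    the report's per-richness histogram makes the filtering auditable.
    """
    if min_biomass < 0:
        raise ValueError("min_biomass must be >= 0")
    dropped: list[dict] = []
    keep_ids = []
    for sward_id, grp in cuts.groupby("sward_id", sort=False):
        h = int(grp["cuts_per_year"].iloc[0])
        info = {
            "sward_id": sward_id,
            "richness": int(grp["richness"].iloc[0]),
            "management": grp["management"].iloc[0],
        }
        if grp["biomass"].isna().any() or len(grp) < h:
            dropped.append({**info, "reason": "missing"})
        elif (grp["biomass"] < min_biomass).any():
            dropped.append({**info, "reason": "small_biomass"})
        else:
            keep_ids.append(sward_id)
    kept = cuts[cuts["sward_id"].isin(keep_ids)].copy()
    report = pd.DataFrame(dropped, columns=["sward_id", "richness", "management", "reason"])
    return kept, report


def dropped_richness_histogram(report: pd.DataFrame) -> pd.Series:
    """Dropped-sward counts per richness level (for comparison with field data)."""
    return report.groupby("richness").size()


def aggregate_annual(cuts: pd.DataFrame, interpolate: bool = True) -> pd.DataFrame:
    """Annual biomass yield, weighted quality and quality-adjusted yield per sward.

    ``cuts`` must already carry the derived quality columns and have passed
    the sward filter.  With ``interpolate=True`` (the measurement protocol),
    interior-cut quality is replaced by the linear interpolation between the
    first and last cut; with False, per-cut quality is used as given.

    Output: one row per sward with biomass_yield, quality_<v>, qa_<v> for
    each quality variable, plus ucp columns from the first cut only and the
    design covariates needed by the diversity model.
    """
    records: list[dict] = []
    for sward_id, grp in cuts.groupby("sward_id", sort=False):
        grp = grp.sort_values("cut")
        h = int(grp["cuts_per_year"].iloc[0])
        if len(grp) != h or grp["biomass"].isna().any():
            raise RuntimeError(
                f"sward {sward_id!r} reached aggregation with missing cuts; "
                "apply filter_swards first"
            )
        biomass = grp["biomass"].to_numpy(dtype=float)
        total = float(biomass.sum())
        if total <= 0:
            raise RuntimeError(
                f"sward {sward_id!r} has zero annual biomass; "
                "it should have been filtered out"
            )
        rec = {"sward_id": sward_id, "n_cuts_used": h, "biomass_yield": total}
        for col in _DESIGN_COLS:
            if col in grp.columns:
                rec[col] = grp[col].iloc[0]
        for var in _INTERP_VARS:
            q = grp[var].to_numpy(dtype=float)
            if interpolate:
                q = interpolate_quality(q[0], q[-1], h)
            qa = float(np.sum(biomass * q)) / 1000.0
            rec[f"quality_{var}"] = qa * 1000.0 / total
            rec[f"qa_{var}"] = qa
        # uCP: first cut only (both content and yield), by measurement design
        ucp1 = float(grp["ucp"].iloc[0]) if "ucp" in grp.columns else np.nan
        rec["quality_ucp"] = ucp1
        rec["qa_ucp"] = biomass[0] * ucp1 / 1000.0
        rec["ucp_first_cut_only"] = True
        records.append(rec)
    return pd.DataFrame(records)
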