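"""Design and simulation of a blocked grassland diversity x management experiment.

The design mirrors a replacement-series biodiversity experiment: a fixed
species pool split into four functional groups (grasses, small herbs, tall
herbs, legumes), 82 main plots arranged in 4 blocks covering sown richness
levels 1, 2, 4, 8, 16 and 60, and five management regimes (cutting frequency
x N fertilization) applied as subplots, giving one sward per plot x regime.

The simulator draws per-cut biomass and raw forage chemistry with the
statistical structure the downstream mixed model assumes: per-management
intercepts and square-root diversity slopes, legume/functional-group terms,
block and plot random intercepts, and independent per-cut residuals.  Forage
chemistry follows monotone within-year trends (energy-related variables
decline from the first to the last cut, fiber and ash increase).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesPool",
    "PlotDesign",
    "ManagementRegime",
    "Sward",
    "SimulationParams",
    "REGIMES",
    "MANAGEMENT_NAMES",
    "RICHNESS_REPLICATES",
    "N_BLOCKS",
    "build_design",
    "build_swards",
    "simulate_cuts",
    "design_table",
]


class ConfigurationError(ValueError):
    """Raised when a design or simulation configuration is invalid."""


# richness level -> number of replicate plots
RICHNESS_REPLICATES: dict[int, int] = {1: 16, 2: 16, 4: 16, 8: 16, 16: 14, 60: 4}
N_BLOCKS = 4

FUNCTIONAL_GROUPS = ("grass", "small_herb", "tall_herb", "legume")


@dataclass(frozen=True)
class SpeciesPool:
    """Functional-group composition of the sown species pool."""

    n_grasses: int = 16
    n_small_herbs: int = 12
    n_tall_herbs: int = 20
    n_legumes: int = 12

    @property
    def total(self) -> int:
        return self.n_grasses + self.n_small_herbs + self.n_tall_herbs + self.n_legumes

    def validate(self, max_richness: int) -> None:
        counts = (self.n_grasses, self.n_small_herbs, self.n_tall_herbs, self.n_legumes)
        if any(c < 0 for c in counts):
            raise ConfigurationError(f"negative group count in species pool: {counts}")
        if self.total < max_richness:
            raise ConfigurationError(
                f"species pool holds {self.total} species but the design requires "
                f"mixtures of {max_richness}"
            )

    def group_labels(self) -> np.ndarray:
        """One functional-group label per species in the pool."""
        return np.repeat(
            np.array(FUNCTIONAL_GROUPS, dtype=object),
            [self.n_grasses, self.n_small_herbs, self.n_tall_herbs, self.n_legumes],
        )


@dataclass(frozen=True)
class PlotDesign:
    """One main plot: block membership and sown community composition."""

    plot_id: str
    block: int
    richness: int
    n_functional_groups: int
    legume_present: bool
    legume_share: float
    grass_present: bool
    small_herb_present: bool
    tall_herb_present: bool

    def __post_init__(self) -> None:
        if (self.legume_share > 0) != self.legume_present:
            raise ConfigurationError(
                f"{self.plot_id}: legume_share={self.legume_share} inconsistent "
                f"with legume_present={self.legume_present}"
            )
        if not 0.0 <= self.legume_share <= 1.0:
            raise ConfigurationError(f"{self.plot_id}: legume_share out of [0, 1]")
        n_present = sum(
            (self.grass_present, self.small_herb_present,
             self.tall_herb_present, self.legume_present)
        )
        if self.n_functional_groups != n_present:
            raise ConfigurationError(
                f"{self.plot_id}: n_functional_groups={self.n_functional_groups} "
                f"but {n_present} groups flagged present"
            )


# regime name -> (cuts per year, N fertilization kg N / ha / a)
REGIMES: dict[str, tuple[int, int]] = {
    "extensive": (1, 0),
    "less_intensive": (2, 0),
    "intensive": (2, 100),
    "highly_intensive": (4, 100),
    "very_highly_intensive": (4, 200),
}
MANAGEMENT_NAMES = tuple(REGIMES)


@dataclass(frozen=True)
class ManagementRegime:
    """A management intensity: cutting frequency and N fertilization level."""

    name: str
    cuts_per_year: int
    n_fert: int

    def __post_init__(self) -> None:
        expected = REGIMES.get(self.name)
        if expected is None:
            raise ConfigurationError(
                f"unknown management regime {self.name!r}; "
                f"expected one of {sorted(REGIMES)}"
            )
        if (self.cuts_per_year, self.n_fert) != expected:
            raise ConfigurationError(
                f"regime {self.name!r} must have (cuts, N) = {expected}, "
                f"got {(self.cuts_per_year, self.n_fert)}"
            )

    @classmethod
    def by_name(cls, name: str) -> "ManagementRegime":
        cuts, n = REGIMES[name]
        return cls(name, cuts, n)


def all_regimes() -> list[ManagementRegime]:
    return [ManagementRegime.by_name(n) for n in MANAGEMENT_NAMES]


@dataclass(frozen=True)
class Sward:
    """One plot x management unit, the observational unit of the experiment."""

    sward_id: str
    plot: PlotDesign
    regime: ManagementRegime


def _as_management_map(value, default: float) -> dict[str, float]:
    if value is None:
        return {m: default for m in MANAGEMENT_NAMES}
    if isinstance(value, (int, float)):
        return {m: float(value) for m in MANAGEMENT_NAMES}
    missing = set(MANAGEMENT_NAMES) - set(value)
    if missing:
        raise ConfigurationError(f"per-management parameter missing entries: {sorted(missing)}")
    return {m: float(value[m]) for m in MANAGEMENT_NAMES}


# chemistry variables simulated on the measured scale (per cut)
CHEM_VARS = ("gas", "cp", "ee", "ndf", "ash")


@dataclass
class SimulationParams:
    """Data-generating parameters for the synthetic experiment.

    Biomass follows the annual-sum structure of the diversity mixed model:
    for a sward with richness D under management M the annual expectation is

        alpha_M + beta_M * sqrt(D) + legume_M * L + fg * FG + grass * G + herb * H
        + block effect + plot effect,

    and each of the h cuts receives mean/h plus an independent residual of
    standard deviation ``sigma_resid`` (so annual residual variance scales
    with cutting frequency, i.e., the residuals are heteroscedastic across
    management regimes).

    Chemistry is drawn per sward as baseline + sward-level noise, then moved
    along a deterministic per-cut trend, which keeps within-year quality
    trends strictly monotone for every sward.  Trend signs are constrained:
    fermentation gas and crude protein may only decline across cuts, NDF and
    ash may only increase.

    Units: biomass in g DM m^-2 a^-1 (annual scale), gas in mL day^-1, CP /
    EE / NDF / ash in g kg^-1 DM, ammonia/N inputs in mg per incubation.
    """

    intercept: dict[str, float] = field(default_factory=lambda: _as_management_map(
        {"extensive": 250.0, "less_intensive": 300.0, "intensive": 350.0,
         "highly_intensive": 380.0, "very_highly_intensive": 420.0}, 0.0))
    sqrt_slope: dict[str, float] = field(default_factory=lambda: _as_management_map(
        {"extensive": 60.0, "less_intensive": 80.0, "intensive": 110.0,
         "highly_intensive": 100.0, "very_highly_intensive": 110.0}, 0.0))
    legume_effect: dict[str, float] = field(default_factory=lambda: _as_management_map(
        {"extensive": 40.0, "less_intensive": 50.0, "intensive": 60.0,
         "highly_intensive": 60.0, "very_highly_intensive": 70.0}, 0.0))
    fg_effect: float = 10.0
    grass_effect: float = 30.0
    tall_herb_effect: float = 10.0

    sigma_block: float = 30.0
    sigma_plot: float = 50.0
    sigma_resid: float = 60.0

    # first-cut chemistry baselines and per-cut trends (per cut index step)
    chem_baseline: dict[str, float] = field(default_factory=lambda: {
        "gas": 45.0, "cp": 160.0, "ee": 25.0, "ndf": 450.0, "ash": 90.0})
    chem_trend: dict[str, float] = field(default_factory=lambda: {
        "gas": -3.0, "cp": -10.0, "ee": 0.0, "ndf": 20.0, "ash": 5.0})
    chem_sigma: dict[str, float] = field(default_factory=lambda: {
        "gas": 2.0, "cp": 10.0, "ee": 3.0, "ndf": 25.0, "ash": 8.0})

    # first-cut incubation inputs for utilizable crude protein
    dm_mg: float = 200.0
    nh3_n_blank: float = 2.0
    ucp_target: float = 140.0
    ucp_sigma: float = 10.0

    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma_block", "sigma_plot", "sigma_resid", "ucp_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for v in CHEM_VARS:
            if v not in self.chem_baseline or v not in self.chem_trend or v not in self.chem_sigma:
                raise ConfigurationError(f"chemistry parameter missing for variable {v!r}")
            if self.chem_sigma[v] < 0:
                raise ConfigurationError(f"chem_sigma[{v!r}] must be >= 0")
        for v in ("gas", "cp"):
            if self.chem_trend[v] > 0:
                raise ConfigurationError(f"chem_trend[{v!r}] must be <= 0 (quality declines across cuts)")
        for v in ("ndf", "ash"):
            if self.chem_trend[v] < 0:
                raise ConfigurationError(f"chem_trend[{v!r}] must be >= 0 (fiber/ash rise across cuts)")
        if self.dm_mg <= 0:
            raise ConfigurationError("dm_mg must be > 0")
        self.intercept = _as_management_map(self.intercept, 0.0)
        self.sqrt_slope = _as_management_map(self.sqrt_slope, 0.0)
        self.legume_effect = _as_management_map(self.legume_effect, 0.0)

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))


def build_design(pool: SpeciesPool | None = None, seed: int = 0,
                 replicates: dict[int, int] | None = None) -> list[PlotDesign]:
    """Draw the plot-level design: 82 plots in 4 blocks across richness levels.

    Community composition of each plot is a uniform draw of ``richness``
    distinct species from the pool (selection is "with replacement" across
    plots: the same species can serve in many mixtures).  Functional-group
    presence flags, functional-group number and legume share follow from the
    drawn composition.  Plots are dealt into blocks so block sizes differ by
    at most one.
    """
    pool = pool or SpeciesPool()
    replicates = dict(replicates or RICHNESS_REPLICATES)
    if not replicates or any(r < 1 for r in replicates.values()):
        raise ConfigurationError(f"invalid replicate counts: {replicates}")
    pool.validate(max(replicates))

    rng = np.random.default_rng(seed)
    labels = pool.group_labels()
    n_species = pool.total

    plots: list[PlotDesign] = []
    pid = 0
    for richness in sorted(replicates):
        for _ in range(replicates[richness]):
            chosen = rng.choice(n_species, size=richness, replace=False)
            groups = labels[chosen]
            n_leg = int(np.sum(groups == "legume"))
            plots.append(
                PlotDesign(
                    plot_id=f"plot{pid:03d}",
                    block=0,  # assigned below
                    richness=richness,
                    n_functional_groups=int(len(np.unique(groups))),
                    legume_present=n_leg > 0,
                    legume_share=n_leg / richness,
                    grass_present=bool(np.any(groups == "grass")),
                    small_herb_present=bool(np.any(groups == "small_herb")),
                    tall_herb_present=bool(np.any(groups == "tall_herb")),
                )
            )
            pid += 1

    # balanced block assignment: shuffle, then deal round-robin
    order = rng.permutation(len(plots))
    blocks = np.empty(len(plots), dtype=int)
    blocks[order] = np.arange(len(plots)) % N_BLOCKS + 1
    plots = [replace(p, block=int(b)) for p, b in zip(plots, blocks)]
    return plots


def build_swards(plots: list[PlotDesign],
                 regimes: list[ManagementRegime] | None = None) -> list[Sward]:
    """One sward per plot x management regime (82 plots -> 410 swards).

    The field layout placed four management subplots inside each main plot
    and used the plot core for the fifth (less intensive two-cut, zero-N)
    regime; positions within the plot are not modelled, so allocation
    reduces to the cross product.
    """
    regimes = regimes or all_regimes()
    return [
        Sward(sward_id=f"{p.plot_id}-{r.name}", plot=p, regime=r)
        for p in plots
        for r in regimes
    ]


def design_table(plots: list[PlotDesign]) -> pd.DataFrame:
    """Tidy one-row-per-plot design table."""
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "block": [p.block for p in plots],
            "richness": [p.richness for p in plots],
            "n_functional_groups": [p.n_functional_groups for p in plots],
            "legume_present": [int(p.legume_present) for p in plots],
            "legume_share": [p.legume_share for p in plots],
            "grass_present": [int(p.grass_present) for p in plots],
            "small_herb_present": [int(p.small_herb_present) for p in plots],
            "tall_herb_present": [int(p.tall_herb_present) for p in plots],
        }
    )


def _annual_mean(sward: Sward, params: SimulationParams) -> float:
    p, m = sward.plot, sward.regime.name
    return (
        params.intercept[m]
        + params.sqrt_slope[m] * np.sqrt(p.richness)
        + params.legume_effect[m] * p.legume_present
        + params.fg_effect * p.n_functional_groups
        + params.grass_effect * p.grass_present
        + params.tall_herb_effect * p.tall_herb_present
    )


def simulate_cuts(swards: list[Sward], params: SimulationParams) -> pd.DataFrame:
    """Simulate the tidy per-cut table (one row per sward x cut).

    Each sward contributes ``cuts_per_year`` rows.  Per-cut biomass is the
    annual expectation (including block and plot random intercepts) divided
    by the number of cuts, plus an independent N(0, sigma_resid^2) residual,
    truncated at zero (a warning is logged when truncation occurs).
    Chemistry variables share a sward-level random offset and move along the
    configured per-cut trends; incubation inputs for utilizable crude
    protein are generated for the first cut only.

    Deterministic for a fixed ``params.seed``: independent substreams are
    derived for block effects, plot effects, residuals and chemistry.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed).spawn(4)
    rng_block = np.random.default_rng(ss[0])
    rng_plot = np.random.default_rng(ss[1])
    rng_resid = np.random.default_rng(ss[2])
    rng_chem = np.random.default_rng(ss[3])

    blocks = sorted({s.plot.block for s in swards})
    plot_ids = sorted({s.plot.plot_id for s in swards})
    u_block = dict(zip(blocks, rng_block.normal(0.0, params.sigma_block, len(blocks))))
    u_plot = dict(zip(plot_ids, rng_plot.normal(0.0, params.sigma_plot, len(plot_ids))))

    rows: list[dict] = []
    n_truncated = 0
    for sward in swards:
        h = sward.regime.cuts_per_year
        mean_annual = (
            _annual_mean(sward, params)
            + u_block[sward.plot.block]
            + u_plot[sward.plot.plot_id]
        )
        resid = rng_resid.normal(0.0, params.sigma_resid, h)
        chem_offset = {
            v: rng_chem.normal(0.0, params.chem_sigma[v]) for v in CHEM_VARS
        }
        ucp_level = rng_chem.normal(params.ucp_target, params.ucp_sigma)
        for cut in range(1, h + 1):
            biomass = mean_annual / h + resid[cut - 1]
            if biomass < 0:
                n_truncated += 1
                biomass = 0.0
            chem = {
                v: max(params.chem_baseline[v] + chem_offset[v]
                       + params.chem_trend[v] * (cut - 1), 0.0)
                for v in CHEM_VARS
            }
            chem["ash"] = min(chem["ash"], 1000.0)
            row = {
                "sward_id": sward.sward_id,
                "plot_id": sward.plot.plot_id,
                "block": sward.plot.block,
                "management": sward.regime.name,
                "cuts_per_year": h,
                "n_fert": sward.regime.n_fert,
                "richness": sward.plot.richness,
                "n_functional_groups": sward.plot.n_functional_groups,
                "legume_present": int(sward.plot.legume_present),
                "legume_share": sward.plot.legume_share,
                "grass_present": int(sward.plot.grass_present),
                "tall_herb_present": int(sward.plot.tall_herb_present),
                "cut": cut,
                "biomass": biomass,
                **chem,
            }
            if cut == 1:
                # back out incubation inputs from the target uCP level:
                # ucp = (nh3_blank + n_sample - nh3_sample) / dm * 6250
                n_sample = chem["cp"] / 6.25 * params.dm_mg / 1000.0
                nh3_sample = (
                    params.nh3_n_blank + n_sample
                    - max(ucp_level, 0.0) * params.dm_mg / 6250.0
                )
                row.update(
                    dm_mg=params.dm_mg,
                    nh3_n_blank=params.nh3_n_blank,
                    n_sample=n_sample,
                    nh3_n_sample=max(nh3_sample, 0.0),
                )
            else:
                row.update(dm_mg=np.nan, nh3_n_blank=np.nan,
                           n_sample=np.nan, nh3_n_sample=np.nan)
            rows.append(row)

    if n_truncated:
        msg = f"{n_truncated} simulated cut biomass values truncated at 0"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return pd.DataFrame(rows)
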