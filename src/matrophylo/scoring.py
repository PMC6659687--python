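"""Matrotrophy-index scoring and trait binarization.

The matrotrophy index (MI) is the ratio of offspring dry mass at birth to
egg dry mass at fertilization.  MI < 1 means the embryo loses mass during
development (yolk-only, lecithotrophic provisioning); MI >> 1 means
substantial post-fertilization (placental) provisioning.  On the standard
0-50 embryonic staging scale, a population's MI is estimated from the OLS
slope b of ln(embryo dry mass) on stage as MI = exp(50 b); the slope
corresponding to MI = 0.7 is ln(0.7)/50 = -0.0071, the conventional
boundary below which provisioning is clearly absent.

Species are scored placentotrophic conservatively: only when the pooled
collection is trustworthy (more than 7 broods and a stage range above 25)
and either (rule 1) some population's slope is significantly greater than
zero, or (rule 2) at least two populations have an estimated MI above 1
with slopes significantly above the MI = 0.7 boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationRegression",
    "ScoringDecision",
    "fit_stage_mass_regression",
    "estimate_mi",
    "slope_threshold_for_mi",
    "score_placentotrophy",
    "sexual_selection_index",
    "median_split_binarize",
    "read_brood_table",
    "score_species_table",
]

STAGE_SPAN = 50.0
MI_THRESHOLD_SLOPE = math.log(0.7) / STAGE_SPAN  # = -0.00713...


@dataclasses.dataclass
class PopulationRegression:
    """OLS of ln(dry mass) on developmental stage for one population."""

    species: str
    population: str
    slope: float
    slope_se: float
    intercept: float
    n_broods: int
    stage_min: float
    stage_max: float
    p_gt_zero: float
    p_gt_threshold: float
    mi_estimate: float

    @property
    def stage_range(self) -> float:
        return self.stage_max - self.stage_min


@dataclasses.dataclass
class ScoringDecision:
    species: str
    placentotrophy: int
    trustworthy: bool
    rule_fired: str  # none | slope_gt_zero | two_pops_mi_gt_1
    n_broods: int
    stage_range: float


def _one_sided_p(slope: float, se: float, df: int, h0: float) -> float:
    """P-value of the one-sided t test of slope > h0 with df = n - 2."""
    if se == 0.0:
        return 0.0 if slope > h0 else (0.5 if slope == h0 else 1.0)
    t = (slope - h0) / se
    return float(stats.t.sf(t, df))


def fit_stage_mass_regression(obs: pd.DataFrame, species: str | None = None,
                              population: str | None = None) -> PopulationRegression:
    """Fit ln(dry_mass_mg) ~ stage for one population's brood observations.

    ``obs`` needs columns ``stage`` and ``dry_mass_mg`` (one row per brood);
    ``species``/``population`` default to the values found in the table.
    Requires at least 3 broods spanning more than one distinct stage.
    """
    if species is None:
        species = str(obs["species"].iloc[0])
    if population is None:
        population = str(obs["population"].iloc[0]) if "population" in obs else "pop1"
    stage = np.asarray(obs["stage"], dtype=float)
    mass = np.asarray(obs["dry_mass_mg"], dtype=float)
    if np.any(mass <= 0):
        raise ValueError("dry mass must be positive")
    if len(stage) < 3:
        raise ValueError("need at least 3 broods for a regression")
    if np.ptp(stage) == 0:
        raise ValueError("all stages identical: slope undefined")
    y = np.log(mass)
    res = stats.linregress(stage, y)
    df = len(stage) - 2
    se = float(res.stderr)
    if not math.isfinite(se):  # perfectly constant response
        se = 0.0
    slope = float(res.slope)
    return PopulationRegression(
        species=species,
        population=population,
        slope=slope,
        slope_se=se,
        intercept=float(res.intercept),
        n_broods=len(stage),
        stage_min=float(stage.min()),
        stage_max=float(stage.max()),
        p_gt_zero=_one_sided_p(slope, se, df, 0.0),
        p_gt_threshold=_one_sided_p(slope, se, df, MI_THRESHOLD_SLOPE),
        mi_estimate=float(np.exp(slope * STAGE_SPAN)),
    )


def estimate_mi(birth_mass: float, egg_mass: float) -> float:
    """Matrotrophy index: offspring dry mass at birth / egg dry mass."""
    if birth_mass <= 0 or egg_mass <= 0:
        raise ValueError("masses must be positive")
    return birth_mass / egg_mass


def slope_threshold_for_mi(mi: float, stage_span: float = STAGE_SPAN) -> float:
    """ln-mass-per-stage slope that corresponds to a given MI.

    ``slope_threshold_for_mi(0.7)`` reproduces the conventional -0.0071
    scoring boundary (4 dp).
    """
    if mi <= 0 or stage_span <= 0:
        raise ValueError("mi and stage_span must be positive")
    return math.log(mi) / stage_span


def score_placentotrophy(regs: Sequence[PopulationRegression],
                         alpha: float = 0.05,
                         min_broods: int = 7,
                         min_stage_range: float = 25.0,
                         per_population_trust: bool = False) -> ScoringDecision:
    """Conservative presence/absence call for placentotrophy in one species.

    Trustworthiness is judged on the pooled species-level collection
    (``per_population_trust=True`` applies it population-wise instead).
    Insufficient data yields 0, never an error: absence is the conservative
    default when false positives are the concern.
    """
    if not regs:
        raise ValueError("need at least one population regression")
    species = regs[0].species
    n_broods = sum(r.n_broods for r in regs)
    stage_range = max(r.stage_max for r in regs) - min(r.stage_min for r in regs)
    if per_population_trust:
        usable = [r for r in regs
                  if r.n_broods > min_broods and r.stage_range > min_stage_range]
        trustworthy = bool(usable)
    else:
        usable = list(regs)
        trustworthy = n_broods > min_broods and stage_range > min_stage_range

    rule = "none"
    placento = 0
    if trustworthy:
        if any(r.p_gt_zero < alpha for r in usable):
            rule, placento = "slope_gt_zero", 1
        elif sum(1 for r in usable
                 if r.mi_estimate > 1.0 and r.p_gt_threshold < alpha) >= 2:
            rule, placento = "two_pops_mi_gt_1", 1
    return ScoringDecision(species=species, placentotrophy=placento,
                           trustworthy=trustworthy, rule_fired=rule,
                           n_broods=n_broods, stage_range=stage_range)


def sexual_selection_index(courtship, dichromatism, ornamentation) -> float:
    """Number of male pre-copulatory traits present (0-3); NaN propagates."""
    vals = [courtship, dichromatism, ornamentation]
    out = 0.0
    for v in vals:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return math.nan
        if v not in (0, 1, 0.0, 1.0):
            raise ValueError(f"binary trait value outside {{0,1}}: {v!r}")
        out += v
    return out


def median_split_binarize(values: Mapping[str, float]) -> dict:
    """Binarize a continuous trait: bottom 50% of species -> 0, top -> 1.

    The lowest ceil(n/2) ranked species get state 0; ties at the boundary
    all get 0; missing values stay missing.
    """
    present = {k: v for k, v in values.items()
               if v is not None and not (isinstance(v, float) and math.isnan(v))}
    if len(present) < 2:
        raise ValueError("need at least 2 non-missing values")
    ordered = sorted(present.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ordered)
    n_low = math.ceil(n / 2)
    boundary = ordered[n_low - 1][1]
    if all(v == boundary for _, v in ordered):
        logger.warning("median split: all values identical; every species scored 0")
    out: dict = {}
    for k, v in values.items():
        if k in present:
            out[k] = 0 if present[k] <= boundary else 1
        else:
            out[k] = math.nan
    return out


def read_brood_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read brood observations (species,population,brood_id,stage,dry_mass_mg)."""
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"species", "population", "stage", "dry_mass_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"brood table missing columns: {sorted(missing)}")
    if (df["dry_mass_mg"] <= 0).any():
        raise ValueError("dry_mass_mg must be positive")
    if ((df["stage"] < 0) | (df["stage"] > STAGE_SPAN)).any():
        raise ValueError("stage outside the 0-50 scale")
    return df


def score_species_table(broods: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Run the full scoring over a brood table; one audit row per species."""
    rows = []
    for species, sdf in broods.groupby("species"):
        regs = []
        for pop, pdf in sdf.groupby("population"):
            try:
                regs.append(fit_stage_mass_regression(pdf, species=str(species),
                                                      population=str(pop)))
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", species, pop, exc)
        if not regs:
            rows.append(dict(species=species, placentotrophy=0,
                             trustworthy=False, rule_fired="none",
                             n_broods=int(len(sdf)), stage_range=float("nan")))
            continue
        d = score_placentotrophy(regs, **kwargs)
        rows.append(dataclasses.asdict(d))
    return pd.DataFrame(rows).set_index("species")
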