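"""Case-study scoring procedures built on the spatial statistics layer:

* spatial uniformity of an inequality measure — the share of a region's
  units sitting in significant high-high / low-low local clusters;
* quintile risk scoring with category-cumulative and overall composite
  risk scores (the pandemic-risk style index);
* social / access / combined inequity scores for program-reach evaluation.

All scores are rank-quintile based: each variable is cut at the 20/40/60/80
rank percentiles into scores 1–5, oriented so that 5 is always "worse".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .spatial_stats import LisaResult, SpatialWeights, local_moran

logger = logging.getLogger(__name__)

__all__ = [
    "UniformityMeasures",
    "uniformity_measures",
    "quintile_score",
    "category_risk",
    "composite_risk",
    "RiskTable",
    "risk_table",
    "InequityScores",
    "inequity_scores",
]


@dataclass
class UniformityMeasures:
    """Per-region shares of significant local clusters.

    u_high: fraction of the region's units in significant high-high
    clusters; u_low: same for low-low; u_any = u_high + u_low (spatial
    outliers HL/LH are excluded from all three).
    """

    regions: list[str]
    u_any: np.ndarray
    u_high: np.ndarray
    u_low: np.ndarray
    lisa: LisaResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.regions, "u_any": self.u_any,
             "u_high": self.u_high, "u_low": self.u_low}
        )


def uniformity_measures(
    values,
    unit_region: dict[str, str],
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> UniformityMeasures:
    """Regional uniformity of a unit-level measure via local Moran labels.

    The local statistics are computed jointly over *all* units, so
    cross-region neighbours contribute to each unit's spatial lag; labels
    are then summarised within regions.
    """
    missing = [u for u in w.ids if u not in unit_region]
    if missing:
        raise ValueError(f"units without a region: {missing[:5]}")
    res = local_moran(values, w, n_perm=n_perm, seed=seed, alpha=alpha)
    regions = sorted(set(unit_region[u] for u in w.ids))
    counts = {r: [0, 0, 0] for r in regions}  # total, HH, LL
    for u, lab in zip(res.ids, res.labels):
        c = counts[unit_region[u]]
        c[0] += 1
        if lab == "HH":
            c[1] += 1
        elif lab == "LL":
            c[2] += 1
    u_high = np.array([counts[r][1] / counts[r][0] for r in regions])
    u_low = np.array([counts[r][2] / counts[r][0] for r in regions])
    for r in regions:
        if counts[r][0] == 0:
            raise ValueError(f"region {r!r} has no units")
    return UniformityMeasures(regions, u_high + u_low, u_high, u_low, res)


def quintile_score(values, worse_is_high: bool = True) -> np.ndarray:
    """Rank-based quintile scores 1–5, 5 = worst.

    Ties get average ranks; cuts fall at rank fractions 0.2/0.4/0.6/0.8.
    ``worse_is_high=False`` reverses the mapping for protective variables.
    Nulls stay null. A constant input collapses to a single bin scored 1.
    """
    x = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all values are null")
    sub = x[ok]
    if np.all(sub == sub[0]):
        logger.warning("quintile_score: constant input collapses to one bin")
        out[ok] = 1.0
        return out
    if n < 5:
        logger.warning("quintile_score: only %d non-null values; bins are coarse", n)
    frac = rankdata(sub, method="average") / n
    score = np.ceil(frac * 5 - 1e-12).astype(float)
    score = np.clip(score, 1, 5)
    if not worse_is_high:
        score = 6 - score
    out[ok] = score
    return out


def category_risk(quintiles: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative risk for one category: row sum of its variables' quintile
    scores. Returns (score, coverage) where coverage is the per-unit
    fraction of non-null variables entering the sum."""
    if quintiles.shape[1] == 0:
        raise ValueError("empty category")
    m = quintiles.to_numpy(dtype=float)
    cov = np.mean(~np.isnan(m), axis=1)
    score = np.nansum(m, axis=1)
    score[cov == 0] = np.nan
    return score, cov


def composite_risk(category_scores: pd.DataFrame) -> np.ndarray:
    """Overall composite risk: sum of the category cumulative scores,
    weighting every category equally."""
    if category_scores.shape[1] == 0:
        raise ValueError("need at least one category")
    m = category_scores.to_numpy(dtype=float)
    out = m.sum(axis=1)  # null category propagates to null composite
    return out


@dataclass
class RiskTable:
    """Quintile scores, per-category cumulative scores, and the composite."""

    units: list[str]
    quintiles: pd.DataFrame  # one column per variable
    category_scores: pd.DataFrame  # one column per category
    composite: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"unit": self.units})
        for c in self.quintiles.columns:
            out[f"q_{c}"] = self.quintiles[c].to_numpy()
        for c in self.category_scores.columns:
            out[f"risk_{c}"] = self.category_scores[c].to_numpy()
        out["composite_risk"] = self.composite
        return out


def risk_table(
    units: list[str],
    data: pd.DataFrame,
    categories: dict[str, list[tuple[str, bool]]],
) -> RiskTable:
    """Full quintile → category → composite pipeline.

    ``categories`` maps category name → list of (variable, worse_is_high).
    """
    quint = pd.DataFrame(index=range(len(units)))
    for cat, specs in categories.items():
        for var, worse_high in specs:
            if var not in data.columns:
                raise KeyError(f"variable {var!r} not in data")
            quint[var] = quintile_score(data[var].to_numpy(), worse_is_high=worse_high)
    cat_scores = pd.DataFrame(index=range(len(units)))
    for cat, specs in categories.items():
        score, _cov = category_risk(quint[[v for v, _ in specs]])
        cat_scores[cat] = score
    comp = composite_risk(cat_scores)
    return RiskTable(list(units), quint, cat_scores, comp)


@dataclass
class InequityScores:
    """Social / access / combined inequity scores per unit, plus cohort
    mean comparisons (program-reach vs rural vs all units)."""

    units: list[str]
    social: np.ndarray
    access: np.ndarray
    combined: np.ndarray
    mean_combined_all: float
    mean_combined_reach: float | None
    mean_combined_rural: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": self.units, "social_inequity": self.social,
             "access_inequity": self.access, "combined_inequity": self.combined}
        )


def inequity_scores(
    units: list[str],
    social: pd.DataFrame,
    access: pd.DataFrame,
    social_worse_high: list[bool] | None = None,
    access_worse_high: list[bool] | None = None,
    reach_flag: np.ndarray | None = None,
    rural_flag: np.ndarray | None = None,
    expected_counts: tuple[int, int] = (7, 4),
) -> InequityScores:
    """Quintile-standardised domain scores and their combination.

    Each measure is quintile-scored (direction-adjusted so 5 = more
    inequitable); the social score is the mean of the social measures'
    quintiles, the access score the mean of the access measures', and the
    combined score the mean of the two domain scores. The conventional
    composition is 7 social and 4 access measures; other counts work but
    are flagged.
    """
    if social.shape[1] != expected_counts[0] or access.shape[1] != expected_counts[1]:
        logger.warning(
            "inequity_scores: %d social / %d access measures (expected %d/%d)",
            social.shape[1], access.shape[1], *expected_counts,
        )
    sw = social_worse_high or [True] * social.shape[1]
    aw = access_worse_high or [True] * access.shape[1]
    sq = np.column_stack(
        [quintile_score(social.iloc[:, j], sw[j]) for j in range(social.shape[1])]
    )
    aq = np.column_stack(
        [quintile_score(access.iloc[:, j], aw[j]) for j in range(access.shape[1])]
    )
    social_score = np.nanmean(sq, axis=1)
    access_score = np.nanmean(aq, axis=1)
    combined = (social_score + access_score) / 2.0
    mean_all = float(np.nanmean(combined))
    mean_reach = (
        float(np.nanmean(combined[np.asarray(reach_flag, dtype=bool)]))
        if reach_flag is not None
        else None
    )
    mean_rural = (
        float(np.nanmean(combined[np.asarray(rural_flag, dtype=bool)]))
        if rural_flag is not None
        else None
    )
    return InequityScores(
        list(units), social_score, access_score, combined,
        mean_all, mean_reach, mean_rural,
    )
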