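"""Hierarchical group comparison of per-cell metrics.

Cells from the same heart are correlated, so each metric is analysed
with a linear mixed model: fixed effects for each group x region stratum
(cell-means coding) and a random intercept per animal, fitted by REML.
Pairwise stratum contrasts use Wald t statistics with a between-within
degrees-of-freedom approximation (between-animal df for contrasts whose
strata share no animals, within-animal df otherwise), and multiplicity
within each contrast family is handled with the Dunn-Sidak correction
p_adj = 1 - (1 - p)^m.

Exact agreement with any particular commercial implementation's
covariance structure or df method is not claimed; orderings and effect
estimates are the object of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "HierarchicalFit",
    "fit_hierarchical",
    "sidak_adjust",
    "pairwise_contrasts",
    "group_contrasts_within_region",
    "region_contrasts_within_group",
    "compare_metrics",
]

_STRATUM_SEP = "||"


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Dunn-Sidak multiplicity correction: 1 - (1 - p)^m, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must cover all comparisons")
    return np.minimum(1.0 - (1.0 - p) ** m, 1.0)


@dataclass
class HierarchicalFit:
    """A fitted random-intercept model for one metric.

    ``coef`` maps stratum (group, region) to its estimated mean;
    ``var_animal`` and ``var_resid`` are the REML variance components.
    """

    metric: str
    strata: list
    coef: np.ndarray
    cov: np.ndarray
    var_animal: float
    var_resid: float
    n_obs: int
    n_animals: int
    n_groups: int
    animals_per_stratum: dict
    n_dropped: int

    def stratum_mean(self, group: str, region: str) -> float:
        return float(self.coef[self.strata.index((group, region))])


def fit_hierarchical(
    table: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    region_col: str = "region",
    animal_col: str = "animal_id",
) -> HierarchicalFit:
    """Fit the random-intercept-per-animal model for one metric.

    Missing outcome values are dropped (and counted); each group must
    contribute at least two animals, otherwise the animal-level contrast
    has no degrees of freedom and an error is raised.
    """
    df = table[[group_col, region_col, animal_col, outcome]].copy()
    n0 = len(df)
    df = df.dropna(subset=[outcome])
    df[outcome] = pd.to_numeric(df[outcome])

    per_group = df.groupby(group_col)[animal_col].nunique()
    if (per_group < 2).any():
        bad = per_group[per_group < 2].index.tolist()
        raise ValueError(
            f"groups {bad} have fewer than 2 animals: the between-animal "
            "contrast has no degrees of freedom"
        )

    df["_stratum"] = df[group_col] + _STRATUM_SEP + df[region_col]
    strata_labels = sorted(df["_stratum"].unique())
    exog = pd.get_dummies(df["_stratum"], dtype=float)[strata_labels]
    endog = df[outcome].to_numpy(dtype=float)

    model = sm.MixedLM(endog, exog.to_numpy(), groups=df[animal_col].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
        except Exception:
            res = model.fit(reml=True, method="powell")

    strata = [tuple(s.split(_STRATUM_SEP)) for s in strata_labels]
    k = len(strata)
    animals_per_stratum = {
        tuple(s.split(_STRATUM_SEP)): set(sub[animal_col])
        for s, sub in df.groupby("_stratum")
    }
    return HierarchicalFit(
        metric=outcome,
        strata=strata,
        coef=np.asarray(res.params[:k], dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float)[:k, :k],
        var_animal=float(np.asarray(res.cov_re)[0, 0]),
        var_resid=float(res.scale),
        n_obs=len(df),
        n_animals=df[animal_col].nunique(),
        n_groups=df[group_col].nunique(),
        animals_per_stratum=animals_per_stratum,
        n_dropped=n0 - len(df),
    )


def _contrast_df(fit: HierarchicalFit, s1: tuple, s2: tuple) -> float:
    """Between-within df approximation for the stratum contrast s1 - s2."""
    a1 = fit.animals_per_stratum[s1]
    a2 = fit.animals_per_stratum[s2]
    if a1 & a2:
        # within-animal comparison: residual df after animal and stratum means
        return max(fit.n_obs - fit.n_animals - len(fit.strata) + fit.n_groups, 1)
    # between-animal comparison: clusters minus group-level parameters
    return max(fit.n_animals - fit.n_groups, 1)


def pairwise_contrasts(
    fit: HierarchicalFit, pairs: list, family_size: int | None = None
) -> pd.DataFrame:
    """Wald t contrasts for the given stratum pairs, Sidak-adjusted.

    ``pairs`` is a list of ((group_a, region_a), (group_b, region_b));
    the Sidak family size defaults to the number of pairs.
    """
    rows = []
    for s1, s2 in pairs:
        i, j = fit.strata.index(s1), fit.strata.index(s2)
        L = np.zeros(len(fit.strata))
        L[i], L[j] = 1.0, -1.0
        est = float(L @ fit.coef)
        se = float(np.sqrt(L @ fit.cov @ L))
        ddf = _contrast_df(fit, s1, s2)
        t = est / se if se > 0 else np.nan
        p = 2.0 * sps.t.sf(abs(t), ddf) if np.isfinite(t) else np.nan
        rows.append(
            {
                "metric": fit.metric,
                "stratum_a": "/".join(s1),
                "stratum_b": "/".join(s2),
                "estimate": est,
                "se": se,
                "df": ddf,
                "t": t,
                "p_raw": p,
                "var_animal": fit.var_animal,
                "var_resid": fit.var_resid,
            }
        )
    out = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(out)
    out["p_sidak"] = sidak_adjust(out["p_raw"].to_numpy(), m=m)
    return out


def group_contrasts_within_region(fit: HierarchicalFit) -> pd.DataFrame:
    """All pairwise group comparisons within each region.

    The Sidak family is counted per region (one metric x region family).
    """
    by_region: dict = {}
    for g, r in fit.strata:
        by_region.setdefault(r, []).append(g)
    frames = []
    for region, groups in sorted(by_region.items()):
        groups = sorted(groups)
        pairs = [
            ((ga, region), (gb, region))
            for i, ga in enumerate(groups)
            for gb in groups[i + 1 :]
        ]
        if pairs:
            sub = pairwise_contrasts(fit, pairs, family_size=len(pairs))
            sub.insert(1, "region", region)
            frames.append(sub)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def region_contrasts_within_group(
    fit: HierarchicalFit, group: str, regions: tuple
) -> pd.DataFrame:
    """Contrast two regions within one group (e.g. border zone vs remote LV)."""
    r1, r2 = regions
    return pairwise_contrasts(fit, [((group, r1), (group, r2))], family_size=1)


def compare_metrics(
    table: pd.DataFrame,
    metrics: list,
    group_col: str = "group",
    region_col: str = "region",
    animal_col: str = "animal_id",
) -> pd.DataFrame:
    """Fit each metric and return the within-region group contrasts."""
    frames = []
    for metric in metrics:
        fit = fit_hierarchical(
            table, metric, group_col=group_col,
            region_col=region_col, animal_col=animal_col,
        )
        frames.append(group_contrasts_within_region(fit))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
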