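"""Field-trial phenotype adjustment and across-location variance analysis.

Stage 1 corrects within-trial soil heterogeneity: every trial is laid out in
sub-blocks that each contain a few repeated control cultivars, while the
breeding lines themselves are unreplicated.  The two-way fixed-effects model

    Y_ij = mu + G_i + B_j + e_ij

is fitted by least squares with a sum-to-zero constraint on the sub-block
effects B_j; the control replication is what identifies the block effects.
A line's adjusted value is its raw value minus the estimated block effect.

Stage 2 analyses the adjusted values across locations with

    Y_il = mu + G_i + Location_l + e_il

(random genotype, fixed location).  On balanced data the variance
components come from the expected mean squares of the two-way layout
(``sigma2_g = (MS_G - MS_E) / n_locations``); unbalanced data fall back to
REML.  Line-mean heritability is ``h2 = s2_g / (s2_g + s2_e / l)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable


def adjust_subblocks(table: PhenotypeTable, location: str, trait: str) -> pd.Series:
    """Per-line adjusted values at one location for one trait.

    Fits ``Y_ij = mu + G_i + B_j + e_ij`` (fixed effects, sum-to-zero block
    constraint) by least squares and returns, for each line, the mean of its
    block-corrected observations.  Every sub-block must contain at least one
    control record.
    """
    df = table.subset(location=location, trait=trait)
    if df.empty:
        raise ValueError(f"no records for trait {trait!r} at {location!r}")
    blocks = sorted(df["sub_block"].unique().tolist())
    for b in blocks:
        sub = df[df["sub_block"] == b]
        if not sub["is_control"].any():
            raise ValueError(f"sub-block {b!r} at {location!r} has no control record")
    lines = sorted(df["line"].unique().tolist())
    li = {l: i for i, l in enumerate(lines)}
    bi = {b: i for i, b in enumerate(blocks)}
    n_obs, nl, nb = len(df), len(lines), len(blocks)
    # design: one column per line (absorbs mu + G_i), nb-1 sum-to-zero block columns
    Z = np.zeros((n_obs, nl + nb - 1))
    y = df["value"].to_numpy()
    for r, (line, block) in enumerate(zip(df["line"], df["sub_block"])):
        Z[r, li[line]] = 1.0
        j = bi[block]
        if j < nb - 1:
            Z[r, nl + j] = 1.0
        else:
            Z[r, nl : nl + nb - 1] = -1.0
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    block_eff = np.append(coef[nl:], -coef[nl:].sum())
    adj = df["value"].to_numpy() - block_eff[[bi[b] for b in df["sub_block"]]]
    out = pd.Series(adj, index=df["line"].to_numpy()).groupby(level=0).mean()
    out.index.name = "line"
    return out.loc[lines]


def adjusted_by_location(table: PhenotypeTable, trait: str, drop_controls: bool = True) -> pd.DataFrame:
    """Sub-block-adjusted values for every location: columns line, location, value.

    Control cultivars are dropped from the output by default (they are
    trial infrastructure, not selection candidates).
    """
    controls = set(table.records.loc[table.records["is_control"], "line"])
    rows = []
    for loc in sorted(table.records["location"].unique().tolist()):
        adj = adjust_subblocks(table, loc, trait)
        for line, v in adj.items():
            if drop_controls and line in controls:
                continue
            rows.append({"line": line, "location": loc, "value": v})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Variance decomposition of adjusted values across locations."""

    sigma2_g: float
    sigma2_e: float
    location_effects: dict
    F_genotype: float
    p_value: float
    n_locations: int
    truncated: bool = False
    method: str = "moments"


def anova_locations(adjusted: pd.DataFrame) -> AnovaResult:
    """Fit ``Y_il = mu + G_i + Location_l + e_il`` (random G, fixed location).

    ``adjusted`` has columns line, location, value with one record per line
    and location.  Balanced data (every line at every location, exactly
    once) use the exact expected-mean-squares decomposition; unbalanced
    data fall back to REML (random line intercept, fixed location) with a
    likelihood-ratio test for the genotypic variance.
    """
    df = pd.DataFrame(adjusted)
    locs = sorted(df["location"].unique().tolist())
    if len(locs) < 2:
        raise ValueError("need at least two locations for the across-location ANOVA")
    wide = df.pivot_table(index="line", columns="location", values="value", aggfunc="count")
    balanced = wide.notna().all().all() and (wide == 1).all().all()
    if balanced:
        Y = df.pivot(index="line", columns="location", values="value").to_numpy()
        n, l = Y.shape
        grand = Y.mean()
        line_means = Y.mean(axis=1)
        loc_means = Y.mean(axis=0)
        ss_g = l * np.sum((line_means - grand) ** 2)
        ss_l = n * np.sum((loc_means - grand) ** 2)
        ss_e = np.sum((Y - line_means[:, None] - loc_means[None, :] + grand) ** 2)
        ms_g = ss_g / (n - 1)
        ms_e = ss_e / ((n - 1) * (l - 1))
        sigma2_g = (ms_g - ms_e) / l
        truncated = bool(sigma2_g < 0)
        if truncated:
            sigma2_g = 0.0
        if ms_e > 0:
            F = ms_g / ms_e
            p = float(stats.f.sf(F, n - 1, (n - 1) * (l - 1)))
        else:
            F, p = np.inf, 0.0
        loc_eff = {loc: float(m - grand) for loc, m in zip(sorted(df["location"].unique()), loc_means)}
        return AnovaResult(
            sigma2_g=float(sigma2_g),
            sigma2_e=float(ms_e),
            location_effects=loc_eff,
            F_genotype=float(F),
            p_value=p,
            n_locations=l,
            truncated=truncated,
            method="moments",
        )
    return _anova_reml(df, locs)


def _anova_reml(df: pd.DataFrame, locs) -> AnovaResult:
    import statsmodels.formula.api as smf

    md = smf.mixedlm("value ~ C(location)", df, groups=df["line"])
    fit = md.fit(reml=True)
    sigma2_g = float(fit.cov_re.iloc[0, 0])
    sigma2_e = float(fit.scale)
    truncated = sigma2_g < 1e-10
    # LRT for the genotypic variance (ML fits; 0.5*chi2_1 mixture at the boundary)
    import statsmodels.api as sm

    ml = md.fit(reml=False)
    X = pd.get_dummies(df["location"], drop_first=True, dtype=float)
    X = sm.add_constant(X)
    ols = sm.OLS(df["value"], X).fit()
    lr = 2.0 * (ml.llf - ols.llf)
    p = 0.5 * float(stats.chi2.sf(max(lr, 0.0), 1))
    grand = df["value"].mean()
    loc_eff = {
        loc: float(df.loc[df["location"] == loc, "value"].mean() - grand) for loc in locs
    }
    return AnovaResult(
        sigma2_g=max(sigma2_g, 0.0),
        sigma2_e=sigma2_e,
        location_effects=loc_eff,
        F_genotype=float("nan"),
        p_value=p,
        n_locations=len(locs),
        truncated=truncated,
        method="reml",
    )


def heritability_line_mean(a: AnovaResult) -> float:
    """Line-mean (entry-mean) heritability: ``s2_g / (s2_g + s2_e / l)``."""
    if a.sigma2_g == 0 and a.sigma2_e == 0:
        raise ValueError("heritability undefined: both variance components are zero")
    return a.sigma2_g / (a.sigma2_g + a.sigma2_e / a.n_locations)
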