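"""Descriptive statistics, multi-environment ANOVA and heritability.

The trial design is genotype x environment with replicates (blocks) nested in
environments.  Variance components come from equating observed mean squares
to their expectations under the random-genotype model:

    MS_error           = s2_e
    MS_GxE             = s2_e + r s2_GE
    MS_G               = s2_e + r s2_GE + e r s2_G
    MS_rep(within E)   = s2_e + g s2_block

Genotype is tested against the GxE mean square and GxE against error.
Negative method-of-moments estimates are truncated to zero and flagged.
Broad-sense heritability is on the entry-mean basis:

    h2_B = s2_G / (s2_G + s2_GE / e + s2_e / (e r)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PhenotypeTable, line_means


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GE: float
    sigma2_E: float
    sigma2_block: float
    sigma2_e: float
    n_env: int
    n_rep: int
    truncated: list[str] = field(default_factory=list)


@dataclass
class AnovaTests:
    F_G: float
    p_G: float
    F_GE: float
    p_GE: float
    ss_table: pd.DataFrame


def trait_summary(
    pheno: PhenotypeTable, trait: str, environment: str | None = None
) -> dict[str, float]:
    """Mean, sample SD, min, max and CV% over line means.

    ``environment=None`` summarizes the across-environment line means (the
    "Mean" row of a descriptive table); otherwise the per-environment line
    means for that environment.
    """
    if environment is None:
        lm = line_means(pheno, "across_environments")
        vals = lm[lm["trait_name"] == trait]["mean_value"]
    else:
        lm = line_means(pheno, "per_environment")
        vals = lm[
            (lm["trait_name"] == trait) & (lm["environment_id"] == environment)
        ]["mean_value"]
    vals = vals.to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 observations")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    cv = float(100.0 * sd / mean) if mean != 0 else float("nan")
    return {
        "mean": mean,
        "sd": sd,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "cv_pct": cv,
    }


def anova_components(
    pheno: PhenotypeTable, trait: str
) -> tuple[VarianceComponents, AnovaTests]:
    """Two-factor ANOVA (G, E, rep-within-E, GxE) with EMS-based components.

    Requires balanced or near-balanced data; unbalanced designs are analyzed
    with unweighted cell means and the average replicate number, with a
    warning.  A single environment leaves sigma2_GE inestimable (NaN, flagged).
    """
    frame = pheno.for_trait(trait).dropna(subset=["value"])
    g = frame["accession_id"].nunique()
    e = frame["environment_id"].nunique()
    reps = frame.groupby(["accession_id", "environment_id"])["value"].size()
    r = float(reps.mean())
    if reps.nunique() > 1:
        warnings.warn(
            f"anova_components({trait}): unbalanced replication, using mean r={r:.2f}"
        )
    y = frame["value"].to_numpy(dtype=float)
    grand = float(y.mean())

    gi = frame.groupby("accession_id")["value"].mean()
    ej = frame.groupby("environment_id")["value"].mean()
    cell = frame.groupby(["accession_id", "environment_id"])["value"].mean()
    blk = frame.groupby(["environment_id", "replicate_id"])["value"].mean()
    n_rep_labels = frame.groupby("environment_id")["replicate_id"].nunique().max()

    ss_G = e * r * float(((gi - grand) ** 2).sum())
    ss_E = g * r * float(((ej - grand) ** 2).sum())
    ss_block = g * float(((blk - blk.index.get_level_values(0).map(ej)) ** 2).sum())
    inter = cell.reset_index()
    inter["dev"] = (
        inter["value"]
        - inter["accession_id"].map(gi)
        - inter["environment_id"].map(ej)
        + grand
    )
    ss_GE = r * float((inter["dev"] ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = max(ss_total - ss_G - ss_E - ss_block - ss_GE, 0.0)

    df_G = g - 1
    df_E = e - 1
    df_block = e * (int(n_rep_labels) - 1)
    df_GE = (g - 1) * (e - 1)
    df_err = max((g - 1) * e * (int(n_rep_labels) - 1) - 0, 1) if e >= 1 else 1
    # on balanced data: df_err = e (r-1)(g-1); recompute exactly
    df_err = (g - 1) * e * (int(n_rep_labels) - 1)
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom (need >=2 replicates)")

    ms_G = ss_G / df_G
    ms_E = ss_E / df_E if df_E > 0 else float("nan")
    ms_block = ss_block / df_block if df_block > 0 else float("nan")
    ms_GE = ss_GE / df_GE if df_GE > 0 else float("nan")
    ms_err = ss_err / df_err

    truncated: list[str] = []

    def _trunc(x: float, name: str) -> float:
        if np.isnan(x):
            return x
        if x < 0:
            truncated.append(name)
            return 0.0
        return x

    s2_e = ms_err
    if e > 1:
        s2_GE = _trunc((ms_GE - ms_err) / r, "sigma2_GE")
        s2_G = _trunc((ms_G - ms_GE) / (e * r), "sigma2_G")
        s2_E = _trunc((ms_E - ms_GE) / (g * r), "sigma2_E")
        F_G = ms_G / ms_GE
        p_G = float(stats.f.sf(F_G, df_G, df_GE))
        F_GE = ms_GE / ms_err
        p_GE = float(stats.f.sf(F_GE, df_GE, df_err))
    else:
        warnings.warn(f"anova_components({trait}): single environment, "
                      "sigma2_GE inestimable")
        s2_GE = float("nan")
        s2_G = _trunc((ms_G - ms_err) / r, "sigma2_G")
        s2_E = float("nan")
        F_G = ms_G / ms_err
        p_G = float(stats.f.sf(F_G, df_G, df_err))
        F_GE, p_GE = float("nan"), float("nan")
    s2_block = _trunc((ms_block - ms_err) / g, "sigma2_block") if df_block > 0 else 0.0

    ss_table = pd.DataFrame(
        {
            "source": ["G", "E", "rep(E)", "GxE", "error", "total"],
            "df": [df_G, df_E, df_block, df_GE, df_err,
                   df_G + df_E + df_block + df_GE + df_err],
            "SS": [ss_G, ss_E, ss_block, ss_GE, ss_err, ss_total],
            "MS": [ms_G, ms_E, ms_block, ms_GE, ms_err, np.nan],
        }
    )
    vc = VarianceComponents(
        sigma2_G=s2_G,
        sigma2_GE=s2_GE,
        sigma2_E=s2_E,
        sigma2_block=s2_block,
        sigma2_e=s2_e,
        n_env=e,
        n_rep=int(n_rep_labels),
        truncated=truncated,
    )
    return vc, AnovaTests(F_G, p_G, F_GE, p_GE, ss_table)


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability, clipped to [0, 1]."""
    s2_ge = 0.0 if np.isnan(vc.sigma2_GE) else vc.sigma2_GE
    denom = vc.sigma2_G + s2_ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom == 0:
        return float("nan")
    return float(np.clip(vc.sigma2_G / denom, 0.0, 1.0))


def trait_correlations(
    line_means_wide: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with t-test significance stars.

    Returns (r, p, stars) as trait x trait tables; stars are '***' for
    p<=0.001, '**' for p<=0.01, '*' for p<=0.05, '' otherwise.  A
    zero-variance trait yields a NaN row/column.
    """
    traits = list(line_means_wide.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xy = line_means_wide[[traits[i], traits[j]]].dropna()
            if len(xy) < 3:
                continue
            x = xy.iloc[:, 0].to_numpy(dtype=float)
            y = xy.iloc[:, 1].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = float(rr)
            p[i, j] = p[j, i] = float(pp)

    def star(pp: float) -> str:
        if np.isnan(pp):
            return ""
        if pp <= 0.001:
            return "***"
        if pp <= 0.01:
            return "**"
        if pp <= 0.05:
            return "*"
        return ""

    stars = pd.DataFrame(
        [[star(p[i, j]) for j in range(k)] for i in range(k)],
        index=traits, columns=traits,
    )
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
        stars,
    )
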