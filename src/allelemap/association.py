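"""Q+K mixed-linear-model marker scan with Bonferroni and stability filters.

Model per trait and environment, on replicate-averaged line means y:

    y = mu + Q v + u + e,   Var(u) = sigma2_g K,  Var(e) = sigma2_e I

with Q the structure covariates (k-1 membership columns) and K the kinship
matrix.  Variance components are estimated once per trait x environment by
REML under the null model, using a one-dimensional optimization over the
variance ratio after an eigendecomposition of K, and reused for every marker
test (the P3D/EMMAX approximation; exact per-marker REML is available behind
a flag).  Each marker enters as a categorical fixed effect over its retained
allele classes and is tested by a generalized-least-squares F-test on the
whitened scale; marker R2 is (RSS_null - RSS_marker)/TSS on that same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import MISSING, GenotypePanel, PhenotypeTable, line_means
from .relatedness import KinshipMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# null-model REML (EMMA-style)
# ---------------------------------------------------------------------------


@dataclass
class MLMFit:
    """Null-model fit: variance components plus the spectral cache of K."""

    trait: str
    environment: str
    accessions: list[str]
    y: np.ndarray
    X0: np.ndarray  # intercept + structure covariates
    eigvals: np.ndarray
    eigvecs: np.ndarray
    delta: float  # sigma2_e / sigma2_g at the REML optimum
    sigma2_g: float
    sigma2_e: float
    reml_ll: float
    K: np.ndarray | None = None  # aligned kinship, kept for per-marker subsets

    @property
    def n(self) -> int:
        return self.y.size

    def whitening(self) -> np.ndarray:
        """T with Cov(T y) proportional to I under the null."""
        w = self.eigvals + self.delta
        return (self.eigvecs / np.sqrt(w)).T


def _reml_loglik(
    log10_delta: float, D: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray
) -> float:
    delta = 10.0 ** log10_delta
    w = D + delta
    n, p = Xstar.shape
    Xw = Xstar / w[:, None]
    XtWX = Xstar.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    q = float(np.sum(r**2 / w))
    sigma2 = q / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0 or sigma2 <= 0:
        return -np.inf
    return -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet + (n - p))


def fit_null_mlm(
    y: pd.Series,
    Q: pd.DataFrame | None,
    K: KinshipMatrix,
    trait: str = "",
    environment: str = "",
) -> MLMFit:
    """REML variance components of the null Q+K model.

    ``y`` is indexed by accession; complete cases (y present, in K, in Q) are
    aligned automatically.  The variance ratio delta = sigma2_e/sigma2_g is
    profiled on a log10 grid and polished by bounded scalar optimization;
    when the likelihood is flat in delta (e.g. K = I), the largest delta is
    taken, attributing the variance to the residual.  Deterministic.
    """
    ids = [a for a in y.index if pd.notna(y[a]) and a in K.accession_ids]
    if Q is not None:
        ids = [a for a in ids if a in Q.index]
    yv = y.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    X0 = np.ones((n, 1))
    if Q is not None:
        X0 = np.column_stack([X0, Q.loc[ids].to_numpy(dtype=float)])
    if n < X0.shape[1] + 2:
        raise ValueError(f"too few complete cases (n={n}) for {X0.shape[1]} covariates")
    Ksub = K.align(ids)
    if np.isnan(Ksub).any():
        raise ValueError("kinship has missing cells among complete cases")
    D, U = np.linalg.eigh(Ksub)
    if D.min() < -1e-8 * max(1.0, float(D.max())):
        raise ValueError(f"K is not positive semidefinite (min eigenvalue {D.min():.3g})")
    D = np.clip(D, 0.0, None)

    ystar = U.T @ yv
    Xstar = U.T @ X0
    grid = np.linspace(-6.0, 6.0, 49)
    lls = np.array([_reml_loglik(g, D, ystar, Xstar) for g in grid])
    # prefer the largest delta on (near-)flat likelihoods
    best_idx = len(lls) - 1 - int(np.argmax(lls[::-1]))
    lo = grid[max(best_idx - 1, 0)]
    hi = grid[min(best_idx + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, D, ystar, Xstar),
        bounds=(lo, hi), method="bounded",
    )
    cand = [(float(_reml_loglik(res.x, D, ystar, Xstar)), float(res.x)),
            (float(lls[best_idx]), float(grid[best_idx]))]
    ll, log10_delta = max(cand, key=lambda t: (t[0], t[1]))
    delta = 10.0 ** log10_delta

    w = D + delta
    Xw = Xstar / w[:, None]
    beta = np.linalg.solve(Xstar.T @ Xw, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    sigma2_g = float(np.sum(r**2 / w)) / (n - X0.shape[1])
    return MLMFit(
        trait=trait,
        environment=environment,
        accessions=ids,
        y=yv,
        X0=X0,
        eigvals=D,
        eigvecs=U,
        delta=delta,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_g * delta,
        reml_ll=ll,
        K=Ksub,
    )


def fit_ols(y: pd.Series, covariates: pd.DataFrame | None = None,
            trait: str = "", environment: str = "") -> MLMFit:
    """Naive fixed-effects fit (V = I): the no-structure-control baseline."""
    ids = [a for a in y.index if pd.notna(y[a])]
    if covariates is not None:
        ids = [a for a in ids if a in covariates.index]
    yv = y.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.column_stack([X0, covariates.loc[ids].to_numpy(dtype=float)])
    return MLMFit(
        trait=trait, environment=environment, accessions=ids, y=yv, X0=X0,
        eigvals=np.ones(n), eigvecs=np.eye(n), delta=0.0,
        sigma2_g=float(np.var(yv, ddof=1)), sigma2_e=0.0, reml_ll=np.nan,
        K=np.eye(n),
    )


# ---------------------------------------------------------------------------
# marker scan (P3D)
# ---------------------------------------------------------------------------


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _marker_design(
    calls: np.ndarray, rare_policy: str, rare_threshold: float
) -> tuple[np.ndarray | None, np.ndarray, int]:
    """Class labels for typed lines under the rare-allele policy.

    Returns (dummies or None, keep-mask over the typed subset, n_classes).
    ``pool`` folds alleles below the frequency threshold into one class;
    ``drop`` removes their carriers.
    """
    typed = calls != MISSING
    vals = calls[typed]
    codes, counts = np.unique(vals, return_counts=True)
    freqs = counts / counts.sum()
    rare = set(codes[freqs < rare_threshold])
    keep = typed.copy()
    if rare_policy == "drop" and rare:
        keep &= ~np.isin(calls, list(rare))
        vals = calls[keep]
        codes = np.unique(vals)
        rare = set()
    elif rare_policy != "pool" and rare_policy != "drop":
        raise ValueError(f"unknown rare_policy {rare_policy!r}")
    labels = np.zeros(vals.size, dtype=int)
    classes = [c for c in codes if c not in rare]
    if rare and rare_policy == "pool":
        class_map = {c: i + 1 for i, c in enumerate(classes)}  # 0 = pooled "other"
        for c, i in class_map.items():
            labels[vals == c] = i
        n_classes = len(classes) + 1
        if not any(v in rare for v in vals):
            n_classes = len(classes)
    else:
        class_map = {c: i for i, c in enumerate(classes)}
        for c, i in class_map.items():
            labels[vals == c] = i
        n_classes = len(classes)
    uniq = np.unique(labels)
    if uniq.size < 2:
        return None, keep, int(uniq.size)
    # re-index to 0..C-1 and build reference-coded dummies
    relab = {u: i for i, u in enumerate(uniq)}
    labels = np.array([relab[v] for v in labels])
    C = uniq.size
    dummies = np.zeros((vals.size, C - 1))
    for c in range(1, C):
        dummies[labels == c, c - 1] = 1.0
    return dummies, keep, C


def marker_scan(
    fit: MLMFit,
    panel: GenotypePanel,
    rare_policy: str = "pool",
    rare_threshold: float = 0.05,
    exact_reml: bool = False,
    Q_for_refit: pd.DataFrame | None = None,
    K_for_refit: KinshipMatrix | None = None,
) -> pd.DataFrame:
    """GLS F-test of every marker against the fitted null model.

    Uses the null-model variance components for all markers (P3D); with
    ``exact_reml`` the null components are re-estimated on each marker's
    complete-case subset (slower, needs ``K_for_refit``).  Lines untyped at a
    marker drop out of that marker's test only.
    """
    acc_index = {a: i for i, a in enumerate(panel.accession_ids)}
    rows_panel = [acc_index[a] for a in fit.accessions]
    T_full = fit.whitening()
    yw_full = T_full @ fit.y
    X0w_full = T_full @ fit.X0
    rss0_full = _rss(X0w_full, yw_full)
    ones = np.ones((fit.n, 1))
    tss_full = _rss(T_full @ ones, yw_full)

    records = []
    for m in panel.marker_ids:
        calls = panel.calls[rows_panel, panel.marker_index(m)]
        dummies, keep, n_classes = _marker_design(calls, rare_policy, rare_threshold)
        if dummies is None:
            logger.info("marker_scan: skipping %s (monomorphic among complete cases)",
                        m)
            continue
        q = dummies.shape[1]
        if keep.all() and not exact_reml:
            yw, X0w, rss0, tss = yw_full, X0w_full, rss0_full, tss_full
            Xm = np.column_stack([fit.X0, dummies])
            Xmw = T_full @ Xm
            n_used = fit.n
        else:
            sub = np.flatnonzero(keep)
            ids_sub = [fit.accessions[i] for i in sub]
            if exact_reml and K_for_refit is not None:
                y_sub = pd.Series(fit.y[sub], index=ids_sub)
                subfit = fit_null_mlm(y_sub, Q_for_refit, K_for_refit,
                                      fit.trait, fit.environment)
                T = subfit.whitening()
                yv, X0s = subfit.y, subfit.X0
            else:
                V = fit.K[np.ix_(sub, sub)] + fit.delta * np.eye(sub.size)
                L = np.linalg.cholesky(V)
                T = np.linalg.inv(L)
                yv, X0s = fit.y[sub], fit.X0[sub, :]
            yw = T @ yv
            X0w = T @ X0s
            rss0 = _rss(X0w, yw)
            tss = _rss(T @ np.ones((sub.size, 1)), yw)
            Xmw = T @ np.column_stack([X0s, dummies])
            n_used = sub.size
        rss1 = _rss(Xmw, yw)
        df2 = n_used - Xmw.shape[1]
        if df2 <= 0:
            logger.info("marker_scan: skipping %s (no residual df)", m)
            continue
        F = max(rss0 - rss1, 0.0) / q / (rss1 / df2)
        p = float(stats.f.sf(F, q, df2))
        records.append(
            {
                "marker": m,
                "trait": fit.trait,
                "environment": fit.environment,
                "neg_log10_p": float(-np.log10(max(p, 1e-300))),
                "p_value": p,
                "marker_R2": float(max(rss0 - rss1, 0.0) / tss) if tss > 0 else np.nan,
                "n_used": int(n_used),
                "df_marker": int(q),
                "n_classes": int(n_classes),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# thresholds and stability
# ---------------------------------------------------------------------------


def bonferroni_threshold(m: int, alpha: float) -> float:
    """-log10(alpha / m): the family-wise significance line on the -log10 scale."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / m))


def scan_all(
    panel: GenotypePanel,
    pheno: PhenotypeTable,
    Q: pd.DataFrame | None,
    K: KinshipMatrix,
    traits: list[str] | None = None,
    environments: list[str] | None = None,
    alpha: float = 0.05,
    detect_alpha: float = 0.01,
    rare_policy: str = "pool",
) -> pd.DataFrame:
    """Per trait x environment Q+K scans with Bonferroni and detection flags.

    ``significant_bonferroni`` marks -log10 p >= -log10(alpha / n_markers);
    ``detected`` marks the looser per-test level ``detect_alpha`` used when
    counting cross-environment detections.
    """
    traits = traits or pheno.traits
    environments = environments or pheno.environments
    K = K.to_psd()  # zero-truncated kinship can be indefinite
    lm = line_means(pheno, "per_environment")
    threshold = bonferroni_threshold(panel.n_markers, alpha)
    out = []
    for trait in traits:
        for env in environments:
            sub = lm[(lm["trait_name"] == trait) & (lm["environment_id"] == env)]
            y = sub.set_index("accession_id")["mean_value"]
            if y.empty:
                continue
            fit = fit_null_mlm(y, Q, K, trait=trait, environment=env)
            rec = marker_scan(fit, panel, rare_policy=rare_policy)
            out.append(rec)
    records = pd.concat(out, ignore_index=True)
    records["significant_bonferroni"] = records["neg_log10_p"] >= threshold
    records["detected"] = records["p_value"] <= detect_alpha
    return records


def stability_filter(
    records: pd.DataFrame,
    min_env: int = 2,
    flag_column: str = "significant_bonferroni",
) -> pd.DataFrame:
    """Flag marker x trait combinations significant in >= min_env environments."""
    counts = (
        records[records[flag_column]]
        .groupby(["marker", "trait"])["environment"]
        .nunique()
        .rename("n_env_significant")
    )
    out = records.merge(counts, on=["marker", "trait"], how="left")
    out["n_env_significant"] = out["n_env_significant"].fillna(0).astype(int)
    out["stable"] = out["n_env_significant"] >= min_env
    return out


def stability_summary(
    records: pd.DataFrame,
    min_env: int = 2,
    flag_column: str = "significant_bonferroni",
) -> dict[str, float]:
    """Counts of associations (marker x trait with >=1 flagged environment)
    and the share detected in >= min_env environments."""
    flagged = records[records[flag_column]]
    counts = flagged.groupby(["marker", "trait"])["environment"].nunique()
    n_assoc = int(len(counts))
    n_stable = int((counts >= min_env).sum())
    pct = 100.0 * n_stable / n_assoc if n_assoc else float("nan")
    return {"n_associations": n_assoc, "n_stable": n_stable, "pct_stable": pct}
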