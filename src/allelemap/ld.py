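"""Pairwise multi-allelic linkage disequilibrium and its decay with distance.

For a pair of multi-allelic loci scored on homozygous lines (treated as
haplotypes), every allele pair (i at A, j at B) is collapsed to a 2x2 table
and r2_ij = (p_ij - p_i q_j)^2 / (p_i (1-p_i) q_j (1-q_j)); the reported
statistic is the weighted average sum_ij p_i q_j r2_ij, with rare alleles
(frequency < 0.05) treated as missing data before frequencies are recomputed.

Significance is a two-sided Fisher exact test for biallelic x biallelic pairs
and otherwise a Monte-Carlo permutation test of one locus, implemented by
sampling contingency tables with the observed margins (Patefield algorithm),
which is exactly the permutation null.

Background LD is the nearest-rank 99th percentile of r2 among unlinked pairs;
the decay curve is the least-squares logarithmic regression r2 = a + b ln(d)
over linked, significant pairs, from which threshold-crossing distances are
read off.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypePanel
from .diversity import RARE_FREQUENCY

logger = logging.getLogger(__name__)

#: Sentinel for a threshold the fitted curve never crosses in range.
NOT_REACHED = None


# ---------------------------------------------------------------------------
# pairwise r2
# ---------------------------------------------------------------------------


def _mask_rare(calls: np.ndarray) -> np.ndarray:
    """Set calls carrying a rare (<0.05) allele to MISSING; single pass."""
    out = calls.copy()
    typed = out != MISSING
    if not typed.any():
        return out
    codes, counts = np.unique(out[typed], return_counts=True)
    freqs = counts / counts.sum()
    for a, p in zip(codes, freqs):
        if p < RARE_FREQUENCY:
            out[out == a] = MISSING
    return out


def _joint_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint count table over lines typed at both loci, after rare masking."""
    a = _mask_rare(a)
    b = _mask_rare(b)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    codes_a = np.unique(a)
    codes_b = np.unique(b)
    table = np.zeros((codes_a.size, codes_b.size), dtype=np.int64)
    for i, ca in enumerate(codes_a):
        sel = a == ca
        for j, cb in enumerate(codes_b):
            table[i, j] = int(np.sum(sel & (b == cb)))
    return table, codes_a, codes_b


def _weighted_r2_from_table(table: np.ndarray) -> float:
    """Weighted multi-allelic r2 from a joint count table (may be batched).

    Accepts shape (ka, kb) or (batch, ka, kb).
    """
    t = np.asarray(table, dtype=float)
    squeeze = t.ndim == 2
    if squeeze:
        t = t[None, :, :]
    n = t.sum(axis=(1, 2), keepdims=True)
    pij = t / n
    pi = pij.sum(axis=2, keepdims=True)  # (batch, ka, 1)
    qj = pij.sum(axis=1, keepdims=True)  # (batch, 1, kb)
    denom = pi * (1 - pi) * qj * (1 - qj)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2ij = (pij - pi * qj) ** 2 / denom
    weights = pi * qj
    r2ij = np.where(denom > 0, r2ij, 0.0)
    out = (weights * r2ij).sum(axis=(1, 2))
    return float(out[0]) if squeeze else out


def pairwise_r2(
    panel: GenotypePanel,
    marker_a: str,
    marker_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Weighted r2 and significance for one locus pair.

    Returns ``(r2, p_value)``; p is a Fisher exact test when both loci are
    biallelic after rare-allele masking, otherwise a Monte-Carlo permutation
    p-value with resolution 1/(n_perm+1) (NaN when ``n_perm == 0``).
    Raises ``ValueError`` if either locus is monomorphic after masking.
    """
    a = panel.calls_for(marker_a)
    b = panel.calls_for(marker_b)
    table, codes_a, codes_b = _joint_counts(a, b)
    if codes_a.size < 2 or codes_b.size < 2:
        raise ValueError(
            f"pair ({marker_a}, {marker_b}): locus monomorphic after rare masking"
        )
    r2 = _weighted_r2_from_table(table)
    if codes_a.size == 2 and codes_b.size == 2:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return r2, float(p)
    if n_perm <= 0:
        return r2, float("nan")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sampled = dist.rvs(size=n_perm, random_state=rng)  # (n_perm, ka, kb)
    r2_null = _weighted_r2_from_table(sampled)
    p = (1.0 + np.sum(r2_null >= r2 - 1e-12)) / (1.0 + n_perm)
    return r2, float(p)


# ---------------------------------------------------------------------------
# panel-wide scan and summaries
# ---------------------------------------------------------------------------


def ld_scan(
    panel: GenotypePanel,
    n_perm: int = 1000,
    seed: int = 0,
    markers: list[str] | None = None,
    max_pairs_per_chrom: int | None = None,
) -> pd.DataFrame:
    """All pairwise r2/p values with linkage status and cM distance.

    ``max_pairs_per_chrom`` subsamples linked pairs per chromosome (plus a
    matching random share of unlinked pairs), for quick reconnaissance runs.
    Pairs where a locus goes monomorphic after rare masking are skipped with a
    log entry.
    """
    if panel.map is None:
        raise ValueError("panel has no genetic map")
    ids = markers if markers is not None else panel.marker_ids
    chrom = {m: panel.map.chromosome(m) for m in ids}
    pos = {m: panel.map.position(m) for m in ids}
    pairs = list(itertools.combinations(ids, 2))
    if max_pairs_per_chrom is not None:
        rng = np.random.default_rng(seed)
        linked_pairs = [p for p in pairs if chrom[p[0]] == chrom[p[1]]]
        unlinked_pairs = [p for p in pairs if chrom[p[0]] != chrom[p[1]]]
        by_chrom: dict[str, list] = {}
        for p in linked_pairs:
            by_chrom.setdefault(chrom[p[0]], []).append(p)
        sel = []
        for plist in by_chrom.values():
            take = min(len(plist), max_pairs_per_chrom)
            sel.extend(plist[i] for i in rng.choice(len(plist), take, replace=False))
        n_unlinked = min(len(unlinked_pairs), max(len(sel), 100))
        sel.extend(
            unlinked_pairs[i]
            for i in rng.choice(len(unlinked_pairs), n_unlinked, replace=False)
        )
        pairs = sel
    rows = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(pairs)) % (2**31)
    for (ma, mb), s in zip(pairs, child_seeds):
        try:
            r2, p = pairwise_r2(panel, ma, mb, n_perm=n_perm, seed=int(s))
        except ValueError:
            logger.info("ld_scan: skipping pair (%s, %s): monomorphic after masking",
                        ma, mb)
            continue
        linked = chrom[ma] == chrom[mb]
        rows.append(
            {
                "marker_a": ma,
                "marker_b": mb,
                "r2": r2,
                "p_value": p,
                "linked": linked,
                "distance_cM": abs(pos[ma] - pos[mb]) if linked else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ld_summary(pairs: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Mean r2 and percent significant for total / linked / unlinked strata."""
    rows = []
    for name, sub in (
        ("total", pairs),
        ("linked", pairs[pairs["linked"]]),
        ("unlinked", pairs[~pairs["linked"]]),
    ):
        if sub.empty:
            warnings.warn(f"ld_summary: stratum {name!r} is empty")
            rows.append({"stratum": name, "n_pairs": 0,
                         "mean_r2": np.nan, "pct_significant": np.nan})
            continue
        rows.append(
            {
                "stratum": name,
                "n_pairs": len(sub),
                "mean_r2": float(sub["r2"].mean()),
                "pct_significant": float(100.0 * (sub["p_value"] <= alpha).mean()),
            }
        )
    return pd.DataFrame(rows)


def background_ld(unlinked_r2: np.ndarray | pd.Series) -> float:
    """Nearest-rank 99th percentile of r2 among unlinked pairs."""
    vals = np.sort(np.asarray(unlinked_r2, dtype=float))
    if vals.size == 0:
        raise ValueError("no unlinked pairs")
    if vals.size < 100:
        warnings.warn(
            f"background_ld: only {vals.size} unlinked pairs (>=100 recommended)"
        )
    rank = int(np.ceil(0.99 * vals.size))
    return float(vals[rank - 1])


# ---------------------------------------------------------------------------
# decay curve
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    """Logarithmic decay r2 = a + b ln(d) and threshold crossings.

    ``crossings`` maps each threshold to the distance d* = exp((t - a)/b) in
    cM, or ``None`` (NOT_REACHED) when the curve never crosses it within
    [min observed d, 10 x max observed d].
    """

    a: float
    b: float
    background_r2: float | None
    crossings: dict[float, float | None] = field(default_factory=dict)
    n_pairs: int = 0

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.log(np.asarray(d, dtype=float))


def fit_decay(
    linked_pairs: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.1, 0.2),
    background_r2: float | None = None,
    alpha: float = 0.01,
) -> DecayFit:
    """Least-squares fit of r2 = a + b ln(d) over linked, significant pairs.

    ``linked_pairs`` needs columns r2, distance_cM and (unless already
    filtered) p_value; pairs with p <= alpha and distance > 0 enter the fit.
    The background level, if given, is prepended to the crossing thresholds.
    """
    sub = linked_pairs
    if "p_value" in sub.columns:
        sub = sub[sub["p_value"] <= alpha]
    sub = sub[(sub["distance_cM"] > 0) & np.isfinite(sub["distance_cM"])]
    if len(sub) < 3 or sub["distance_cM"].nunique() < 2:
        raise ValueError("need >=3 linked significant pairs at distinct distances")
    d = sub["distance_cM"].to_numpy(dtype=float)
    r2 = sub["r2"].to_numpy(dtype=float)
    b, a = np.polyfit(np.log(d), r2, 1)
    all_thresholds = list(thresholds)
    if background_r2 is not None:
        all_thresholds = [background_r2] + all_thresholds
    crossings: dict[float, float | None] = {}
    d_lo, d_hi = float(d.min()), 10.0 * float(d.max())
    if b >= 0:
        warnings.warn("fit_decay: non-negative slope, no crossing reached")
    for t in all_thresholds:
        if b >= 0:
            crossings[t] = NOT_REACHED
            continue
        d_star = float(np.exp((t - a) / b))
        crossings[t] = d_star if d_lo <= d_star <= d_hi else NOT_REACHED
    return DecayFit(float(a), float(b), background_r2, crossings, n_pairs=len(sub))


def plot_decay(pairs: pd.DataFrame, fit: DecayFit, path, alpha: float = 0.01) -> None:
    """Scatter of linked significant pairs with the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = pairs[pairs["linked"] & (pairs["p_value"] <= alpha) & (pairs["distance_cM"] > 0)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(sub["distance_cM"], sub["r2"], s=8, alpha=0.5)
    if len(sub):
        grid = np.linspace(sub["distance_cM"].min(), sub["distance_cM"].max(), 200)
        ax.plot(grid, fit.predict(grid), color="crimson")
    if fit.background_r2 is not None:
        ax.axhline(fit.background_r2, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("genetic distance (cM)")
    ax.set_ylabel(r"$r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
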