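"""Population structure and kinship.

Three ingredients feed the mixed-model scan:

* the Evanno delta-k statistic on replicate log-likelihoods LnP(D) selects
  the number of subpopulations k;
* a Q matrix of admixture proportions — canonically imported from an external
  Bayesian clustering run, with a lightweight multiplicative-EM surrogate
  (:func:`estimate_Q_em`) for self-contained runs — with the >0.5 membership
  rule for hard assignment;
* the Loiselle et al. (1995) kinship estimator on homozygous lines, with
  negative values truncated to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

#: Label for accessions with no membership above 0.5.
ADMIXED = "ADMIXED"


# ---------------------------------------------------------------------------
# Evanno delta-k
# ---------------------------------------------------------------------------


def delta_k(lnp_runs: dict[int, list[float]]) -> tuple[dict[int, float], int]:
    """Evanno's ad hoc statistic on replicate LnP(D) values.

    delta_k(k) = |mean L(k+1) - 2 mean L(k) + mean L(k-1)| / sd(L(k)),
    defined for interior k with at least two replicates; the chosen k is the
    argmax, ties broken toward smaller k (parsimony) with a warning.
    """
    ks = sorted(lnp_runs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need at least 3 consecutive k values")
    means = {k: float(np.mean(lnp_runs[k])) for k in ks}
    out: dict[int, float] = {}
    for k in ks[1:-1]:
        reps = np.asarray(lnp_runs[k], dtype=float)
        if reps.size < 2:
            raise ValueError(f"k={k}: need >=2 replicates for the interior sd")
        sd = float(np.std(reps, ddof=1))
        if sd == 0.0:
            raise ValueError(f"k={k}: replicate sd is zero, delta-k undefined")
        out[k] = abs(means[k + 1] - 2.0 * means[k] + means[k - 1]) / sd
    best = max(out.values())
    winners = [k for k, v in out.items() if v == best]
    if len(winners) > 1:
        warnings.warn(f"delta-k tie at k={winners}; choosing the smallest")
    return out, min(winners)


def lnp_replicates_em(
    panel: GenotypePanel,
    ks: range | list[int],
    n_reps: int = 3,
    seed: int = 0,
    max_iter: int = 200,
) -> dict[int, list[float]]:
    """Replicate maximized log-likelihoods across k from the EM surrogate.

    Feeds :func:`delta_k` when no external clustering run is available; the
    replicate spread comes from random EM initializations.
    """
    out: dict[int, list[float]] = {}
    for k in ks:
        out[int(k)] = [
            estimate_Q_em(panel, int(k), seed=seed * 1000 + k * 17 + r,
                          max_iter=max_iter)[1][-1]
            for r in range(n_reps)
        ]
    return out


def read_lnp_table(path) -> dict[int, list[float]]:
    """Two-column (k, LnP(D)) replicate table -> k -> replicate list."""
    frame = pd.read_csv(path, sep=None, engine="python")
    out: dict[int, list[float]] = {}
    for _, row in frame.iterrows():
        out.setdefault(int(row.iloc[0]), []).append(float(row.iloc[1]))
    return out


# ---------------------------------------------------------------------------
# Q matrix
# ---------------------------------------------------------------------------


def assign_subpopulations(Q: pd.DataFrame) -> pd.Series:
    """Hard assignment by the Q>0.5 rule; otherwise ADMIXED.

    Q rows must sum to 1 within 1e-6.  Returned labels are 1-based subpopulation
    numbers (as strings the column names, if informative) or ``ADMIXED``.
    """
    vals = Q.to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = Q.index[np.abs(sums - 1.0) > 1e-6].tolist()
        raise ValueError(f"Q rows do not sum to 1: {bad[:5]}")
    best = vals.argmax(axis=1)
    labels = [
        Q.columns[b] if vals[i, b] > 0.5 else ADMIXED for i, b in enumerate(best)
    ]
    return pd.Series(labels, index=Q.index, name="subpop")


def read_q_matrix(path) -> pd.DataFrame:
    """Whitespace/tab table: accession label followed by k membership columns."""
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    frame.columns = [f"Q{j + 1}" for j in range(frame.shape[1])]
    return frame.astype(float)


def write_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t")


def structure_covariates(Q: pd.DataFrame) -> pd.DataFrame:
    """Drop the last membership column so Q is not collinear with the intercept."""
    return Q.iloc[:, :-1]


def select_structure_markers(panel: GenotypePanel, min_spacing_cM: float = 20.0) -> list[str]:
    """Thin the map to roughly one marker per ``min_spacing_cM`` for structure runs."""
    if panel.map is None:
        raise ValueError("panel has no genetic map")
    chosen: list[str] = []
    for _, grp in panel.map.frame.groupby("chromosome", sort=False):
        last = -np.inf
        for _, row in grp.sort_values("position_cM").iterrows():
            if row["position_cM"] - last >= min_spacing_cM:
                chosen.append(row["marker_id"])
                last = row["position_cM"]
    return chosen


def estimate_Q_em(
    panel: GenotypePanel,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, list[float]]:
    """Admixture proportions by multiplicative EM on haploid/inbred calls.

    Maximizes sum_i sum_l log( sum_c q_ic f_cl(a_il) ) over memberships q and
    subpopulation allele frequencies f.  A convenience surrogate for an
    external Bayesian clustering run, not a replacement for it.  The
    log-likelihood is asserted non-decreasing each iteration.
    """
    n, m = panel.n_accessions, panel.n_markers
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of accessions ({n})")
    rng = np.random.default_rng(seed)
    calls = panel.calls
    n_alleles = [int(calls[:, l].max()) if (calls[:, l] != MISSING).any() else 1
                 for l in range(m)]

    if k == 1:
        Q = pd.DataFrame(np.ones((n, 1)), index=panel.accession_ids, columns=["Q1"])
        ll = 0.0
        for l in range(m):
            col = calls[:, l]
            typed = col != MISSING
            if not typed.any():
                continue
            codes, counts = np.unique(col[typed], return_counts=True)
            p = counts / counts.sum()
            freq = dict(zip(codes, p))
            ll += float(sum(np.log(freq[c]) for c in col[typed]))
        return Q, [ll]

    # init: k-means on the one-hot genotype matrix gives hard seeds
    onehot_cols = []
    for l in range(m):
        col = calls[:, l]
        for a in range(1, n_alleles[l] + 1):
            onehot_cols.append((col == a).astype(float))
    X = np.vstack(onehot_cols).T if onehot_cols else np.zeros((n, 1))
    try:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31)))
        hard = km.fit_predict(X)
    except Exception:  # pragma: no cover - sklearn always present in practice
        hard = rng.integers(0, k, size=n)
    q = np.full((n, k), 0.1 / max(k - 1, 1))
    q[np.arange(n), hard] = 0.9
    q = q / q.sum(axis=1, keepdims=True)

    pseudo = 1e-6
    # f[l]: k x n_alleles[l], initialized from the hard seed clusters so the
    # first E step already separates the components
    f = []
    for l in range(m):
        col = calls[:, l]
        fl = np.full((k, n_alleles[l]), pseudo)
        for c in range(k):
            sub = col[(hard == c) & (col != MISSING)]
            for a in range(1, n_alleles[l] + 1):
                fl[c, a - 1] += np.sum(sub == a)
        fl = fl / fl.sum(axis=1, keepdims=True)
        f.append(fl)

    def loglik_and_resp():
        ll = 0.0
        resp_sum_q = np.zeros((n, k))  # sum over loci of responsibilities
        resp_count = np.zeros(n)
        new_f = [np.full_like(fl, pseudo) for fl in f]
        for l in range(m):
            col = calls[:, l]
            typed = np.flatnonzero(col != MISSING)
            if typed.size == 0:
                continue
            a_idx = col[typed] - 1
            like = q[typed, :] * f[l][:, a_idx].T  # (n_typed, k)
            tot = like.sum(axis=1)
            ll += float(np.log(tot).sum())
            r = like / tot[:, None]
            resp_sum_q[typed, :] += r
            resp_count[typed] += 1
            np.add.at(new_f[l].T, a_idx, r)  # accumulate per allele
        return ll, resp_sum_q, resp_count, new_f

    lls: list[float] = []
    for it in range(max_iter):
        ll, rq, rc, new_f = loglik_and_resp()
        if lls:
            assert ll >= lls[-1] - 1e-6 * (1 + abs(lls[-1])), "EM log-likelihood decreased"
        lls.append(ll)
        # M step
        rc = np.maximum(rc, 1)
        q_new = rq / rc[:, None]
        q_new = np.clip(q_new, pseudo, None)
        q_new = q_new / q_new.sum(axis=1, keepdims=True)
        f_new = []
        for fl in new_f:
            fl = fl / fl.sum(axis=1, keepdims=True)
            f_new.append(fl)
        q, f = q_new, f_new
        if len(lls) >= 2 and lls[-1] - lls[-2] < tol * (1 + abs(lls[-2])):
            break
    Q = pd.DataFrame(q, index=panel.accession_ids,
                     columns=[f"Q{j + 1}" for j in range(k)])
    return Q, lls


# ---------------------------------------------------------------------------
# Loiselle kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix, negatives truncated at zero."""

    values: np.ndarray
    accession_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)

    def align(self, accessions: list[str]) -> np.ndarray:
        idx = [self.accession_ids.index(a) for a in accessions]
        return self.values[np.ix_(idx, idx)]

    def to_psd(self) -> "KinshipMatrix":
        """Nearest positive-semidefinite projection (negative eigenvalues
        clipped to zero).

        The zero-truncation of negative kinship estimates can leave the matrix
        indefinite; the mixed model needs a valid covariance, so the standard
        remedy is an eigenvalue clip before fitting.
        """
        D, U = np.linalg.eigh(self.values)
        if D.min() >= 0:
            return self
        K = (U * np.clip(D, 0.0, None)) @ U.T
        K = (K + K.T) / 2.0
        return KinshipMatrix(K, list(self.accession_ids))


def loiselle_kinship(
    panel: GenotypePanel, small_sample_correction: bool = False
) -> KinshipMatrix:
    """Loiselle et al. (1995) pairwise kinship for homozygous lines.

    F_ij = sum_l sum_a (x_ila - p_la)(x_jla - p_la) / sum_l sum_a p_la (1 - p_la)

    with x the 0/1 individual allele frequency and p the panel frequency.
    Loci missing for either member of a pair drop out of both sums; negative
    estimates are truncated to zero.  The optional small-sample correction
    adds p(1-p)/(n_l - 1) per allele to the numerator.
    """
    n, m = panel.n_accessions, panel.n_markers
    if n < 2:
        raise ValueError("need at least 2 accessions")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    any_poly = False
    for l in range(m):
        col = panel.calls[:, l]
        typed = col != MISSING
        n_l = int(typed.sum())
        if n_l < 2:
            continue
        codes = np.unique(col[typed])
        if codes.size < 2:
            continue  # monomorphic locus carries no information
        any_poly = True
        p = np.array([(col[typed] == a).mean() for a in codes])
        X = np.zeros((n, codes.size))
        for j, a in enumerate(codes):
            X[:, j] = col == a
        A = X - p[None, :]
        A[~typed, :] = 0.0
        contrib = A @ A.T
        if small_sample_correction:
            contrib += float(np.sum(p * (1 - p)) / (n_l - 1))
        pair_mask = np.outer(typed, typed)
        num += np.where(pair_mask, contrib, 0.0)
        den += np.where(pair_mask, float(np.sum(p * (1 - p))), 0.0)
    if not any_poly:
        raise ValueError("no polymorphic locus in panel")
    with np.errstate(invalid="ignore", divide="ignore"):
        K = num / den
    if np.isnan(K).any():
        n_bad = int(np.isnan(K).sum())
        warnings.warn(f"{n_bad} kinship cells have no shared typed locus (set NaN)")
    K = np.where(np.isnan(K), np.nan, np.maximum(K, 0.0))
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(panel.accession_ids))
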