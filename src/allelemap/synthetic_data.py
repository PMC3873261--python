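"""Structured synthetic panels for offline testing of the analysis chain.

The generator emulates the statistical shape of a historical germplasm panel
of selfed (homozygous) lines scored at multi-allelic SSR loci:

* two (or more) diverged but admixed subpopulations, with subpopulation allele
  frequencies drawn around a shared ancestral frequency vector under a
  Balding-Nichols-style divergence model parameterized by Fst;
* chromosomes built as founder-haplotype mosaics recombined for a configurable
  number of generations at genetic-map distances (Haldane map function), so
  linkage disequilibrium decays with cM distance;
* seven correlated yield traits measured in multiple environments with two
  replicates, composed of QTL allele effects, a marker-driven polygenic line
  effect (hence correlated with kinship), genotype-by-environment deviations
  and replicate error, with realized broad-sense heritabilities in the
  0.3-0.75 band typical of such trials.

Lines are represented by a single haplotype; doubling to homozygosity is
implicit.  All randomness flows from one seed via named sub-streams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    AccessionMeta,
    GeneticMap,
    GenotypePanel,
    PhenotypeTable,
    YIELD_TRAITS,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSpec:
    """Generative variance model for one trait.

    ``sigma2_g`` is the polygenic line variance (QTL effects add on top),
    ``sigma2_ge`` the genotype-by-environment variance, ``sigma2_e`` the
    replicate (plot) error variance, all in squared trait units.
    ``env_effect_sd`` scales fixed environment offsets around the grand mean.
    """

    grand_mean: float
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    env_effect_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    def heritability(self, n_env: int, n_rep: int) -> float:
        """Entry-mean broad-sense heritability implied by the components."""
        denom = self.sigma2_g + self.sigma2_ge / n_env + self.sigma2_e / (n_env * n_rep)
        return self.sigma2_g / denom if denom > 0 else float("nan")


@dataclass(frozen=True)
class QTLSpec:
    """A marker whose allele codes shift a trait additively."""

    marker_id: str
    trait: str
    allele_effects: Mapping[int, float]  # allele code -> effect in trait units


def _default_trait_specs(n_env: int = 3, n_rep: int = 2) -> dict[str, TraitSpec]:
    """Trait models matching the descriptive scale of a lint-yield trial.

    Grand means, coefficients of variation and entry-mean heritabilities are
    set to the magnitudes typical for LY/SY/BN/BW/LP/LI/SI in multi-location
    upland cotton trials (h2 roughly 0.27-0.76, CV roughly 9-29%).  The
    non-genetic remainder is split evenly between GxE and plot error on the
    entry-mean scale.
    """
    targets = {
        # trait: (grand mean, CV% of line means, entry-mean h2)
        "LY": (22.57, 29.09, 0.691),
        "SY": (62.68, 23.19, 0.550),
        "BN": (17.96, 19.36, 0.509),
        "BW": (4.76, 9.11, 0.610),
        "LP": (35.98, 9.33, 0.758),
        "LI": (6.15, 12.48, 0.711),
        "SI": (10.96, 9.02, 0.611),
    }
    specs = {}
    for trait, (mean, cv, h2) in targets.items():
        var_p = (cv / 100.0 * mean) ** 2  # variance of line means
        s2g = h2 * var_p
        rem = var_p - s2g  # = s2ge/n_env + s2e/(n_env*n_rep)
        s2ge = rem / 2 * n_env
        s2e = rem / 2 * n_env * n_rep
        specs[trait] = TraitSpec(mean, s2g, s2ge, s2e, env_effect_sd=0.15 * mean)
    return specs


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the panel generator; defaults mirror the target study design."""

    n_accessions: int = 356
    n_loci: int = 145
    n_chromosomes: int = 26
    chrom_length_cM: float = 150.0
    alleles_per_locus_range: tuple[int, int] = (2, 9)
    n_subpops: int = 2
    divergence_Fst: float = 0.10
    admixture_alpha: float = 0.2
    generations_of_mating: int = 10
    n_founder_haplotypes: int = 6
    missing_rate: float = 0.02
    n_env: int = 3
    n_rep: int = 2
    qtl_spec: tuple[QTLSpec, ...] = ()
    trait_spec: Mapping[str, TraitSpec] = field(default_factory=_default_trait_specs)
    era_assignment: Mapping[str, float] = field(
        default_factory=lambda: {
            # proportions follow the historical cohort sizes of the panel design
            "CK": 6 / 356, "I": 26 / 356, "II": 26 / 356, "III": 39 / 356,
            "IV": 83 / 356, "V": 125 / 356, "VI": 49 / 356, "other": 2 / 356,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alleles_per_locus_range
        if not (2 <= lo <= hi <= 9):
            raise ValueError("alleles_per_locus_range must lie within [2, 9]")
        for p in (self.divergence_Fst, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must be in [0, 1]")
        if self.admixture_alpha <= 0:
            raise ValueError("admixture_alpha must be positive")
        for q in self.qtl_spec:
            if q.trait not in self.trait_spec:
                raise ValueError(f"QTL trait {q.trait!r} has no trait_spec")
            if not all(np.isfinite(list(q.allele_effects.values()))):
                raise ValueError("QTL effects must be finite")


def default_qtls(n_loci: int = 145) -> tuple[QTLSpec, ...]:
    """A small default QTL architecture on the deterministic marker grid.

    Effects are moderate (a fraction of a phenotypic SD) and two markers are
    shared between correlated traits so that trait correlations have a genetic
    component.  Marker ids follow the generator's ``M{index:04d}`` scheme and
    are spread over the locus range.
    """
    at = [int(round(f * (n_loci - 1))) for f in (0.05, 0.25, 0.5, 0.7, 0.9)]
    m = [f"M{i:04d}" for i in at]
    # allele-class gaps sized so each QTL explains roughly 8-12% of the
    # phenotypic variance of line means, the upper range of detectable
    # yield QTLs in germplasm panels
    return (
        QTLSpec(m[0], "LY", {1: 2.0, 2: -2.0}),
        QTLSpec(m[0], "SY", {1: 5.0, 2: -5.0}),  # shared with LY
        QTLSpec(m[1], "BN", {1: 1.2, 2: -1.2}),
        QTLSpec(m[2], "BW", {1: 0.15, 2: -0.15}),
        QTLSpec(m[3], "LP", {1: 1.2, 2: -1.2}),
        QTLSpec(m[3], "LI", {1: 0.28, 2: -0.28}),  # shared with LP
        QTLSpec(m[4], "SI", {1: 0.35, 2: -0.35}),
    )


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    """Ground truth stored alongside the generated artifacts."""

    subpop_membership: list[int]  # argmax of admixture proportions per line
    admixture: np.ndarray  # n_accessions x n_subpops
    subpop_freqs: list[np.ndarray]  # per locus: n_subpops x n_alleles
    ancestral_freqs: list[np.ndarray]  # per locus: n_alleles
    qtl_spec: tuple[QTLSpec, ...]
    genetic_values: pd.DataFrame  # accession x trait total genetic value
    realized_components: pd.DataFrame  # trait x (sigma2_g, sigma2_ge, sigma2_e, h2)

    def to_json(self) -> str:
        payload = {
            "subpop_membership": self.subpop_membership,
            "admixture": self.admixture.tolist(),
            "qtl_spec": [
                {"marker_id": q.marker_id, "trait": q.trait,
                 "allele_effects": {str(k): v for k, v in q.allele_effects.items()}}
                for q in self.qtl_spec
            ],
            "realized_components": self.realized_components.to_dict(orient="index"),
        }
        return json.dumps(payload, indent=2)


@dataclass
class SimulationResult:
    panel: GenotypePanel
    phenotypes: PhenotypeTable
    meta: list[AccessionMeta]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _build_map(cfg: SimulationConfig, rng: np.random.Generator) -> GeneticMap:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_loci // cfg.n_chromosomes)
    per_chrom[: cfg.n_loci % cfg.n_chromosomes] += 1
    rows = []
    idx = 0
    for c in range(cfg.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, cfg.chrom_length_cM, size=per_chrom[c]))
        for p in pos:
            rows.append((f"M{idx:04d}", f"chr{c + 1:02d}", round(float(p), 3)))
            idx += 1
    return GeneticMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM"]))


#: Allele-count distribution over 2..9, skewed so ~80% of loci carry 2-3 alleles.
_ALLELE_COUNT_WEIGHTS = np.array([0.45, 0.35, 0.08, 0.05, 0.03, 0.02, 0.01, 0.01])


def _draw_allele_counts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.alleles_per_locus_range
    support = np.arange(2, 10)
    keep = (support >= lo) & (support <= hi)
    w = _ALLELE_COUNT_WEIGHTS[keep] / _ALLELE_COUNT_WEIGHTS[keep].sum()
    return rng.choice(support[keep], size=cfg.n_loci, p=w)


def _draw_frequencies(
    cfg: SimulationConfig, counts: np.ndarray, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Ancestral and per-subpopulation allele frequencies (Balding-Nichols)."""
    fst = cfg.divergence_Fst
    anc_list, sub_list = [], []
    for k in counts:
        anc = rng.dirichlet(np.full(k, 0.6))
        anc = np.clip(anc, 1e-4, None)
        anc = anc / anc.sum()
        if fst <= 1e-12:
            subs = np.tile(anc, (cfg.n_subpops, 1))
        else:
            conc = anc * (1.0 - fst) / fst
            subs = np.vstack([rng.dirichlet(conc) for _ in range(cfg.n_subpops)])
            subs = np.clip(subs, 1e-6, None)
            subs = subs / subs.sum(axis=1, keepdims=True)
        anc_list.append(anc)
        sub_list.append(subs)
    return anc_list, sub_list


def _haldane_switch_prob(d_cM: np.ndarray, generations: int) -> np.ndarray:
    """P(ancestry/founder segment break between adjacent markers).

    Per-meiosis recombination fraction from the Haldane map function,
    compounded over the mating generations.
    """
    r = 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))
    return 1.0 - (1.0 - r) ** generations


def _simulate_genotypes(
    cfg: SimulationConfig,
    gmap: GeneticMap,
    sub_freqs: list[np.ndarray],
    admixture: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder-mosaic haplotypes for every line (one haplotype per line)."""
    n = cfg.n_accessions
    # founder haplotype pools, one per subpopulation, drawn locus-independently
    founders = np.zeros((cfg.n_subpops, cfg.n_founder_haplotypes, cfg.n_loci), dtype=np.int16)
    for l, freqs in enumerate(sub_freqs):
        k = freqs.shape[1]
        for c in range(cfg.n_subpops):
            founders[c, :, l] = rng.choice(
                np.arange(1, k + 1), size=cfg.n_founder_haplotypes, p=freqs[c]
            )

    calls = np.zeros((n, cfg.n_loci), dtype=np.int16)
    frame = gmap.frame
    for chrom, grp in frame.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["position_cM"].to_numpy()
        switch = _haldane_switch_prob(np.diff(pos), cfg.generations_of_mating)
        # initial ancestry + founder per line
        anc = np.array([rng.choice(cfg.n_subpops, p=admixture[i]) for i in range(n)])
        fou = rng.integers(0, cfg.n_founder_haplotypes, size=n)
        calls[:, idx[0]] = founders[anc, fou, idx[0]]
        for j in range(1, len(idx)):
            flip = rng.random(n) < switch[j - 1]
            if flip.any():
                flipped = np.flatnonzero(flip)
                for i in flipped:
                    anc[i] = rng.choice(cfg.n_subpops, p=admixture[i])
                fou[flip] = rng.integers(0, cfg.n_founder_haplotypes, size=flip.sum())
            calls[:, idx[j]] = founders[anc, fou, idx[j]]

    # alleles drawn for a locus but lost through the founder bottleneck enter
    # as low-copy variants (mutation / minor introgression) carried by a
    # handful of lines: the source of the rare- and unique-allele classes
    for l in range(cfg.n_loci):
        k = sub_freqs[l].shape[1]
        present = set(np.unique(calls[:, l]))
        for a in range(1, k + 1):
            if a in present:
                continue
            n_carriers = min(int(rng.geometric(0.6)), 5, n)
            lines = rng.choice(n, size=n_carriers, replace=False)
            calls[lines, l] = a
    return calls


def _polygenic_effect(
    calls: np.ndarray, counts: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Line effect as a sum of small random per-allele effects over all loci.

    Built from the marker genotypes themselves, the effect is automatically
    correlated with marker-based kinship.  Standardized to variance sigma2.
    """
    n = calls.shape[0]
    g = np.zeros(n)
    for l in range(calls.shape[1]):
        eff = rng.normal(0.0, 1.0, size=int(counts[l]) + 1)
        eff[0] = 0.0  # missing contributes nothing
        g += eff[calls[:, l]]
    sd = g.std()
    if sd < 1e-12:
        return np.zeros(n)
    return (g - g.mean()) / sd * np.sqrt(sigma2)


def simulate_panel(config: SimulationConfig) -> SimulationResult:
    """Generate a panel, replicated phenotypes, metadata and the truth record."""
    cfg = config
    rngs = _streams(
        cfg.seed,
        ["map", "alleles", "freqs", "admixture", "genotypes", "missing",
         "phenotypes", "meta"],
    )

    gmap = _build_map(cfg, rngs["map"])
    counts = _draw_allele_counts(cfg, rngs["alleles"])
    anc_freqs, sub_freqs = _draw_frequencies(cfg, counts, rngs["freqs"])
    admixture = rngs["admixture"].dirichlet(
        np.full(cfg.n_subpops, cfg.admixture_alpha), size=cfg.n_accessions
    )
    calls_true = _simulate_genotypes(cfg, gmap, sub_freqs, admixture, rngs["genotypes"])

    for q in cfg.qtl_spec:
        if q.marker_id not in gmap.marker_ids:
            raise ValueError(f"QTL marker {q.marker_id!r} not in map")

    # phenotypes from the un-masked genotypes
    accession_ids = [f"ACC{i:04d}" for i in range(cfg.n_accessions)]
    marker_ids = gmap.marker_ids
    marker_pos = {m: j for j, m in enumerate(marker_ids)}
    rng_ph = rngs["phenotypes"]
    env_ids = [f"E{e + 1}" for e in range(cfg.n_env)]
    rep_ids = [f"R{r + 1}" for r in range(cfg.n_rep)]

    records = []
    gen_values = {}
    realized = {}
    for trait, spec in cfg.trait_spec.items():
        qtl_effect = np.zeros(cfg.n_accessions)
        for q in cfg.qtl_spec:
            if q.trait != trait:
                continue
            col = calls_true[:, marker_pos[q.marker_id]]
            for code, eff in q.allele_effects.items():
                qtl_effect[col == code] += eff
        poly = _polygenic_effect(calls_true, counts, spec.sigma2_g, rng_ph)
        genetic = qtl_effect + poly
        gen_values[trait] = genetic
        env_off = rng_ph.normal(0.0, spec.env_effect_sd, size=cfg.n_env)
        ge = rng_ph.normal(0.0, np.sqrt(spec.sigma2_ge), size=(cfg.n_accessions, cfg.n_env))
        for e, env in enumerate(env_ids):
            for r, rep in enumerate(rep_ids):
                err = rng_ph.normal(0.0, np.sqrt(spec.sigma2_e), size=cfg.n_accessions)
                vals = spec.grand_mean + env_off[e] + genetic + ge[:, e] + err
                for i, acc in enumerate(accession_ids):
                    records.append((acc, env, rep, trait, vals[i]))
        s2g_real = float(np.var(genetic, ddof=1))
        s2ge_real = float(np.var(ge, ddof=1))
        denom = s2g_real + s2ge_real / cfg.n_env + spec.sigma2_e / (cfg.n_env * cfg.n_rep)
        realized[trait] = {
            "sigma2_g": s2g_real,
            "sigma2_ge": s2ge_real,
            "sigma2_e": spec.sigma2_e,
            "h2": s2g_real / denom if denom > 0 else float("nan"),
        }

    pheno = PhenotypeTable(
        pd.DataFrame(records, columns=PhenotypeTable.COLUMNS)
    )

    # mask missing genotypes
    calls = calls_true.copy()
    mask = rngs["missing"].random(calls.shape) < cfg.missing_rate
    calls[mask] = MISSING
    panel = GenotypePanel(accession_ids, marker_ids, calls, gmap)

    # era-group metadata; CK lines double as founders
    rng_meta = rngs["meta"]
    groups = list(cfg.era_assignment)
    probs = np.array([cfg.era_assignment[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    assign = rng_meta.choice(len(groups), size=cfg.n_accessions, p=probs)
    if not (assign == groups.index("CK")).any() and "CK" in groups:
        assign[0] = groups.index("CK")  # keep the founder group non-empty
    regions = rng_meta.choice(
        ["YellowRiver", "YangtzeRiver", "NorthNorthwest"], size=cfg.n_accessions,
        p=[0.5, 0.32, 0.18],
    )
    meta = [
        AccessionMeta(
            accession_id=acc,
            era_group=groups[assign[i]],
            region=str(regions[i]),
            is_founder=groups[assign[i]] == "CK",
        )
        for i, acc in enumerate(accession_ids)
    ]

    truth = TruthRecord(
        subpop_membership=[int(a) for a in admixture.argmax(axis=1)],
        admixture=admixture,
        subpop_freqs=sub_freqs,
        ancestral_freqs=anc_freqs,
        qtl_spec=tuple(cfg.qtl_spec),
        genetic_values=pd.DataFrame(gen_values, index=accession_ids),
        realized_components=pd.DataFrame(realized).T,
    )
    return SimulationResult(panel, pheno, meta, truth)


# ---------------------------------------------------------------------------
# realism report
# ---------------------------------------------------------------------------


@dataclass
class RealismReport:
    realized_fst: float
    mean_alleles_per_locus: float
    rare_allele_fraction: float
    ld_half_decay_cM: float
    heritability: dict[str, float]
    targets: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("realized_fst", self.realized_fst, self.targets.get("divergence_Fst")),
            ("mean_alleles_per_locus", self.mean_alleles_per_locus, None),
            ("rare_allele_fraction", self.rare_allele_fraction, None),
            ("ld_half_decay_cM", self.ld_half_decay_cM, None),
        ]
        for t, h in self.heritability.items():
            rows.append((f"h2_{t}", h, self.targets.get(f"h2_{t}")))
        return pd.DataFrame(rows, columns=["quantity", "realized", "target"])


def verify_realism(result: SimulationResult, config: SimulationConfig) -> RealismReport:
    """Compare realized panel statistics against the generator's targets."""
    from . import diversity as _div
    from . import ld as _ld

    panel = result.panel
    # realized Fst from subpopulation frequency spread at the truth memberships
    member = np.asarray(result.truth.subpop_membership)
    fst_vals = []
    for m in panel.marker_ids:
        col = panel.calls_for(m)
        typed = col != MISSING
        if typed.sum() < 4:
            continue
        alleles = np.unique(col[typed])
        for a in alleles:
            x = (col == a).astype(float)
            ps = [x[typed & (member == c)].mean() for c in range(config.n_subpops)
                  if (typed & (member == c)).sum() > 1]
            if len(ps) < 2:
                continue
            pbar = float(np.mean(ps))
            if pbar <= 0 or pbar >= 1:
                continue
            fst_vals.append(float(np.var(ps)) / (pbar * (1 - pbar)))
    realized_fst = float(np.mean(fst_vals)) if fst_vals else float("nan")

    table = _div.diversity_table(panel)
    mean_alleles = float(table["n_alleles"].mean())
    total_alleles = int(table["n_alleles"].sum())
    rare_fraction = float(table["n_rare"].sum()) / total_alleles if total_alleles else 0.0

    # LD half-decay from the fitted logarithmic curve on a linked-pair sample
    half = float("nan")
    try:
        pairs = _ld.ld_scan(panel, max_pairs_per_chrom=40, n_perm=0, seed=config.seed)
        linked = pairs[pairs["linked"] & (pairs["distance_cM"] > 0)]
        if len(linked) >= 3:
            fit = np.polyfit(np.log(linked["distance_cM"]), linked["r2"], 1)
            b, a = fit[0], fit[1]
            d_min = float(linked["distance_cM"].min())
            r0 = a + b * np.log(d_min)
            if b < 0 and r0 > 0:
                half = float(np.exp((r0 / 2 - a) / b))
    except Exception:  # pragma: no cover - report-only, never raises
        logger.warning("verify_realism: LD half-decay not computable")

    from .pheno_stats import anova_components, heritability as _h2

    h2 = {}
    for trait in result.phenotypes.traits:
        vc, _ = anova_components(result.phenotypes, trait)
        h2[trait] = _h2(vc)

    targets = {"divergence_Fst": config.divergence_Fst}
    for t, spec in config.trait_spec.items():
        targets[f"h2_{t}"] = spec.heritability(config.n_env, config.n_rep)
    return RealismReport(realized_fst, mean_alleles, rare_fraction, half, h2, targets)
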