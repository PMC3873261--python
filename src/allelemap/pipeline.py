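"""Run the whole analysis chain from a single config, with a hashed manifest.

Stages (in dependency order): simulate -> diversity -> structure -> kinship ->
ld -> pheno -> assoc -> alleles.  Every stage writes plain-text tables into the
output directory and records a content hash in ``manifest.json``; rerunning
with the same config and seed is byte-identical for deterministic stages.
Stochastic stages (simulation, EM restarts, permutation p-values) take their
seeds from the config; a missing seed is an error, not a silent default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import allele_mining, association, diversity, ld, pheno_stats, relatedness
from .core_io import (
    line_means_wide,
    read_genotypes,
    read_map,
    read_metadata,
    read_phenotypes,
    write_genotypes,
    write_map,
    write_metadata,
    write_phenotypes,
    filter_markers,
    GenotypePanel,
)
from .synthetic_data import (
    QTLSpec,
    SimulationConfig,
    TraitSpec,
    default_qtls,
    simulate_panel,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "diversity", "structure", "kinship", "ld",
              "pheno", "assoc", "alleles")


class StageError(RuntimeError):
    """A stage's upstream inputs are missing."""


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        return cls(
            out_dir=Path(raw.get("out_dir", "allelemap_out")),
            seed=int(raw["seed"]),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs", {}),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            params=raw.get("params", {}),
        )


def _simulation_config(block: dict[str, Any], seed: int) -> SimulationConfig:
    kwargs = dict(block or {})
    kwargs.setdefault("seed", seed)
    if "qtl_spec" in kwargs:
        kwargs["qtl_spec"] = tuple(
            QTLSpec(q["marker_id"], q["trait"],
                    {int(k): float(v) for k, v in q["allele_effects"].items()})
            for q in kwargs["qtl_spec"]
        )
    elif kwargs.pop("default_qtls", True):
        kwargs["qtl_spec"] = default_qtls(int(kwargs.get("n_loci", 145)))
    if "trait_spec" in kwargs:
        kwargs["trait_spec"] = {
            t: TraitSpec(**s) for t, s in kwargs["trait_spec"].items()
        }
    if "alleles_per_locus_range" in kwargs:
        kwargs["alleles_per_locus_range"] = tuple(kwargs["alleles_per_locus_range"])
    return SimulationConfig(**kwargs)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "files": {}}
    params = config.params

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _hash_file(p)
            manifest["stages"][stage].append(str(p.relative_to(out)))

    # --- inputs -----------------------------------------------------------
    panel = pheno = meta = None
    if "simulate" in config.stages:
        if config.simulate is None and not config.inputs:
            config = RunConfig(config.out_dir, config.seed, {}, {},
                               config.stages, config.params)
        sim_cfg = _simulation_config(config.simulate or {}, config.seed)
        sim = simulate_panel(sim_cfg)
        panel, pheno, meta = sim.panel, sim.phenotypes, sim.meta
        write_genotypes(panel, out / "genotypes.tsv")
        write_map(panel.map, out / "map.tsv")
        write_phenotypes(pheno, out / "phenotypes.tsv")
        write_metadata(meta, out / "metadata.tsv")
        (out / "truth.json").write_text(sim.truth.to_json())
        record("simulate", out / "genotypes.tsv", out / "map.tsv",
               out / "phenotypes.tsv", out / "metadata.tsv", out / "truth.json")
    else:
        if "genotypes" in config.inputs:
            panel = read_genotypes(config.inputs["genotypes"])
            if "map" in config.inputs:
                panel = GenotypePanel(panel.accession_ids, panel.marker_ids,
                                      panel.calls, read_map(config.inputs["map"]))
        if "phenotypes" in config.inputs:
            pheno = read_phenotypes(config.inputs["phenotypes"])
        if "metadata" in config.inputs:
            meta = read_metadata(config.inputs["metadata"])

    if panel is not None:
        panel = filter_markers(panel, params.get("max_missing_rate", 0.10))

    # --- diversity --------------------------------------------------------
    if "diversity" in config.stages:
        if panel is None:
            raise StageError("diversity: no genotype panel (run simulate or give inputs)")
        table = diversity.diversity_table(panel)
        table.to_csv(out / "diversity_loci.tsv", sep="\t", index=False)
        files = [out / "diversity_loci.tsv"]
        if meta is not None:
            _, summary = diversity.diversity_by_group(panel, meta)
            summary.to_csv(out / "diversity_groups.tsv", sep="\t", index=False)
            files.append(out / "diversity_groups.tsv")
        record("diversity", *files)

    # --- structure --------------------------------------------------------
    Q = None
    if "structure" in config.stages:
        if panel is None:
            raise StageError("structure: no genotype panel")
        if "q_matrix" in config.inputs:
            Q = relatedness.read_q_matrix(config.inputs["q_matrix"])
        else:
            k = int(params.get("structure_k", 2))
            markers = relatedness.select_structure_markers(
                panel, params.get("structure_marker_spacing_cM", 20.0)
            )
            Q, _ = relatedness.estimate_Q_em(
                panel.subset_markers(markers), k, seed=config.seed
            )
        assignments = relatedness.assign_subpopulations(Q)
        relatedness.write_matrix(Q, out / "q_matrix.tsv")
        assignments.to_csv(out / "assignments.tsv", sep="\t")
        record("structure", out / "q_matrix.tsv", out / "assignments.tsv")

    # --- kinship ----------------------------------------------------------
    K = None
    if "kinship" in config.stages:
        if panel is None:
            raise StageError("kinship: no genotype panel")
        K = relatedness.loiselle_kinship(panel)
        relatedness.write_matrix(K.to_frame(), out / "kinship.tsv")
        record("kinship", out / "kinship.tsv")

    # --- ld ---------------------------------------------------------------
    if "ld" in config.stages:
        if panel is None:
            raise StageError("ld: no genotype panel")
        pairs = ld.ld_scan(
            panel,
            n_perm=int(params.get("ld_n_perm", 500)),
            seed=config.seed,
            max_pairs_per_chrom=params.get("ld_max_pairs_per_chrom"),
        )
        pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        summary = ld.ld_summary(pairs, alpha=params.get("ld_alpha", 0.01))
        summary.to_csv(out / "ld_summary.tsv", sep="\t", index=False)
        files = [out / "ld_pairs.tsv", out / "ld_summary.tsv"]
        unlinked = pairs[~pairs["linked"]]
        decay_info: dict[str, Any] = {}
        if not unlinked.empty:
            bg = ld.background_ld(unlinked["r2"])
            decay_info["background_r2"] = bg
            try:
                fit = ld.fit_decay(pairs[pairs["linked"]], background_r2=bg,
                                   alpha=params.get("ld_alpha", 0.01))
                decay_info.update(
                    {"a": fit.a, "b": fit.b,
                     "crossings": {str(k): v for k, v in fit.crossings.items()},
                     "n_pairs": fit.n_pairs}
                )
                if params.get("ld_plot", False):
                    ld.plot_decay(pairs, fit, out / "ld_decay.png")
            except ValueError as err:
                logger.warning("ld: decay fit skipped: %s", err)
        (out / "ld_decay.json").write_text(json.dumps(decay_info, indent=2))
        files.append(out / "ld_decay.json")
        record("ld", *files)

    # --- pheno ------------------------------------------------------------
    if "pheno" in config.stages:
        if pheno is None:
            raise StageError("pheno: no phenotype table")
        rows = []
        for trait in pheno.traits:
            vc, tests = pheno_stats.anova_components(pheno, trait)
            summ = pheno_stats.trait_summary(pheno, trait)
            rows.append(
                {"trait": trait, **summ,
                 "sigma2_G": vc.sigma2_G, "sigma2_GE": vc.sigma2_GE,
                 "sigma2_e": vc.sigma2_e, "p_G": tests.p_G, "p_GE": tests.p_GE,
                 "h2_B": pheno_stats.heritability(vc)}
            )
        pd.DataFrame(rows).to_csv(out / "pheno_summary.tsv", sep="\t", index=False)
        lmw = line_means_wide(pheno)
        r, p, stars = pheno_stats.trait_correlations(lmw)
        r.to_csv(out / "trait_correlations.tsv", sep="\t")
        record("pheno", out / "pheno_summary.tsv", out / "trait_correlations.tsv")

    # --- assoc ------------------------------------------------------------
    records = None
    if "assoc" in config.stages:
        if panel is None or pheno is None:
            raise StageError("assoc: needs genotypes and phenotypes")
        if K is None:
            raise StageError("assoc: kinship stage must run first")
        Qcov = relatedness.structure_covariates(Q) if Q is not None else None
        records = association.scan_all(
            panel, pheno, Qcov, K,
            alpha=params.get("assoc_alpha", 0.05),
            detect_alpha=params.get("assoc_detect_alpha", 0.01),
            rare_policy=params.get("rare_policy", "pool"),
        )
        records = association.stability_filter(
            records, min_env=int(params.get("min_env", 2)),
            flag_column=params.get("stability_flag", "significant_bonferroni"),
        )
        records.to_csv(out / "associations_full.tsv", sep="\t", index=False)
        sig = records[records["significant_bonferroni"]]
        sig.to_csv(out / "associations_significant.tsv", sep="\t", index=False)
        record("assoc", out / "associations_full.tsv",
               out / "associations_significant.tsv")

    # --- alleles ----------------------------------------------------------
    if "alleles" in config.stages:
        if records is None:
            raise StageError("alleles: assoc stage must run first")
        if pheno is None or panel is None:
            raise StageError("alleles: needs genotypes and phenotypes")
        stable = records[records["stable"] & records["significant_bonferroni"]]
        lmw = line_means_wide(pheno)
        effects, trans = allele_mining.mine_alleles(
            panel, lmw, stable, meta=meta,
            min_carriers=int(params.get("min_carriers", 0)),
            high_freq_threshold=params.get("high_freq_threshold", 0.8),
        )
        effects.to_csv(out / "allele_effects.tsv", sep="\t", index=False)
        files = [out / "allele_effects.tsv"]
        if trans is not None:
            trans.to_csv(out / "transmission.tsv", sep="\t", index=False)
            files.append(out / "transmission.tsv")
        record("alleles", *files)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
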