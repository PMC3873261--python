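#!/usr/bin/env python
"""Phenotypic analysis: descriptives, ANOVA, heritability, correlations.

Per trait and environment, reports mean/SD/min/max/CV of line means; per
trait, the variance components from the two-factor ANOVA (genotype,
environment, replicate-within-environment, GxE), the significance of G and
GxE, and entry-mean broad-sense heritability; plus the trait correlation
matrix on across-environment line means.
"""

from pathlib import Path

import pandas as pd

from allelemap.core_io import line_means_wide, read_phenotypes
from allelemap.pheno_stats import (
    anova_components,
    heritability,
    trait_correlations,
    trait_summary,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pheno = read_phenotypes(BASE / "panel" / "phenotypes.tsv")
    out = BASE / "pheno"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for trait in pheno.traits:
        vc, tests = anova_components(pheno, trait)
        h2 = heritability(vc)
        for env in pheno.environments + [None]:
            s = trait_summary(pheno, trait, env)
            rows.append({"trait": trait, "environment": env or "Mean", **s,
                         "h2_B_pct": round(100 * h2, 2) if env is None else "",
                         "p_G": tests.p_G if env is None else "",
                         "p_GxE": tests.p_GE if env is None else ""})
    table = pd.DataFrame(rows)
    table.to_csv(out / "pheno_summary.tsv", sep="\t", index=False)

    wide = line_means_wide(pheno)
    r, p, stars = trait_correlations(wide)
    (r.round(3).astype(str) + stars).to_csv(out / "trait_correlations.tsv", sep="\t")

    mean_rows = table[table["environment"] == "Mean"]
    print(mean_rows[["trait", "mean", "sd", "cv_pct", "h2_B_pct"]]
          .to_string(index=False))
    print("\ntrait correlations (line means across environments):")
    print((r.round(2)).to_string())


if __name__ == "__main__":
    main()
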