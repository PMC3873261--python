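#!/usr/bin/env python
"""Favorable-allele mining and founder-to-modern transmission analysis.

For every marker x trait association detected in more than one environment,
computes each allele's phenotypic effect a_i (carrier mean minus panel mean
on across-environment line means), flags favorable alleles by the breeding
objective of each trait (maximize everything except seed index), lists the
top-3 representative carrier accessions, and classifies each favorable
allele's era-group frequency trajectory into the three transmission classes.
"""

from pathlib import Path

import pandas as pd

from allelemap.allele_mining import mine_alleles
from allelemap.core_io import (
    filter_markers, line_means_wide, read_genotypes, read_metadata,
    read_phenotypes,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = filter_markers(read_genotypes(BASE / "panel" / "genotypes.tsv"), 0.10)
    pheno = read_phenotypes(BASE / "panel" / "phenotypes.tsv")
    meta = read_metadata(BASE / "panel" / "metadata.tsv")
    records = pd.read_csv(BASE / "association" / "associations_significant.tsv",
                          sep="\t")
    stable = records[records["n_env_significant"] >= 2]
    out = BASE / "alleles"
    out.mkdir(parents=True, exist_ok=True)

    effects, trans = mine_alleles(panel, line_means_wide(pheno), stable,
                                  meta=meta)
    effects.to_csv(out / "allele_effects.tsv", sep="\t", index=False)
    fav = effects[effects["favorable"]]
    print(f"{len(effects)} allele effects scored at "
          f"{effects['marker'].nunique()} stably associated loci; "
          f"{len(fav)} favorable alleles")
    if len(fav):
        cols = ["trait", "marker", "allele", "a_i", "n_carriers",
                "representative_accessions"]
        print(fav[cols].round({"a_i": 2}).to_string(index=False))
    if trans is not None:
        trans.to_csv(out / "transmission.tsv", sep="\t", index=False)
        counts = trans["transmission_class"].value_counts().sort_index()
        print("\ntransmission classes of favorable alleles "
              "(1 = founder-fixed, 2 = founder-present/underused, "
              "3 = founder-absent):")
        print(counts.to_string())


if __name__ == "__main__":
    main()
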