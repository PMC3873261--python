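#!/usr/bin/env python
"""Generate the study panel: 356 selfed lines x 145 SSR loci, 7 yield traits.

Writes genotype/map/phenotype/metadata tables plus the truth record under
results/panel/, and a realism report comparing the realized panel statistics
(Fst, alleles per locus, rare-allele fraction, LD half-decay, heritabilities)
with the generator's targets.
"""

from pathlib import Path

from allelemap.core_io import (
    write_genotypes, write_map, write_metadata, write_phenotypes,
)
from allelemap.synthetic_data import (
    SimulationConfig, default_qtls, simulate_panel, verify_realism,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED, qtl_spec=default_qtls())
    res = simulate_panel(cfg)
    write_genotypes(res.panel, OUT / "genotypes.tsv")
    write_map(res.panel.map, OUT / "map.tsv")
    write_phenotypes(res.phenotypes, OUT / "phenotypes.tsv")
    write_metadata(res.meta, OUT / "metadata.tsv")
    (OUT / "truth.json").write_text(res.truth.to_json())

    report = verify_realism(res, cfg)
    frame = report.to_frame()
    frame.to_csv(OUT / "realism_report.tsv", sep="\t", index=False)

    print(f"panel: {res.panel.n_accessions} lines x {res.panel.n_markers} loci "
          f"-> {OUT}")
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
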