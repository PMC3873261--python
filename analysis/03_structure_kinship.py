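#!/usr/bin/env python
"""Population structure (delta-k model selection + Q matrix) and kinship.

Runs the admixture EM surrogate for k = 1..6 with replicate restarts on a
map-thinned marker subset, selects k by the Evanno delta-k statistic,
estimates the Q matrix at the chosen k, assigns lines by the Q>0.5 rule, and
computes the zero-truncated Loiselle kinship matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from allelemap.core_io import filter_markers, read_genotypes, read_map
from allelemap.core_io import GenotypePanel
from allelemap.relatedness import (
    assign_subpopulations,
    delta_k,
    estimate_Q_em,
    lnp_replicates_em,
    loiselle_kinship,
    select_structure_markers,
    write_matrix,
)

SEED = 1
BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_genotypes(BASE / "panel" / "genotypes.tsv")
    gmap = read_map(BASE / "panel" / "map.tsv")
    panel = filter_markers(
        GenotypePanel(panel.accession_ids, panel.marker_ids, panel.calls, gmap),
        0.10,
    )
    out = BASE / "structure"
    out.mkdir(parents=True, exist_ok=True)

    markers = select_structure_markers(panel, min_spacing_cM=20.0)
    sub = panel.subset_markers(markers)
    print(f"structure subset: {len(markers)} of {panel.n_markers} markers")

    runs = lnp_replicates_em(sub, range(1, 7), n_reps=3, seed=SEED)
    dk, chosen = delta_k(runs)
    pd.DataFrame(
        {"k": list(dk), "delta_k": list(dk.values())}
    ).to_csv(out / "delta_k.tsv", sep="\t", index=False)
    print(f"delta-k selects k = {chosen} "
          f"(delta_k: {', '.join(f'{k}:{v:.1f}' for k, v in dk.items())})")

    Q, _ = estimate_Q_em(sub, chosen, seed=SEED)
    write_matrix(Q, out / "q_matrix.tsv")
    assignments = assign_subpopulations(Q)
    assignments.to_csv(out / "assignments.tsv", sep="\t")
    counts = assignments.value_counts()
    print("subpopulation sizes:", dict(counts))

    K = loiselle_kinship(panel)
    write_matrix(K.to_frame(), out / "kinship.tsv")
    iu = np.triu_indices(panel.n_accessions, 1)
    vals = K.values[iu]
    print(f"kinship: {100 * (vals < 0.05).mean():.2f}% of pairs < 0.05, "
          f"{100 * ((vals >= 0.05) & (vals < 0.10)).mean():.2f}% in 0.05-0.10")


if __name__ == "__main__":
    main()
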