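#!/usr/bin/env python
"""Linkage disequilibrium: pairwise r2, background level and decay curve.

Computes the weighted multi-allelic r2 for every locus pair (rare alleles
masked), summarizes LD for the total/linked/unlinked strata in the entire
panel and in each subpopulation, takes the 99th percentile of unlinked r2 as
the background level, fits r2 = a + b ln(d) on linked significant pairs and
reports the distances at which the curve crosses the background, 0.1 and 0.2.
"""

import json
from pathlib import Path

import pandas as pd

from allelemap.core_io import GenotypePanel, filter_markers, read_genotypes, read_map
from allelemap.ld import background_ld, fit_decay, ld_scan, ld_summary, plot_decay

SEED = 1
N_PERM = 500
BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = read_genotypes(BASE / "panel" / "genotypes.tsv")
    gmap = read_map(BASE / "panel" / "map.tsv")
    panel = filter_markers(
        GenotypePanel(panel.accession_ids, panel.marker_ids, panel.calls, gmap),
        0.10,
    )
    out = BASE / "ld"
    out.mkdir(parents=True, exist_ok=True)

    pairs = ld_scan(panel, n_perm=N_PERM, seed=SEED)
    pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)

    summaries = [ld_summary(pairs, alpha=0.01).assign(group="entire")]
    assignments = pd.read_csv(BASE / "structure" / "assignments.tsv",
                              sep="\t", index_col=0)["subpop"]
    for label, accs in assignments.groupby(assignments):
        if label == "ADMIXED" or len(accs) < 30:
            continue
        sub = panel.subset_accessions(list(accs.index))
        sub_pairs = ld_scan(sub, n_perm=N_PERM, seed=SEED)
        summaries.append(ld_summary(sub_pairs, alpha=0.01).assign(group=label))
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "ld_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    bg = background_ld(pairs[~pairs["linked"]]["r2"])
    fit = fit_decay(pairs[pairs["linked"]], background_r2=bg, alpha=0.01)
    decay = {"a": fit.a, "b": fit.b, "background_r2": bg,
             "n_pairs": fit.n_pairs,
             "crossings_cM": {f"{t:.4f}": d for t, d in fit.crossings.items()}}
    (out / "ld_decay.json").write_text(json.dumps(decay, indent=2))
    plot_decay(pairs, fit, out / "ld_decay.png", alpha=0.01)

    print(f"background LD (99th pct of unlinked r2): {bg:.4f}")
    for t, d in fit.crossings.items():
        where = f"{d:.1f} cM" if d is not None else "not reached"
        print(f"  r2 = {t:.4f} crossed at {where}")


if __name__ == "__main__":
    main()
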