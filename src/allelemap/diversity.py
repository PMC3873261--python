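"""Per-locus and per-group diversity statistics.

Gene diversity is the uncorrected expected heterozygosity He = 1 - sum p_i^2.
PIC follows the Botstein (1980) definition
PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
Frequencies are computed over typed lines only; an allele is *rare* when its
frequency is strictly below 0.05 and *unique* when exactly one accession
carries it (regardless of frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, AccessionMeta, GenotypePanel, meta_frame

RARE_FREQUENCY = 0.05


@dataclass(frozen=True)
class LocusDiversity:
    marker_id: str
    n_typed: int
    allele_freqs: dict[int, float]
    n_alleles: int
    gene_diversity: float
    pic: float
    rare_alleles: frozenset[int]
    unique_alleles: frozenset[int]


def allele_frequencies(
    panel: GenotypePanel, marker: str, subset: Sequence[str] | None = None
) -> dict[int, float]:
    """Allele frequencies over non-missing calls, optionally within a subset."""
    calls = panel.calls_for(marker)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("subset must be non-empty")
        idx = [panel.accession_ids.index(a) for a in subset]
        calls = calls[idx]
    typed = calls[calls != MISSING]
    if typed.size == 0:
        raise ValueError(f"all calls missing for marker {marker!r}")
    codes, counts = np.unique(typed, return_counts=True)
    total = counts.sum()
    return {int(c): float(n) / total for c, n in zip(codes, counts)}


def gene_diversity(freqs: Mapping[int, float]) -> float:
    """He = 1 - sum p_i^2."""
    if not freqs:
        raise ValueError("empty frequency map")
    p = np.asarray(list(freqs.values()), dtype=float)
    return float(1.0 - np.sum(p**2))


def pic(freqs: Mapping[int, float]) -> float:
    """PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2  (Botstein convention)."""
    if not freqs:
        raise ValueError("empty frequency map")
    p = np.asarray(list(freqs.values()), dtype=float)
    s2 = np.sum(p**2)
    s4 = np.sum(p**4)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return float(1.0 - s2 - (s2**2 - s4))


def locus_diversity(
    panel: GenotypePanel, marker: str, subset: Sequence[str] | None = None
) -> LocusDiversity:
    calls = panel.calls_for(marker)
    if subset is not None:
        idx = [panel.accession_ids.index(a) for a in subset]
        calls = calls[idx]
    typed = calls[calls != MISSING]
    freqs = allele_frequencies(panel, marker, subset)
    carrier_counts = {int(a): int(np.sum(typed == a)) for a in freqs}
    return LocusDiversity(
        marker_id=marker,
        n_typed=int(typed.size),
        allele_freqs=freqs,
        n_alleles=len(freqs),
        gene_diversity=gene_diversity(freqs),
        pic=pic(freqs),
        rare_alleles=frozenset(a for a, p in freqs.items() if p < RARE_FREQUENCY),
        unique_alleles=frozenset(a for a, n in carrier_counts.items() if n == 1),
    )


def diversity_table(
    panel: GenotypePanel, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-locus summary table (one row per marker)."""
    rows = []
    for m in panel.marker_ids:
        d = locus_diversity(panel, m, subset)
        rows.append(
            {
                "marker_id": d.marker_id,
                "n_typed": d.n_typed,
                "n_alleles": d.n_alleles,
                "gene_diversity": d.gene_diversity,
                "pic": d.pic,
                "n_rare": len(d.rare_alleles),
                "n_unique": len(d.unique_alleles),
            }
        )
    return pd.DataFrame(rows)


def diversity_by_group(
    panel: GenotypePanel, meta: Iterable[AccessionMeta]
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-era-group locus tables plus a group-level summary.

    The summary carries, per group: number of lines, total alleles detected,
    mean alleles per locus (total / n_loci identity), mean gene diversity and
    mean PIC.
    """
    frame = meta_frame(list(meta))
    unknown = set(frame["accession_id"]) - set(panel.accession_ids)
    if unknown:
        raise ValueError(f"metadata for accessions absent from panel: {sorted(unknown)}")
    tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for group, sub in frame.groupby("era_group", sort=True):
        accs = list(sub["accession_id"])
        if not accs:
            raise ValueError(f"empty era group {group!r}")
        table = diversity_table(panel, accs)
        tables[str(group)] = table
        total = int(table["n_alleles"].sum())
        summary_rows.append(
            {
                "era_group": group,
                "n_lines": len(accs),
                "total_alleles": total,
                "alleles_per_locus": total / panel.n_markers,
                "mean_gene_diversity": float(table["gene_diversity"].mean()),
                "mean_pic": float(table["pic"].mean()),
            }
        )
    return tables, pd.DataFrame(summary_rows)
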