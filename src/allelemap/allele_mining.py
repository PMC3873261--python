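"""Per-allele phenotypic effects, favorable-allele calls and transmission.

The allele effect is

    a_i = (1/n_i) sum_j x_ij  -  N_k / n_k

the mean trait value over the n_i carriers of allele i minus the overall mean
over all n_k phenotyped accessions (N_k their summed value).  Alleles whose
effect sign matches the trait's breeding objective (+1 maximize, -1 minimize)
are favorable.  For each favorable allele the top carriers in the objective
direction are the representative accessions, and its frequency trajectory
across the founder (CK) and era groups classifies its transmission:

* class 1 - present in the founders and at high frequency in every modern
  group (passed down and nearly fixed);
* class 2 - present in the founders but at moderate/low frequency
  (underutilized);
* class 3 - absent from the founders (novel or introduced variation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, AccessionMeta, GenotypePanel, meta_frame

logger = logging.getLogger(__name__)

#: Default breeding objectives: larger is better for yield and its components,
#: smaller for seed index.
DEFAULT_OBJECTIVES: dict[str, int] = {
    "LY": +1, "SY": +1, "BN": +1, "BW": +1, "LP": +1, "LI": +1, "SI": -1,
}

#: Era-group columns, in reporting order (CK = founder parents).
GROUP_ORDER = ("CK", "I", "II", "III", "IV", "V", "VI")


# ---------------------------------------------------------------------------
# allele effects
# ---------------------------------------------------------------------------


def allele_effect(
    line_means_wide: pd.DataFrame,
    panel: GenotypePanel,
    marker: str,
    allele: int,
    trait: str,
) -> tuple[float, int]:
    """a_i = carrier mean minus overall mean; returns (a_i, carrier count).

    ``line_means_wide`` is an accession x trait table of across-environment
    line means.  Carriers are lines whose call equals the allele; untyped
    lines leave the carrier set but still count in the overall mean when
    phenotyped.  NaN with a warning if no carrier is phenotyped.
    """
    if trait not in line_means_wide.columns:
        raise KeyError(f"trait {trait!r} not in line means")
    calls = panel.calls_for(marker)
    pheno = line_means_wide[trait]
    phenotyped = pheno.dropna()
    overall = float(phenotyped.mean())
    carrier_ids = [
        a for a, c in zip(panel.accession_ids, calls) if c == allele
    ]
    carrier_vals = phenotyped.loc[[a for a in carrier_ids if a in phenotyped.index]]
    if carrier_vals.empty:
        warnings.warn(f"allele {marker}-{allele}: no phenotyped carrier")
        return float("nan"), 0
    return float(carrier_vals.mean()) - overall, int(len(carrier_vals))


def allele_effects_table(
    line_means_wide: pd.DataFrame,
    panel: GenotypePanel,
    marker_traits: Iterable[tuple[str, str]],
    min_carriers: int = 0,
) -> pd.DataFrame:
    """Effects for every allele of every (marker, trait) combination."""
    rows = []
    for marker, trait in marker_traits:
        calls = panel.calls_for(marker)
        alleles = sorted(int(a) for a in np.unique(calls[calls != MISSING]))
        for a in alleles:
            eff, n_i = allele_effect(line_means_wide, panel, marker, a, trait)
            if n_i < min_carriers:
                continue
            rows.append(
                {"marker": marker, "allele": a, "trait": trait,
                 "a_i": eff, "n_carriers": n_i}
            )
    return pd.DataFrame(rows)


def favorable_alleles(
    effects: pd.DataFrame, objectives: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Flag effects whose sign matches the trait objective (a_i = 0 is not)."""
    objectives = dict(DEFAULT_OBJECTIVES if objectives is None else objectives)
    missing = set(effects["trait"]) - set(objectives)
    if missing:
        raise ValueError(f"no breeding objective for traits: {sorted(missing)}")
    out = effects.copy()
    direction = out["trait"].map(objectives)
    out["favorable"] = np.sign(out["a_i"]) == direction
    out.loc[out["a_i"].isna(), "favorable"] = False
    return out


def representative_accessions(
    panel: GenotypePanel,
    line_means_wide: pd.DataFrame,
    marker: str,
    allele: int,
    trait: str,
    top_n: int = 3,
    direction: int = +1,
) -> list[str]:
    """Top carriers by trait value in the objective direction.

    Ties are broken by lexicographic accession id.  Returns fewer than
    ``top_n`` if there are fewer phenotyped carriers.
    """
    calls = panel.calls_for(marker)
    pheno = line_means_wide[trait].dropna()
    carriers = [
        a for a, c in zip(panel.accession_ids, calls)
        if c == allele and a in pheno.index
    ]
    key = sorted(carriers, key=lambda a: (-direction * pheno[a], a))
    return key[:top_n]


# ---------------------------------------------------------------------------
# transmission across era groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransmissionRow:
    marker: str
    allele: int
    frequencies: dict[str, float]  # group (incl. "Total") -> frequency
    transmission_class: int


def transmission_class(
    ck_freq: float,
    group_freqs: Sequence[float],
    high_freq_threshold: float = 0.8,
) -> int:
    """Classify a favorable allele from its founder and era-group frequencies.

    Class 3 iff absent from the founders; class 1 if founder-present and at
    or above the high-frequency threshold in every modern group; class 2
    otherwise.
    """
    if ck_freq == 0.0:
        return 3
    if len(group_freqs) and min(group_freqs) >= high_freq_threshold:
        return 1
    return 2


def transmission_table(
    panel: GenotypePanel,
    meta: Iterable[AccessionMeta],
    alleles_of_interest: Iterable[tuple[str, int]],
    high_freq_threshold: float = 0.8,
) -> list[TransmissionRow]:
    """Per-era-group frequency of each allele plus its transmission class.

    Frequencies are over typed lines per group; the Total column pools all
    groups.  The CK (founder) group must be non-empty.
    """
    frame = meta_frame(list(meta))
    groups_present = [g for g in GROUP_ORDER if (frame["era_group"] == g).any()]
    if "CK" not in groups_present:
        raise ValueError("CK (founder) group is empty")
    acc_group = dict(zip(frame["accession_id"], frame["era_group"]))
    rows = []
    for marker, allele in alleles_of_interest:
        calls = panel.calls_for(marker)
        typed_alleles = set(int(a) for a in np.unique(calls[calls != MISSING]))
        if allele not in typed_alleles:
            raise ValueError(f"allele {marker}-{allele} absent from panel")
        freqs: dict[str, float] = {}
        n_total = 0
        c_total = 0
        for g in groups_present:
            accs = [a for a in panel.accession_ids if acc_group.get(a) == g]
            idx = [panel.accession_ids.index(a) for a in accs]
            sub = calls[idx]
            typed = sub != MISSING
            n = int(typed.sum())
            c = int(np.sum(sub[typed] == allele))
            freqs[g] = c / n if n else float("nan")
            n_total += n
            c_total += c
        freqs["Total"] = c_total / n_total if n_total else float("nan")
        modern = [freqs[g] for g in groups_present if g != "CK" and not np.isnan(freqs[g])]
        cls = transmission_class(freqs["CK"], modern, high_freq_threshold)
        rows.append(TransmissionRow(marker, int(allele), freqs, cls))
    return rows


def transmission_frame(rows: list[TransmissionRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        rec = {"marker": r.marker, "allele": r.allele}
        rec.update(r.frequencies)
        rec["transmission_class"] = r.transmission_class
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# orchestration over stable associations
# ---------------------------------------------------------------------------


def mine_alleles(
    panel: GenotypePanel,
    line_means_wide: pd.DataFrame,
    stable_records: pd.DataFrame,
    meta: Iterable[AccessionMeta] | None = None,
    objectives: Mapping[str, int] | None = None,
    min_carriers: int = 0,
    top_n: int = 3,
    high_freq_threshold: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Effects + favorable flags + representatives for stably associated loci,
    and (when metadata is given) the transmission table of favorable alleles."""
    objectives = dict(DEFAULT_OBJECTIVES if objectives is None else objectives)
    pairs = sorted(
        set(zip(stable_records["marker"], stable_records["trait"]))
    )
    effects = allele_effects_table(line_means_wide, panel, pairs, min_carriers)
    if effects.empty:
        return effects, None
    effects = favorable_alleles(effects, objectives)
    reps = []
    for _, row in effects.iterrows():
        if not row["favorable"]:
            reps.append("")
            continue
        direction = objectives[row["trait"]]
        top = representative_accessions(
            panel, line_means_wide, row["marker"], int(row["allele"]),
            row["trait"], top_n=top_n, direction=direction,
        )
        reps.append(", ".join(top))
    effects["representative_accessions"] = reps

    trans = None
    if meta is not None:
        fav = effects[effects["favorable"]]
        alleles = sorted(set(zip(fav["marker"], fav["allele"].astype(int))))
        if alleles:
            trans = transmission_frame(
                transmission_table(panel, meta, alleles, high_freq_threshold)
            )
    return effects, trans
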