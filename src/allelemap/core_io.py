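"""Domain types and tabular readers/writers.

Conventions
-----------
* Allele codes are positive small integers that are *locus-local* labels:
  code 2 at locus A and code 2 at locus B are unrelated states.
* Lines are homozygous by construction (selfed germplasm), so one code per
  accession per locus; heterozygous cells are not representable and any cell
  listing two codes is rejected.
* ``MISSING`` (0) marks an untyped call inside the integer matrix; on disk the
  missing token defaults to ``"NA"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: In-matrix sentinel for an untyped genotype call (codes themselves are >= 1).
MISSING: int = 0

#: Default on-disk token for a missing value.
MISSING_TOKEN: str = "NA"

#: Era-group labels: CK are founder parents, I..VI are release-period cohorts.
ERA_GROUPS: tuple[str, ...] = ("CK", "I", "II", "III", "IV", "V", "VI", "other")

#: The seven lint-yield traits, in conventional order.
YIELD_TRAITS: tuple[str, ...] = ("LY", "SY", "BN", "BW", "LP", "LI", "SI")


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


class EmptyPanelError(ValueError):
    """Raised when an operation would leave a panel with no markers."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions in centimorgans.

    Markers on the same chromosome are *linked*, on different chromosomes
    *unlinked*; the cM distance between linked markers drives the LD-decay
    analysis.
    """

    frame: pd.DataFrame  # columns: marker_id, chromosome, position_cM

    def __post_init__(self) -> None:
        required = ["marker_id", "chromosome", "position_cM"]
        if list(self.frame.columns[:3]) != required:
            raise FormatError(f"map columns must be {required}")
        if self.frame["marker_id"].duplicated().any():
            dups = self.frame["marker_id"][self.frame["marker_id"].duplicated()]
            raise FormatError(f"duplicate marker ids in map: {sorted(set(dups))}")
        pos = self.frame["position_cM"].to_numpy(dtype=float)
        if not np.all(np.isfinite(pos)) or (pos < 0).any():
            raise FormatError("map positions must be finite and non-negative")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.frame["marker_id"])

    def chromosome(self, marker: str) -> str:
        return str(self._row(marker)["chromosome"])

    def position(self, marker: str) -> float:
        return float(self._row(marker)["position_cM"])

    def linked(self, marker_a: str, marker_b: str) -> bool:
        return self.chromosome(marker_a) == self.chromosome(marker_b)

    def distance(self, marker_a: str, marker_b: str) -> float:
        """cM distance for linked markers; NaN for unlinked ones."""
        if not self.linked(marker_a, marker_b):
            return float("nan")
        return abs(self.position(marker_a) - self.position(marker_b))

    def restrict(self, markers: Sequence[str]) -> "GeneticMap":
        keep = self.frame[self.frame["marker_id"].isin(set(markers))]
        order = {m: i for i, m in enumerate(markers)}
        keep = keep.sort_values("marker_id", key=lambda s: s.map(order))
        return GeneticMap(keep.reset_index(drop=True))

    def _row(self, marker: str) -> pd.Series:
        sel = self.frame[self.frame["marker_id"] == marker]
        if sel.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return sel.iloc[0]


@dataclass
class GenotypePanel:
    """Accessions x loci matrix of allele codes for homozygous lines."""

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # int matrix, shape (n_accessions, n_loci), 0 = MISSING
    map: GeneticMap | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if not np.issubdtype(self.calls.dtype, np.integer):
            raise FormatError("allele codes must be integers")
        if (self.calls < 0).any():
            raise FormatError("allele codes must be >= 1 (0 marks missing)")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise FormatError("duplicate accession ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise FormatError("duplicate marker ids")
        if self.map is not None:
            missing = set(self.marker_ids) - set(self.map.marker_ids)
            if missing:
                raise FormatError(f"markers absent from map: {sorted(missing)}")
            self.map = self.map.restrict(self.marker_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_ids.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None

    def calls_for(self, marker: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker)]

    def missing_rate(self) -> np.ndarray:
        """Per-marker missing fraction."""
        return (self.calls == MISSING).mean(axis=0)

    def subset_accessions(self, accessions: Sequence[str]) -> "GenotypePanel":
        idx = [self.accession_ids.index(a) for a in accessions]
        return GenotypePanel(
            list(accessions), list(self.marker_ids), self.calls[idx, :], self.map
        )

    def subset_markers(self, markers: Sequence[str]) -> "GenotypePanel":
        idx = [self.marker_index(m) for m in markers]
        return GenotypePanel(
            list(self.accession_ids), list(markers), self.calls[:, idx], self.map
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.accession_ids, columns=self.marker_ids
        )


@dataclass(frozen=True)
class AccessionMeta:
    """Era group (CK = founder parents), region of origin and founder flag."""

    accession_id: str
    era_group: str
    region: str = ""
    is_founder: bool = False

    def __post_init__(self) -> None:
        if self.era_group not in ERA_GROUPS:
            raise FormatError(
                f"era_group {self.era_group!r} not in {ERA_GROUPS}"
            )
        if self.era_group == "CK" and not self.is_founder:
            raise FormatError(
                f"accession {self.accession_id}: CK group implies is_founder"
            )


def meta_frame(meta: Iterable[AccessionMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession_id": m.accession_id,
                "era_group": m.era_group,
                "region": m.region,
                "is_founder": m.is_founder,
            }
            for m in meta
        ]
    )


@dataclass
class PhenotypeTable:
    """Long-format trait observations by accession/environment/replicate."""

    frame: pd.DataFrame  # accession_id, environment_id, replicate_id, trait_name, value

    COLUMNS = ["accession_id", "environment_id", "replicate_id", "trait_name", "value"]

    def __post_init__(self) -> None:
        if list(self.frame.columns[:5]) != self.COLUMNS:
            raise FormatError(f"phenotype columns must be {self.COLUMNS}")
        key = self.frame[self.COLUMNS[:4]]
        if key.duplicated().any():
            raise FormatError("duplicate (accession, environment, replicate, trait)")
        vals = self.frame["value"].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("phenotype values must be finite or missing")

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait_name"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.frame["environment_id"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        if trait not in set(self.frame["trait_name"]):
            raise KeyError(f"unknown trait {trait!r}")
        return self.frame[self.frame["trait_name"] == trait]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, **kw)


def read_genotypes(path, missing_token: str = MISSING_TOKEN) -> GenotypePanel:
    """Read a delimited accession x marker matrix of allele codes.

    First column holds accession ids, the header row marker ids.  Cells are
    positive integers or the missing token; anything else raises
    :class:`FormatError`.
    """
    with open(path) as fh:  # inspect the raw header: pandas mangles duplicates
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    raw_markers = header.split(sep)[1:]
    if len(set(raw_markers)) != len(raw_markers):
        raise FormatError("duplicate marker columns in genotype table")
    raw = _read_table(path)
    acc = list(raw.iloc[:, 0])
    markers = list(raw.columns[1:])
    if len(set(acc)) != len(acc):
        raise FormatError("duplicate accession ids in genotype table")
    calls = np.zeros((len(acc), len(markers)), dtype=np.int16)
    for j, m in enumerate(markers):
        col = raw.iloc[:, j + 1]
        for i, cell in enumerate(col):
            cell = str(cell).strip()
            if cell == missing_token or cell.lower() == "nan":
                calls[i, j] = MISSING
                continue
            try:
                code = int(cell)
            except ValueError:
                raise FormatError(
                    f"non-integer genotype cell {cell!r} at {acc[i]}/{m}"
                ) from None
            if code < 1:
                raise FormatError(f"allele code must be >= 1, got {code} at {acc[i]}/{m}")
            calls[i, j] = code
    return GenotypePanel([str(a) for a in acc], markers, calls)


def write_genotypes(panel: GenotypePanel, path, missing_token: str = MISSING_TOKEN) -> None:
    frame = panel.to_frame().astype(object)
    frame = frame.where(frame != MISSING, missing_token)
    frame.index.name = "accession_id"
    frame.to_csv(path, sep="\t")


def read_map(path) -> GeneticMap:
    raw = _read_table(path)
    frame = pd.DataFrame(
        {
            "marker_id": raw.iloc[:, 0].astype(str),
            "chromosome": raw.iloc[:, 1].astype(str),
            "position_cM": raw.iloc[:, 2].astype(float),
        }
    )
    return GeneticMap(frame)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.frame.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, missing_token: str = MISSING_TOKEN) -> PhenotypeTable:
    raw = _read_table(path, na_values=[missing_token])
    frame = pd.DataFrame(
        {
            "accession_id": raw.iloc[:, 0].astype(str),
            "environment_id": raw.iloc[:, 1].astype(str),
            "replicate_id": raw.iloc[:, 2].astype(str),
            "trait_name": raw.iloc[:, 3].astype(str),
            "value": pd.to_numeric(raw.iloc[:, 4], errors="raise"),
        }
    )
    return PhenotypeTable(frame)


def write_phenotypes(pheno: PhenotypeTable, path, missing_token: str = MISSING_TOKEN) -> None:
    pheno.frame.to_csv(path, sep="\t", index=False, na_rep=missing_token)


def read_metadata(path) -> list[AccessionMeta]:
    raw = _read_table(path)
    out = []
    for _, row in raw.iterrows():
        out.append(
            AccessionMeta(
                accession_id=str(row.iloc[0]),
                era_group=str(row.iloc[1]),
                region=str(row.iloc[2]) if len(row) > 2 and pd.notna(row.iloc[2]) else "",
                is_founder=str(row.iloc[3]).strip().lower() in {"true", "1", "yes"}
                if len(row) > 3
                else str(row.iloc[1]) == "CK",
            )
        )
    return out


def write_metadata(meta: Iterable[AccessionMeta], path) -> None:
    meta_frame(meta).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def filter_markers(panel: GenotypePanel, max_missing_rate: float) -> GenotypePanel:
    """Drop markers whose missing fraction *strictly exceeds* the threshold.

    A marker with exactly the threshold fraction missing is kept.  Survivor
    order is preserved and every removal is logged.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    rates = panel.missing_rate()
    keep = [m for m, r in zip(panel.marker_ids, rates) if r <= max_missing_rate]
    for m, r in zip(panel.marker_ids, rates):
        if r > max_missing_rate:
            logger.info("filter_markers: dropping %s (missing %.3f > %.3f)",
                        m, r, max_missing_rate)
    if not keep:
        raise EmptyPanelError("all markers exceed the missing-data threshold")
    if len(keep) == panel.n_markers:
        return panel
    return panel.subset_markers(keep)


def line_means(pheno: PhenotypeTable, level: str = "per_environment") -> pd.DataFrame:
    """Replicate-averaged line means, per environment or across environments.

    ``across_environments`` is the unweighted mean of the available
    per-environment means (a line missing in an environment is averaged over
    the environments where it was observed, with a warning).
    """
    per_env = (
        pheno.frame.dropna(subset=["value"])
        .groupby(["accession_id", "environment_id", "trait_name"], sort=True)["value"]
        .mean()
        .reset_index(name="mean_value")
    )
    if level == "per_environment":
        return per_env
    if level != "across_environments":
        raise ValueError(f"unknown level {level!r}")
    n_env = per_env["environment_id"].nunique()
    counts = per_env.groupby(["accession_id", "trait_name"])["environment_id"].nunique()
    if (counts < n_env).any():
        short = counts[counts < n_env]
        logger.warning(
            "line_means: %d accession/trait cells observed in fewer than %d "
            "environments; averaging available environments", len(short), n_env
        )
    across = (
        per_env.groupby(["accession_id", "trait_name"], sort=True)["mean_value"]
        .mean()
        .reset_index()
    )
    return across


def line_means_wide(pheno: PhenotypeTable) -> pd.DataFrame:
    """Across-environment line means as an accession x trait table."""
    across = line_means(pheno, "across_environments")
    return across.pivot(index="accession_id", columns="trait_name", values="mean_value")
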