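"""Core in-memory containers shared by every pipeline stage.

The three containers mirror the objects a quantitative geneticist works
with: a pedigree (directed acyclic parent map), a genotype dosage matrix
(individuals x SNPs coded 0/1/2 with missing values), and a symmetric
relationship matrix keyed by genotype ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = ""

_PEDIGREE_COLUMNS = ["id", "sire", "dam", "family", "generation"]


class PedigreeError(ValueError):
    """Raised for structural problems in a pedigree (cycles, missing parents)."""


@dataclass
class Pedigree:
    """Directed acyclic parent map defining founders and full-sib families.

    ``table`` has columns id, sire, dam, family, generation.  Founders have
    both parents unknown (empty string) and generation 0.  Every non-founder
    has exactly two known parents that appear earlier in the table.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PEDIGREE_COLUMNS if c not in self.table.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise PedigreeError(f"duplicated pedigree ids: {dups}")
        self._validate_order()

    def _validate_order(self) -> None:
        seen: set[str] = set()
        for row in self.table.itertuples(index=False):
            for parent in (row.sire, row.dam):
                if parent == UNKNOWN_PARENT:
                    continue
                if parent == row.id:
                    raise PedigreeError(f"individual {row.id!r} is its own parent")
                if parent not in seen:
                    raise PedigreeError(
                        f"parent {parent!r} of {row.id!r} does not precede it; "
                        "pedigree must be topologically ordered"
                    )
            seen.add(row.id)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def founders(self) -> list[str]:
        t = self.table
        mask = (t["sire"] == UNKNOWN_PARENT) & (t["dam"] == UNKNOWN_PARENT)
        return t.loc[mask, "id"].tolist()

    @property
    def offspring(self) -> pd.DataFrame:
        t = self.table
        return t[(t["sire"] != UNKNOWN_PARENT) | (t["dam"] != UNKNOWN_PARENT)]

    def families(self) -> dict[str, list[str]]:
        """Map family label -> offspring ids (founders carry no family)."""
        out: dict[str, list[str]] = {}
        for row in self.offspring.itertuples(index=False):
            out.setdefault(row.family, []).append(row.id)
        return out

    def parents_of(self) -> dict[str, tuple[str, str]]:
        return {
            row.id: (row.sire, row.dam) for row in self.table.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix in {0, 1, 2}, NaN for missing calls.

    ``locus_map`` optionally assigns each SNP to a gene locus (used for
    redundancy summaries and locus-aware bookkeeping).
    """

    ids: list[str]
    snp_ids: list[str]
    values: np.ndarray  # float array, shape (n_ind, n_snp), NaN = missing
    locus_map: pd.Series | None = None  # index snp_id -> locus id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated individual ids in genotype matrix")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.values[~ok])
            raise ValueError(f"genotype codes outside {{0,1,2,missing}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def call_rate_individuals(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=1)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        index = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [index[s] for s in snp_ids]
        lm = None
        if self.locus_map is not None:
            lm = self.locus_map.loc[snp_ids]
        return GenotypeMatrix(
            ids=list(self.ids),
            snp_ids=list(snp_ids),
            values=self.values[:, cols].copy(),
            locus_map=lm,
        )

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            ids=list(ids),
            snp_ids=list(self.snp_ids),
            values=self.values[rows, :].copy(),
            locus_map=None if self.locus_map is None else self.locus_map.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.snp_ids)


@dataclass
class RelationshipMatrix:
    """Symmetric relatedness matrix with aligned genotype ids.

    ``kind`` is one of A, D, Ga, Gd, Ga_blended, Gd_blended.  ``provenance``
    records where the matrix came from (SNP count or pedigree size).
    """

    values: np.ndarray
    ids: list[str]
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicated ids in relationship matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    def align(self, ids: list[str]) -> np.ndarray:
        """Return the sub-matrix for ``ids`` in that order."""
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids absent from {self.kind} matrix: {missing[:10]}")
        rows = np.asarray([index[s] for s in ids])
        return self.values[np.ix_(rows, rows)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
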