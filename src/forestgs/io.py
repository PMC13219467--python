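"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (unphased GT) or CSV matrices (individuals as rows,
SNP ids as header); pedigree, phenotypes, relationship matrices, genetic
values and density curves as CSV; run configuration and manifests as
YAML/JSON.  Referential integrity between tables is checked on read and
every orphan reference is listed, not just the first.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import UNKNOWN_PARENT, GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes_csv",
    "write_genotypes_vcf",
    "read_tables",
    "write_relationship_csv",
    "read_relationship_csv",
    "write_manifest",
]

_UNKNOWN_CODES = {"0", "NA", "", "nan", ".", "None"}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; round-trips via YAML."""

    genotypes: str = ""
    pedigree: str = ""
    phenotypes: str = ""
    locus_map: str = ""
    method: str = "gblup"
    use_plot: bool = False
    blend_weight: float = 0.02
    qc: dict = field(default_factory=dict)
    grid: list[int] | None = None
    replicates: int = 5
    cv_folds: int = 10
    cv_repetitions: int = 1
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated individual ids: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    looks_like_snp_rows = df.shape[0] > 0 and all(
        str(c).upper().startswith(("IND", "TREE", "GENO")) for c in df.columns[:3]
    )
    if looks_like_snp_rows:
        raise ValueError(
            "genotype CSV appears transposed (SNPs as rows); expected "
            "individuals as rows with a header of SNP ids — transpose the "
            "file and retry"
        )
    return GenotypeMatrix(
        ids=[str(i) for i in df.index],
        snp_ids=[str(c) for c in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        gts = var.genotype.array()
        if gts.shape[1] > 3:
            raise ValueError(f"non-diploid record at {var.CHROM}:{var.POS}")
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        rows.append(alleles.sum(axis=1))
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample ids in VCF")
    return GenotypeMatrix(
        ids=ids, snp_ids=snp_ids, values=np.asarray(rows).T
    )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from VCF or CSV (auto-detected by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "csv")
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    if fmt == "csv":
        return _read_genotypes_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes_csv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    genotypes.to_frame().to_csv(path, index_label="id")


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal unphased-GT VCF export (one pseudo-contig, dosage recoded as
    0/0, 0/1, 1/1, ./. for missing)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.ids) + "\n"
        )
        for j, snp in enumerate(genotypes.snp_ids):
            col = genotypes.values[:, j]
            gts = "\t".join(
                "./." if np.isnan(v) else code[float(v)] for v in col
            )
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_tables(
    pedigree_path: str | Path,
    phenotype_path: str | Path,
    locus_map_path: str | Path | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> tuple[Pedigree, pd.DataFrame, pd.Series | None]:
    """Load pedigree + phenotypes (+ optional SNP->locus map) with
    referential-integrity checks."""
    ped_df = pd.read_csv(pedigree_path, dtype=str).fillna("")
    for col in ("id", "sire", "dam"):
        if col not in ped_df.columns:
            raise ValueError(f"pedigree CSV missing column {col!r}")
        ped_df[col] = ped_df[col].map(
            lambda v: UNKNOWN_PARENT if v.strip() in _UNKNOWN_CODES else v.strip()
        )
    if "family" not in ped_df.columns:
        ped_df["family"] = [
            f"{s}x{d}" if s or d else "" for s, d in zip(ped_df["sire"], ped_df["dam"])
        ]
    if "generation" not in ped_df.columns:
        ped_df["generation"] = [
            0 if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT else 1
            for s, d in zip(ped_df["sire"], ped_df["dam"])
        ]
    ped_df["generation"] = ped_df["generation"].astype(int)
    pedigree = Pedigree(ped_df[["id", "sire", "dam", "family", "generation"]])

    pheno = pd.read_csv(phenotype_path)
    for col in ("genotype", "site", "block"):
        if col not in pheno.columns:
            raise ValueError(f"phenotype CSV missing column {col!r}")
    if "tree" not in pheno.columns:
        pheno["tree"] = pheno["genotype"]
    pheno["genotype"] = pheno["genotype"].astype(str)

    ped_ids = set(pedigree.ids)
    orphans = sorted(set(pheno["genotype"]) - ped_ids)
    if orphans:
        raise ValueError(
            f"{len(orphans)} phenotyped genotypes absent from pedigree: {orphans}"
        )
    if genotypes is not None:
        missing = sorted(set(pheno["genotype"]) - set(genotypes.ids))
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped genotypes absent from genotype "
                f"matrix: {missing}"
            )
    if "family" not in pheno.columns:
        fam = dict(zip(pedigree.table["id"], pedigree.table["family"]))
        pheno["family"] = pheno["genotype"].map(fam)

    locus_map = None
    if locus_map_path is not None:
        lm = pd.read_csv(locus_map_path, dtype=str)
        if not {"snp", "locus"} <= set(lm.columns):
            raise ValueError("locus map CSV needs columns snp,locus")
        locus_map = lm.set_index("snp")["locus"]
    return pedigree, pheno, locus_map


def write_relationship_csv(matrix: RelationshipMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index_label="id")


def read_relationship_csv(path: str | Path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(
        values=df.to_numpy(dtype=float),
        ids=[str(i) for i in df.index],
        kind=kind,
    )


def write_pedigree_csv(pedigree: Pedigree, path: str | Path) -> None:
    out = pedigree.table.copy()
    out.loc[out["sire"] == UNKNOWN_PARENT, "sire"] = "0"
    out.loc[out["dam"] == UNKNOWN_PARENT, "dam"] = "0"
    out.to_csv(path, index=False)


def write_manifest(
    out_dir: str | Path, config: RunConfig, extra: dict | None = None
) -> Path:
    """JSON run manifest: resolved config, seed, package version, wall time."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
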