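"""Marker-density resampling study.

For a grid of SNP subset sizes, random subsets are drawn with replication;
for each draw the genomic relationship matrices are rebuilt, blended with
their pedigree counterparts, the GBLUP-AD model is refit, heritability
estimates recomputed, and (optionally) within-family cross-validation rerun.
Means and standard deviations over replicates per subset size form the
density curve, with the full-panel GBLUP-AD and the pedigree-only ABLUP-AD
fits attached as reference lines.  No automatic plateau breakpoint is
computed — curves and replicate SDs are the deliverable — but an advisory
heuristic (first size whose mean stays inside a band around the full-panel
estimate) is available as a clearly-labelled extension.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree, RelationshipMatrix
from .genpar import heritability_estimates
from .kinship import blend_and_invert, build_A, build_D, build_Ga, build_Gd
from .mixedmodel import ModelData, ModelSpec, reml_fit
from .cv import run_cross_validation

__all__ = [
    "snp_grid",
    "subsample_snps",
    "DensityCurve",
    "run_density_study",
    "advisory_plateau_size",
]

_METRICS = ["h2", "d2", "H2", "PA_BV", "PA_GV", "PACC_BV", "PACC_GV"]


def snp_grid(total_snps: int, step: int = 1000, start: int = 500) -> list[int]:
    """Arithmetic subset-size grid start, start+step, ... with the full
    panel size appended.  Explicit lists can be passed straight to
    ``run_density_study`` instead."""
    if start > total_snps:
        raise ValueError(f"start {start} exceeds total SNPs {total_snps}")
    sizes = list(range(start, total_snps, step))
    sizes.append(total_snps)
    return sizes


def log_grid(total_snps: int, n_points: int = 8, start: int = 500) -> list[int]:
    """Logarithmically spaced grid for very large panels."""
    if start > total_snps:
        raise ValueError(f"start {start} exceeds total SNPs {total_snps}")
    pts = np.unique(
        np.round(np.geomspace(start, total_snps, n_points)).astype(int)
    )
    return [int(p) for p in pts]


def subsample_snps(
    genotypes: GenotypeMatrix, n: int, seed: int
) -> GenotypeMatrix:
    """Uniform draw of n SNPs without replacement; individuals unchanged,
    locus map restricted to the drawn SNPs."""
    if n > genotypes.n_snps:
        raise ValueError(f"cannot draw {n} SNPs from {genotypes.n_snps}")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(genotypes.n_snps, size=n, replace=False))
    return genotypes.subset_snps([genotypes.snp_ids[int(j)] for j in cols])


@dataclass
class DensityCurve:
    """Aggregated study output plus reference fits."""

    summary: pd.DataFrame  # one row per subset size: mean/sd per metric
    cells: pd.DataFrame  # one row per (size, replicate)
    full_panel: dict[str, float]
    ablup: dict[str, float]
    failures: list[dict] = field(default_factory=list)


def _dataset_hash(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.nan_to_num(genotypes.values, nan=-1.0)))
    h.update(phenotypes["y"].to_numpy().tobytes())
    return h.hexdigest()[:16]


def _fit_cell(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    A: RelationshipMatrix,
    D: RelationshipMatrix,
    spec: ModelSpec,
    blend_weight: float,
    cv_options: dict | None,
    seed: int,
) -> dict[str, float]:
    Ga, _ = blend_and_invert(build_Ga(genotypes), A, blend_weight)
    Gd, _ = blend_and_invert(build_Gd(genotypes), D, blend_weight)
    data = ModelData(phenotypes, Ga, Gd, spec)
    fit = reml_fit(data)
    est = heritability_estimates(fit.components)
    out = {"h2": est.h2, "d2": est.d2, "H2": est.H2,
           "converged": float(fit.converged)}
    if cv_options is not None:
        metrics, _ = run_cross_validation(
            phenotypes, Ga, Gd, spec=spec, seed=seed,
            k=cv_options.get("k", 10),
            repetitions=cv_options.get("repetitions", 1),
        )
        out.update(metrics.as_dict())
    return out


def run_density_study(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    grid: list[int] | None = None,
    replicates: int = 5,
    spec: ModelSpec | None = None,
    blend_weight: float = 0.02,
    cv_options: dict | None = None,
    seed: int = 0,
    cache_dir: str | Path | None = None,
) -> DensityCurve:
    """Run the full resampling study.

    Per grid size x replicate: draw a SNP subset, rebuild and blend Ga/Gd,
    refit GBLUP-AD, recompute heritability estimates, optionally rerun
    cross-validation.  A failed cell is recorded and excluded from the
    aggregation; the run continues.  With ``cache_dir`` each cell's result
    is stored as JSON keyed on (dataset hash, size, replicate seed), making
    interrupted runs resumable.
    """
    spec = spec or ModelSpec(method="gblup")
    grid = sorted(grid) if grid is not None else snp_grid(genotypes.n_snps)
    A = build_A(pedigree)
    D = build_D(pedigree)

    dhash = _dataset_hash(genotypes, phenotypes)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    # reference fits
    full = _fit_cell(genotypes, phenotypes, A, D, spec, blend_weight,
                     cv_options, seed)
    ablup_spec = ModelSpec(method="ablup", use_plot=spec.use_plot)
    ablup = _fit_cell_pedigree(phenotypes, A, D, ablup_spec, cv_options, seed)

    rows = []
    failures: list[dict] = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = {
        (size, rep): int(s.generate_state(1)[0] % (2 ** 31))
        for (size, rep), s in zip(
            [(size, rep) for size in grid for rep in range(replicates)],
            ss.spawn(len(grid) * replicates),
        )
    }
    for size in grid:
        for rep in range(replicates):
            cell_seed = cell_seeds[(size, rep)]
            key = f"{dhash}_{size}_{cell_seed}.json"
            if cache is not None and (cache / key).exists():
                result = json.loads((cache / key).read_text())
            else:
                try:
                    subset = subsample_snps(genotypes, size, cell_seed)
                    result = _fit_cell(subset, phenotypes, A, D, spec,
                                       blend_weight, cv_options, cell_seed)
                except Exception as exc:  # noqa: BLE001 — cell-level isolation
                    failures.append(
                        {"size": size, "replicate": rep, "error": str(exc)}
                    )
                    continue
                if cache is not None:
                    (cache / key).write_text(json.dumps(result))
            rows.append({"size": size, "replicate": rep, **result})

    cells = pd.DataFrame(rows)
    summary_rows = []
    for size in grid:
        sub = cells[cells["size"] == size]
        row: dict[str, float] = {"size": size, "n_replicates": len(sub)}
        for m in _METRICS:
            if m in sub.columns:
                row[f"{m}_mean"] = float(sub[m].mean())
                row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        for m in _METRICS:
            if m in full:
                row[f"{m}_full_panel"] = full[m]
            if m in ablup:
                row[f"{m}_ablup"] = ablup[m]
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    return DensityCurve(summary=summary, cells=cells, full_panel=full,
                        ablup=ablup, failures=failures)


def _fit_cell_pedigree(
    phenotypes: pd.DataFrame,
    A: RelationshipMatrix,
    D: RelationshipMatrix,
    spec: ModelSpec,
    cv_options: dict | None,
    seed: int,
) -> dict[str, float]:
    data = ModelData(phenotypes, A, D, spec)
    fit = reml_fit(data)
    est = heritability_estimates(fit.components)
    out = {"h2": est.h2, "d2": est.d2, "H2": est.H2,
           "converged": float(fit.converged)}
    if cv_options is not None:
        metrics, _ = run_cross_validation(
            phenotypes, A, D, spec=spec, seed=seed,
            k=cv_options.get("k", 10),
            repetitions=cv_options.get("repetitions", 1),
        )
        out.update(metrics.as_dict())
    return out


def advisory_plateau_size(
    curve: DensityCurve, metric: str = "h2", band: float | None = None
) -> int | None:
    """ADVISORY heuristic, not a formal breakpoint: the smallest subset size
    from which the metric's mean stays within a band of the full-panel value
    for all larger sizes.  ``band`` defaults to the replicate SD at the
    largest subset size."""
    s = curve.summary.sort_values("size")
    full = curve.full_panel[metric]
    if band is None:
        band = max(float(s[f"{metric}_sd"].iloc[-1]), 1e-6)
    ok = (s[f"{metric}_mean"] - full).abs() <= band
    sizes = s["size"].tolist()
    for i in range(len(sizes)):
        if ok.iloc[i:].all():
            return int(sizes[i])
    return None
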