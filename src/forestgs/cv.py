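"""Within-family k-fold cross-validation of genomic-prediction models.

Genotypes are split into k folds stratified by full-sib family (each fold
holds as close to 1/k of every family as integers allow).  For each fold the
mixed model is refit with the validation phenotypes withheld by deleting
their records — the relationship matrices keep all genotypes, so BLUPs for
the withheld genotypes flow through kinship — and the withheld genotypes'
site-level EBV/EDV are predicted.  Metrics:

* predictive ability  PA_BV / PA_GV: Pearson correlation of cross-validated
  EBV / EGV with the raw observed phenotype, within each site, using each
  genotype's home-site prediction;
* prediction accuracy PACC_BV / PACC_GV: correlation of cross-validated
  values with the full-data-model values used as truth proxies;

each averaged over sites and repetitions.  When clonal ramets exist, one
ramet per clone is drawn at random per repetition and folding happens at
the genotype (clone) level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodel import (
    ModelData,
    ModelFit,
    ModelSpec,
    predict_genetic_values,
    reml_fit,
    solve_blups,
)

__all__ = [
    "FoldAssignment",
    "CVMetrics",
    "make_folds",
    "cross_validate",
    "cv_metrics",
    "run_cross_validation",
]


@dataclass
class FoldAssignment:
    """Genotype -> fold index (1..k), for one repetition."""

    folds: dict[str, int]
    k: int
    repetition: int = 0
    seed: int = 0

    def validation_set(self, fold: int) -> list[str]:
        return [g for g, f in self.folds.items() if f == fold]


def make_folds(
    families: pd.Series | dict[str, str],
    k: int = 10,
    seed: int = 0,
    repetition: int = 0,
) -> FoldAssignment:
    """Family-stratified random partition of genotypes into k folds.

    ``families`` maps genotype id -> family label.  Within every family the
    fold sizes differ by at most one: members are shuffled and dealt
    round-robin onto a per-family random permutation of the folds.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if isinstance(families, dict):
        families = pd.Series(families)
    rng = np.random.default_rng(np.random.SeedSequence([seed, repetition]))
    assignment: dict[str, int] = {}
    for fam in sorted(families.unique()):
        members = sorted(families.index[families == fam].tolist())
        rng.shuffle(members)
        fold_order = rng.permutation(k)
        for i, g in enumerate(members):
            assignment[g] = int(fold_order[i % k]) + 1
    return FoldAssignment(folds=assignment, k=k, repetition=repetition, seed=seed)


@dataclass
class CVPredictions:
    """Cross-validated and full-model genetic values for every genotype."""

    table: pd.DataFrame  # genotype, site(home), fold, cv_ebv, cv_egv,
    #                      full_ebv, full_egv, phenotype
    fold_fits: list[ModelFit] = field(default_factory=list)


def _home_site_values(values: pd.DataFrame) -> pd.DataFrame:
    t = values
    return t[t["site"] == t["home_site"]].set_index("genotype")


def cross_validate(
    data: ModelData,
    folds: FoldAssignment,
    full_fit: ModelFit,
    max_iter: int = 60,
) -> CVPredictions:
    """Refit per fold with validation phenotypes withheld; predict withheld
    genotypes at their home site.  Every genotype is predicted exactly once.
    Fold refits warm-start at the full-model components."""
    full_values, _ = solve_blups(full_fit, data, force=True)
    full_home = _home_site_values(full_values.table)

    pheno_by_geno = data.df.groupby("genotype", sort=False)["y"].mean()

    rows = []
    fits = []
    for fold in range(1, folds.k + 1):
        held = set(folds.validation_set(fold))
        if not held:
            continue
        train_df = data.df[~data.df["genotype"].isin(held)]
        for s in data.sites:
            if (train_df["site"] == s).sum() == 0:
                raise ValueError(
                    f"withholding fold {fold} empties site {s}; reduce k"
                )
        train = ModelData(
            train_df, data.K_additive, data.K_dominance, data.spec
        )
        fit = reml_fit(train, start=full_fit.components, max_iter=max_iter,
                       restarts=False)
        fits.append(fit)
        held_sorted = sorted(held)
        pred = predict_genetic_values(fit, train, held_sorted)
        vt = pred.set_index(["genotype", "site"])
        for g in held_sorted:
            home = data.home_site[g]
            ebv = float(vt.loc[(g, home), "ebv"])
            egv = float(vt.loc[(g, home), "egv"])
            rows.append(
                {
                    "genotype": g,
                    "site": home,
                    "fold": fold,
                    "cv_ebv": ebv,
                    "cv_egv": egv,
                    "full_ebv": float(full_home.loc[g, "ebv"]),
                    "full_egv": float(full_home.loc[g, "egv"]),
                    "phenotype": float(pheno_by_geno.loc[g]),
                }
            )
    table = pd.DataFrame(rows)
    counts = table["genotype"].value_counts()
    if (counts != 1).any():
        raise RuntimeError("internal error: a genotype was predicted twice")
    return CVPredictions(table=table, fold_fits=fits)


@dataclass
class CVMetrics:
    """Site-averaged predictive ability and prediction accuracy."""

    pa_bv: float
    pa_gv: float
    pacc_bv: float
    pacc_gv: float
    per_site: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "PA_BV": self.pa_bv,
            "PA_GV": self.pa_gv,
            "PACC_BV": self.pacc_bv,
            "PACC_GV": self.pacc_gv,
        }


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cv_metrics(predictions: pd.DataFrame) -> CVMetrics:
    """Per-site Pearson correlations, averaged over sites.

    Sites where a prediction vector has zero variance (or fewer than three
    genotypes) are flagged and excluded from the average.
    """
    pairs = [
        ("PA_BV", "cv_ebv", "phenotype"),
        ("PA_GV", "cv_egv", "phenotype"),
        ("PACC_BV", "cv_ebv", "full_ebv"),
        ("PACC_GV", "cv_egv", "full_egv"),
    ]
    warnings: list[str] = []
    rows = []
    for site, grp in predictions.groupby("site"):
        row = {"site": site, "n": len(grp)}
        for name, a, b in pairs:
            r = _safe_corr(grp[a].to_numpy(), grp[b].to_numpy())
            if np.isnan(r):
                warnings.append(
                    f"{name} undefined at site {site} (degenerate vector); "
                    "excluded from the average"
                )
            row[name] = r
        rows.append(row)
    per_site = pd.DataFrame(rows)
    means = {name: float(np.nanmean(per_site[name])) for name, *_ in pairs}
    return CVMetrics(
        pa_bv=means["PA_BV"],
        pa_gv=means["PA_GV"],
        pacc_bv=means["PACC_BV"],
        pacc_gv=means["PACC_GV"],
        per_site=per_site,
        warnings=warnings,
    )


def _select_ramets(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One randomly chosen ramet (tree record set) per genotype, for trials
    with clonal replicates."""
    if "tree" not in df.columns or df["tree"].equals(df["genotype"]):
        return df
    keep_rows = []
    for g, grp in df.groupby("genotype", sort=False):
        trees = grp["tree"].unique()
        chosen = trees[rng.integers(len(trees))]
        keep_rows.append(grp[grp["tree"] == chosen])
    return pd.concat(keep_rows, ignore_index=True)


def run_cross_validation(
    phenotypes: pd.DataFrame,
    K_additive,
    K_dominance,
    spec: ModelSpec | None = None,
    k: int = 10,
    repetitions: int = 1,
    seed: int = 0,
) -> tuple[CVMetrics, pd.DataFrame]:
    """Full CV driver: per repetition, redraw ramets and folds, refit per
    fold, compute metrics; return the over-repetition average plus the
    per-repetition, per-site table."""
    spec = spec or ModelSpec()
    rep_rows = []
    all_sites = []
    for rep in range(repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep, 7]))
        df = _select_ramets(phenotypes, rng)
        data = ModelData(df, K_additive, K_dominance, spec)
        full_fit = reml_fit(data)
        families = df.groupby("genotype", sort=False)["family"].first()
        folds = make_folds(families, k=k, seed=seed, repetition=rep)
        preds = cross_validate(data, folds, full_fit)
        metrics = cv_metrics(preds.table)
        row = {"repetition": rep, **metrics.as_dict()}
        rep_rows.append(row)
        site_table = metrics.per_site.copy()
        site_table["repetition"] = rep
        all_sites.append(site_table)
    rep_table = pd.DataFrame(rep_rows)
    agg = CVMetrics(
        pa_bv=float(rep_table["PA_BV"].mean()),
        pa_gv=float(rep_table["PA_GV"].mean()),
        pacc_bv=float(rep_table["PACC_BV"].mean()),
        pacc_gv=float(rep_table["PACC_GV"].mean()),
        per_site=pd.concat(all_sites, ignore_index=True),
    )
    return agg, rep_table
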