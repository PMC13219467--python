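"""SNP and individual quality control for progeny-trial genotype panels.

Filters follow standard array-genotyping practice for structured full-sib
populations: per-SNP call rate, minor allele frequency, fixation-index
bound, an explicit non-singleton check, optional reproducibility from
replicated controls, per-individual call rate, and Mendelian consistency
checks against the pedigree (trio incompatibilities plus an exact
segregation test within informative families).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import UNKNOWN_PARENT, GenotypeMatrix, Pedigree

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_snps_and_individuals",
    "mendelian_checks",
    "summarize_locus_redundancy",
    "exact_multinomial_pvalue",
]


@dataclass
class QCThresholds:
    """Quality-filter thresholds; defaults mirror common SNP-array practice."""

    min_snp_call_rate: float = 0.90
    min_maf: float = 0.01
    max_abs_fixation_index: float = 0.50
    min_reproducibility: float = 0.95
    min_individual_call_rate: float = 0.90
    max_mendelian_error_fraction: float = 0.05
    segregation_alpha: float = 0.001
    max_failing_families: int = 3
    min_family_size: int = 10

    def __post_init__(self) -> None:
        for name in (
            "min_snp_call_rate", "min_maf", "max_abs_fixation_index",
            "min_reproducibility", "min_individual_call_rate",
            "max_mendelian_error_fraction", "segregation_alpha",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-filter removal counts and a summary of the retained panel."""

    input_snps: int
    input_individuals: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_individuals: int = 0
    retained_snps: int = 0
    retained_individuals: int = 0
    summary: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "input_snps": self.input_snps,
            "input_individuals": self.input_individuals,
            "removed_snps_by_filter": dict(self.removed),
            "removed_individuals": self.removed_individuals,
            "retained_snps": self.retained_snps,
            "retained_individuals": self.retained_individuals,
            "retained_summary": dict(self.summary),
            "notes": list(self.notes),
        }


def _freq_stats(values: np.ndarray):
    """Allele frequency, MAF, minor-allele count, observed/expected
    heterozygosity per SNP, from non-missing calls (pooled across families)."""
    with np.errstate(invalid="ignore"):
        n_called = np.sum(~np.isnan(values), axis=0).astype(float)
        p = np.nansum(values, axis=0) / np.maximum(2.0 * n_called, 1.0)
        maf = np.minimum(p, 1.0 - p)
        mac = np.minimum(np.nansum(values, axis=0),
                         2.0 * n_called - np.nansum(values, axis=0))
        h_obs = np.nansum(values == 1.0, axis=0) / np.maximum(n_called, 1.0)
        h_exp = 2.0 * p * (1.0 - p)
    return p, maf, mac, h_obs, h_exp, n_called


def fixation_index(values: np.ndarray) -> np.ndarray:
    """F_e = 1 - observed heterozygosity / expected heterozygosity (2pq)."""
    _, _, _, h_obs, h_exp, _ = _freq_stats(values)
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = 1.0 - h_obs / h_exp
    fe[h_exp == 0.0] = 0.0
    return fe


def filter_snps_and_individuals(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    reproducibility: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP filters, then drop low-call-rate individuals.

    SNP filters in order: call rate, MAF (which also removes singletons;
    a minor-allele-count >= 2 check is enforced explicitly as well),
    fixation-index bound, and — when per-SNP reproducibility rates from
    replicated controls are supplied — the reproducibility filter.
    """
    th = thresholds or QCThresholds()
    report = QCReport(
        input_snps=genotypes.n_snps, input_individuals=genotypes.n_individuals
    )
    for key in ("call_rate", "maf_or_singleton", "fixation_index"):
        report.removed[key] = 0
    if reproducibility is not None:
        reproducibility = np.asarray(reproducibility, dtype=float)
        if reproducibility.shape != (genotypes.n_snps,):
            raise ValueError("reproducibility must be one rate per input SNP")
        repro = pd.Series(reproducibility, index=genotypes.snp_ids)
        report.removed["reproducibility"] = 0
    else:
        repro = None
        report.notes.append(
            "reproducibility filter skipped: no replicated-control rates supplied"
        )

    # SNP and individual filters interact (dropping individuals shifts SNP
    # statistics), so both stages iterate to a fixpoint: re-filtering the
    # output removes nothing
    out = genotypes
    while True:
        values = out.values
        keep = np.ones(out.n_snps, dtype=bool)

        call = out.call_rate_snps()
        fail = keep & (call < th.min_snp_call_rate)
        report.removed["call_rate"] += int(fail.sum())
        keep &= ~fail

        _, maf, mac, _, _, _ = _freq_stats(values)
        fail = keep & ((maf < th.min_maf) | (mac < 2))
        report.removed["maf_or_singleton"] += int(fail.sum())
        keep &= ~fail

        fe = fixation_index(values)
        fail = keep & (np.abs(fe) > th.max_abs_fixation_index)
        report.removed["fixation_index"] += int(fail.sum())
        keep &= ~fail

        if repro is not None:
            fail = keep & (repro.loc[out.snp_ids].to_numpy()
                           < th.min_reproducibility)
            report.removed["reproducibility"] += int(fail.sum())
            keep &= ~fail

        if not keep.any():
            raise ValueError(
                "all SNPs removed by quality filters; review the thresholds"
            )
        snps_changed = not keep.all()
        if snps_changed:
            out = out.subset_snps(
                [s for s, k in zip(out.snp_ids, keep) if k]
            )

        ind_keep = out.call_rate_individuals() >= th.min_individual_call_rate
        report.removed_individuals += int((~ind_keep).sum())
        if not ind_keep.all():
            out = out.subset_individuals(
                [s for s, k in zip(out.ids, ind_keep) if k]
            )
        if not snps_changed and ind_keep.all():
            break

    report.retained_snps = out.n_snps
    report.retained_individuals = out.n_individuals
    _, maf2, _, _, _, _ = _freq_stats(out.values)
    report.summary = {
        "mean_maf": float(np.mean(maf2)),
        "mean_fixation_index": float(np.mean(fixation_index(out.values))),
        "mean_call_rate": float(np.mean(out.call_rate_snps())),
    }
    report.notes.append("allele frequencies pooled across families")
    return out, report


# Possible offspring dosages given unordered parent dosages.
_ALLOWED = np.zeros((3, 3, 3), dtype=bool)
for _gs in range(3):
    for _gd in range(3):
        _s_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[_gs]
        _d_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[_gd]
        for _a in _s_alleles:
            for _b in _d_alleles:
                _ALLOWED[_gs, _gd, _a + _b] = True

# Mendelian expected genotype proportions over {0,1,2} for each parent pair.
_EXPECTED = {
    (0, 0): np.array([1.0, 0.0, 0.0]),
    (0, 1): np.array([0.5, 0.5, 0.0]),
    (0, 2): np.array([0.0, 1.0, 0.0]),
    (1, 1): np.array([0.25, 0.5, 0.25]),
    (1, 2): np.array([0.0, 0.5, 0.5]),
    (2, 2): np.array([0.0, 0.0, 1.0]),
}


def exact_multinomial_pvalue(
    counts: np.ndarray, probs: np.ndarray, max_enumeration: int = 400
) -> float:
    """Exact multinomial goodness-of-fit p-value.

    Sums the probability of every outcome no more probable than the observed
    one.  Zero-probability categories must hold zero counts (otherwise the
    outcome is impossible and p = 0).  Falls back to the chi-square
    approximation when the total count exceeds ``max_enumeration``.
    """
    counts = np.asarray(counts, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if counts[probs == 0.0].sum() > 0:
        return 0.0
    support = probs > 0.0
    counts = counts[support]
    probs = probs[support]
    n = int(counts.sum())
    if n == 0:
        return 1.0
    k = counts.size
    if k == 1:
        return 1.0
    if n > max_enumeration:
        expected = n * probs
        stat = float(np.sum((counts - expected) ** 2 / expected))
        return float(chi2.sf(stat, k - 1))

    log_probs = np.log(probs)
    lgamma = math.lgamma

    def log_pmf(vec: tuple[int, ...]) -> float:
        out = lgamma(n + 1)
        for c, lp in zip(vec, log_probs):
            out += c * lp - lgamma(c + 1)
        return out

    observed = log_pmf(tuple(counts))
    total = 0.0

    def recurse(prefix: list[int], remaining: int, depth: int) -> None:
        nonlocal total
        if depth == k - 1:
            vec = tuple(prefix + [remaining])
            lp = log_pmf(vec)
            if lp <= observed + 1e-9:
                total += math.exp(lp)
            return
        for c in range(remaining + 1):
            recurse(prefix + [c], remaining - c, depth + 1)

    recurse([], n, 0)
    return min(1.0, total)


@dataclass
class MendelianReport:
    """Outcome of pedigree-consistency checks on a genotype panel."""

    flagged_error_rate: list[str]
    flagged_segregation: list[str]
    error_fraction: pd.Series  # per SNP, over tested trios
    family_incompatibilities: pd.DataFrame  # family x snp counts (long form)
    n_untested_trios: int

    @property
    def flagged(self) -> list[str]:
        return sorted(set(self.flagged_error_rate) | set(self.flagged_segregation))


def mendelian_checks(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    thresholds: QCThresholds | None = None,
) -> MendelianReport:
    """Trio incompatibility counts and within-family segregation tests.

    A genotype is incompatible when impossible under Mendelian transmission
    from its parents' genotypes.  SNPs with an incompatibility fraction at or
    above the threshold are flagged; SNPs whose genotype counts depart from
    the Mendelian expected ratios (exact multinomial test at the configured
    alpha) in more than the allowed number of sufficiently large families are
    flagged as segregation-distorted.  Trios with a missing parental
    genotype are skipped and counted as untested.
    """
    th = thresholds or QCThresholds()
    gidx = {s: i for i, s in enumerate(genotypes.ids)}
    trios = []  # (offspring row, sire row, dam row, family)
    n_untested = 0
    for row in pedigree.offspring.itertuples(index=False):
        if row.id not in gidx or row.sire not in gidx or row.dam not in gidx:
            n_untested += 1
            continue
        trios.append((gidx[row.id], gidx[row.sire], gidx[row.dam], row.family))
    if not trios:
        raise ValueError("no offspring with both parents genotyped")

    V = genotypes.values
    off = np.array([t[0] for t in trios])
    sire = np.array([t[1] for t in trios])
    dam = np.array([t[2] for t in trios])
    fams = np.array([t[3] for t in trios])

    Go, Gs, Gd = V[off], V[sire], V[dam]
    tested = ~(np.isnan(Go) | np.isnan(Gs) | np.isnan(Gd))
    incompat = np.zeros_like(tested)
    m = tested
    incompat[m] = ~_ALLOWED[
        Gs[m].astype(int), Gd[m].astype(int), Go[m].astype(int)
    ]

    n_tested = tested.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        err_frac = incompat.sum(axis=0) / np.maximum(n_tested, 1.0)
    err_series = pd.Series(err_frac, index=genotypes.snp_ids, name="error_fraction")
    flagged_err = [
        s for s, e, nt in zip(genotypes.snp_ids, err_frac, n_tested)
        if nt > 0 and e >= th.max_mendelian_error_fraction
    ]

    fam_rows = []
    fail_counts = np.zeros(genotypes.n_snps, dtype=int)
    for fam in np.unique(fams):
        sel = fams == fam
        if sel.sum() < th.min_family_size:
            continue
        go, gs, gd = Go[sel], Gs[sel], Gd[sel]
        # one parental pair per full-sib family; take it per SNP from the
        # first trio (all trios in a family share parents)
        ps = gs[0].astype(float)
        pd_ = gd[0].astype(float)
        for j in range(genotypes.n_snps):
            if np.isnan(ps[j]) or np.isnan(pd_[j]):
                continue
            pair = tuple(sorted((int(ps[j]), int(pd_[j]))))
            probs = _EXPECTED[pair]
            if (probs > 0).sum() < 2:
                continue  # uninformative cross
            col = go[:, j]
            col = col[~np.isnan(col)]
            if col.size < th.min_family_size:
                continue
            counts = np.bincount(col.astype(int), minlength=3)
            pval = exact_multinomial_pvalue(counts, probs)
            fam_rows.append(
                {"family": fam, "snp": genotypes.snp_ids[j],
                 "n": int(col.size), "p_value": pval}
            )
            if pval < th.segregation_alpha:
                fail_counts[j] += 1
    flagged_seg = [
        s for s, c in zip(genotypes.snp_ids, fail_counts)
        if c > th.max_failing_families
    ]
    fam_table = pd.DataFrame(
        fam_rows, columns=["family", "snp", "n", "p_value"]
    )
    return MendelianReport(
        flagged_error_rate=flagged_err,
        flagged_segregation=flagged_seg,
        error_fraction=err_series,
        family_incompatibilities=fam_table,
        n_untested_trios=n_untested,
    )


def summarize_locus_redundancy(n_snps: int, n_loci: int) -> float:
    """Mean number of SNPs per gene locus, rounded half-up to one decimal."""
    if n_loci <= 0 or n_snps <= 0:
        raise ValueError("SNP and locus counts must be positive")
    if n_snps < n_loci:
        raise ValueError("cannot have fewer SNPs than gene loci")
    ratio = Decimal(n_snps) / Decimal(n_loci)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def locus_redundancy_from_map(locus_map: pd.Series) -> float:
    """Redundancy summary computed from a SNP -> locus map by counting."""
    return summarize_locus_redundancy(len(locus_map), locus_map.nunique())
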