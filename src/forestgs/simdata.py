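"""Synthetic partial-diallel, two-site progeny-trial generator.

Emulates the structure of conifer breeding trials: full-sib families from a
partial diallel mating design, offspring planted on two sites in a
randomized complete block layout with small row plots, SNP panels with
configurable SNP-per-locus redundancy, and traits with site-specific
additive and dominance architecture linked across sites by type-B genetic
correlations.  Every downstream stage (QC, kinship, REML, cross-validation,
marker-density study) can therefore be checked against known truth.

All randomness flows from one user seed through named independent
substreams (pedigree, genotypes, effects, design, noise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import UNKNOWN_PARENT, GenotypeMatrix, Pedigree

__all__ = [
    "TraitArchitecture",
    "TrialDesign",
    "GenomeMap",
    "SimulatedTrial",
    "make_diallel_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_trial",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (seed, stream name)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _tag(name)]))

def _tag(name: str) -> int:
    return int.from_bytes(name.encode()[:4].ljust(4, b"_"), "little")


@dataclass
class GenomeMap:
    """Linkage map: chromosome lengths in centimorgans, SNPs placed uniformly.

    The default emulates a conifer-like genome of 12 chromosomes totalling
    2000 cM.  Crossovers are Poisson along each chromosome (no interference),
    so adjacent-marker recombination fractions follow the Haldane map
    function.
    """

    chromosome_lengths_cM: tuple[float, ...] = tuple([2000.0 / 12] * 12)

    @property
    def total_cM(self) -> float:
        return float(sum(self.chromosome_lengths_cM))

    def place_snps(self, n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
        """Assign SNPs to chromosomes proportionally and sort by position."""
        lengths = np.asarray(self.chromosome_lengths_cM, dtype=float)
        probs = lengths / lengths.sum()
        chrom = rng.choice(len(lengths), size=n_snps, p=probs)
        pos = rng.uniform(0.0, lengths[chrom])
        order = np.lexsort((pos, chrom))
        return pd.DataFrame({"chrom": chrom[order], "pos_cM": pos[order]})


@dataclass
class TraitArchitecture:
    """Generating truth for one trait: QTL count, per-site variances, type-B
    correlations, design variances, residuals, and fixed site means.

    Variance symbols follow the two-site mixed model: sigma2_a / sigma2_d are
    per-site additive and dominance variances tied across sites by the
    correlations r_a and r_d; sigma2_b, sigma2_p, sigma2_e are per-site
    block, plot and residual variances.
    """

    n_qtl: int = 200
    additive_var: tuple[float, float] = (0.4, 0.4)
    r_a: float = 0.8
    dominance_var: tuple[float, float] = (0.1, 0.1)
    r_d: float = 0.8
    block_var: tuple[float, float] = (0.1, 0.1)
    plot_var: tuple[float, float] = (0.0, 0.0)
    residual_var: tuple[float, float] = (0.5, 0.5)
    site_means: tuple[float, float] = (10.0, 12.0)

    def __post_init__(self) -> None:
        for name in ("additive_var", "dominance_var", "block_var",
                     "plot_var", "residual_var"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be non-negative")
        for name in ("r_a", "r_d"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be positive")


@dataclass
class TrialDesign:
    """Field layout: two sites, randomized complete blocks, small row plots."""

    n_sites: int = 2
    blocks_per_site: int = 8
    trees_per_plot: int = 4
    ramets_per_clone: int = 1
    missing_genotype_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites != 2:
            raise ValueError("the trial design models exactly two sites")
        if self.blocks_per_site < 1 or self.trees_per_plot < 1:
            raise ValueError("blocks_per_site and trees_per_plot must be >= 1")
        if not 0.0 <= self.missing_genotype_rate < 1.0:
            raise ValueError("missing_genotype_rate must be in [0, 1)")
        if self.ramets_per_clone < 1:
            raise ValueError("ramets_per_clone must be >= 1")


def make_diallel_pedigree(
    n_parents: int,
    n_families: int,
    offspring_per_family: int,
    seed: int,
) -> Pedigree:
    """Partial diallel pedigree: unrelated founders crossed in distinct
    unordered pairs, each pair yielding a full-sib family.

    Raises ``ValueError`` when more families are requested than the
    n_parents*(n_parents-1)/2 distinct pairs available.
    """
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    max_pairs = n_parents * (n_parents - 1) // 2
    if n_families > max_pairs:
        raise ValueError(
            f"{n_families} families infeasible: {n_parents} parents allow at "
            f"most {max_pairs} distinct crosses"
        )
    if offspring_per_family < 1:
        raise ValueError("offspring_per_family must be >= 1")
    rng = _substream(seed, "pedigree")

    parents = [f"P{i + 1:03d}" for i in range(n_parents)]
    pairs = list(itertools.combinations(range(n_parents), 2))
    chosen = rng.choice(len(pairs), size=n_families, replace=False)
    chosen = sorted(int(c) for c in chosen)

    rows: list[tuple[str, str, str, str, int]] = [
        (p, UNKNOWN_PARENT, UNKNOWN_PARENT, "", 0) for p in parents
    ]
    counter = 0
    for fam_idx, pair_idx in enumerate(chosen):
        i, j = pairs[pair_idx]
        fam = f"F{fam_idx + 1:03d}"
        for _ in range(offspring_per_family):
            counter += 1
            rows.append((f"O{counter:05d}", parents[i], parents[j], fam, 1))
    table = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "family", "generation"]
    )
    return Pedigree(table)


def _founder_haplotypes(
    n_founders: int, freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg founders in linkage equilibrium: independent Bernoulli
    alleles per haplotype, shape (n_founders, 2, n_snps)."""
    return (
        rng.random((n_founders, 2, freqs.size)) < freqs[None, None, :]
    ).astype(np.int8)


def _gamete(
    haplos: np.ndarray,
    rng: np.random.Generator,
    recomb: np.ndarray | None,
) -> np.ndarray:
    """Draw one gamete from a (2, n_snps) parental haplotype pair.

    ``recomb`` gives per-interval switch probabilities between adjacent SNPs
    (0.5 across chromosome boundaries and in unlinked mode); None means fully
    independent inheritance per SNP.
    """
    n = haplos.shape[1]
    if recomb is None:
        pick = rng.integers(0, 2, size=n)
    else:
        switches = rng.random(n - 1) < recomb
        pick = np.empty(n, dtype=np.int64)
        pick[0] = rng.integers(0, 2)
        pick[1:] = (pick[0] + np.cumsum(switches)) % 2
    return haplos[pick, np.arange(n)]


def _build_locus_map(snp_ids: list[str], snps_per_locus: float) -> pd.Series:
    """Assign consecutive SNPs to gene loci hitting the requested mean
    redundancy as closely as integer counts allow."""
    n = len(snp_ids)
    n_loci = max(1, int(round(n / snps_per_locus)))
    # spread n SNPs over n_loci consecutive runs as evenly as possible
    base, extra = divmod(n, n_loci)
    loci: list[str] = []
    for k in range(n_loci):
        size = base + (1 if k < extra else 0)
        loci.extend([f"L{k + 1:06d}"] * size)
    return pd.Series(loci, index=snp_ids, name="locus")


def simulate_genotypes(
    pedigree: Pedigree,
    n_snps: int,
    snps_per_locus: float = 1.0,
    maf_bounds: tuple[float, float] = (0.05, 0.5),
    map_config: GenomeMap | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop SNP genotypes through the pedigree.

    Founders are drawn at Hardy-Weinberg proportions with per-SNP allele
    frequencies uniform on ``maf_bounds``; offspring receive Mendelian
    gametes.  By default SNPs segregate independently; with ``map_config`` a
    12-chromosome linkage map applies Haldane recombination fractions between
    adjacent SNPs.  ``snps_per_locus`` controls the SNP-to-gene-locus
    redundancy recorded in the locus map.
    """
    if len(pedigree) == 0:
        raise ValueError("empty pedigree")
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    lo, hi = maf_bounds
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_bounds must satisfy 0 < low <= high <= 0.5")
    rng = _substream(seed, "genotypes")

    freqs = rng.uniform(lo, hi, size=n_snps)
    recomb: np.ndarray | None = None
    if map_config is not None:
        placed = map_config.place_snps(n_snps, rng)
        d = np.diff(placed["pos_cM"].to_numpy())
        same = np.diff(placed["chrom"].to_numpy()) == 0
        # Haldane map function; independent assortment across chromosomes
        recomb = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * np.abs(d) / 100.0)), 0.5)

    ids = pedigree.ids
    index = {s: i for i, s in enumerate(ids)}
    haplos = np.zeros((len(ids), 2, n_snps), dtype=np.int8)
    founder_rows = [index[f] for f in pedigree.founders]
    haplos[founder_rows] = _founder_haplotypes(len(founder_rows), freqs, rng)
    for row in pedigree.offspring.itertuples(index=False):
        i = index[row.id]
        haplos[i, 0] = _gamete(haplos[index[row.sire]], rng, recomb)
        haplos[i, 1] = _gamete(haplos[index[row.dam]], rng, recomb)

    values = haplos.sum(axis=1).astype(float)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan

    snp_ids = [f"SNP{j + 1:06d}" for j in range(n_snps)]
    locus_map = _build_locus_map(snp_ids, snps_per_locus)
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, values=values,
                          locus_map=locus_map)


def _correlated_site_values(
    M: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Site-specific genetic values with realized correlation exactly r.

    Draws two independent QTL-effect vectors, maps them through the coded
    genotype matrix M, orthonormalizes the realized value vectors, and
    recombines them as v2 = r*v1 + sqrt(1-r^2)*v_perp.  Because v_perp is a
    linear combination of M-mapped effect vectors, both site values remain
    exact linear functions of QTL effects — the correlation is calibrated in
    value space without breaking marker-trait linkage.  Calibrating on the
    realized vectors matters: the family-structured genotype covariance has
    low effective rank, which would otherwise push realized correlations
    toward +/-1 well above the target.
    """
    e1 = rng.standard_normal(M.shape[1])
    e_perp = rng.standard_normal(M.shape[1])
    v1 = M @ e1
    v1 = v1 - v1.mean()
    w = M @ e_perp
    w = w - w.mean()
    denom = float(v1 @ v1)
    if denom > 0:
        w = w - (float(w @ v1) / denom) * v1
    sd1 = v1.std()
    sdw = w.std()
    v1u = v1 / sd1 if sd1 > 0 else v1
    wu = w / sdw if sdw > 0 else w
    v2 = r * v1u + np.sqrt(max(0.0, 1.0 - r * r)) * wu
    return np.column_stack([v1u, v2])


def _scale_to_variance(
    values_by_site: np.ndarray, home_site: np.ndarray, targets: tuple[float, float]
) -> np.ndarray:
    """Rescale each site column so the realized sample variance among the
    trees growing at that site equals the target (realized genic scaling)."""
    out = values_by_site.copy()
    for s in (0, 1):
        at_site = home_site == s
        v = out[at_site, s].var(ddof=1) if at_site.sum() > 1 else 0.0
        if targets[s] == 0.0:
            out[:, s] = 0.0
        elif v > 0:
            out[:, s] *= np.sqrt(targets[s] / v)
    return out


@dataclass
class SimulatedTrial:
    """Bundle of everything a synthetic run produces."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # tree, genotype, family, site, block, plot, y
    true_values: pd.DataFrame  # genotype, site, true_bv, true_dv, true_gv, home_site
    realized: dict = field(default_factory=dict)
    qtl_ids: list[str] = field(default_factory=list)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    arch: TraitArchitecture,
    design: TrialDesign,
    seed: int = 0,
) -> SimulatedTrial:
    """Simulate a two-site trial phenotype from the genotypes.

    Offspring of every family are split evenly between the two sites (so
    both sites contain every family), grouped into family row plots within
    randomized complete blocks.  Each tree's record is

        site mean + block + plot + additive(site) + dominance(site) + residual

    with site-specific QTL effects correlated across sites at r_a (additive)
    and r_d (dominance), and genetic values rescaled so realized per-site
    variances hit the architecture targets.
    """
    offspring = pedigree.offspring
    if len(offspring) == 0:
        raise ValueError("pedigree contains no offspring to phenotype")
    if arch.n_qtl > genotypes.n_snps:
        raise ValueError(
            f"{arch.n_qtl} QTLs requested but only {genotypes.n_snps} SNPs"
        )
    total_var = (
        sum(arch.additive_var) + sum(arch.dominance_var)
        + sum(arch.block_var) + sum(arch.plot_var) + sum(arch.residual_var)
    )
    if total_var <= 0:
        raise ValueError("trait architecture has zero total variance")

    rng_eff = _substream(seed, "effects")
    rng_design = _substream(seed, "design")
    rng_noise = _substream(seed, "noise")

    geno_ids = offspring["id"].tolist()
    families = offspring["family"].tolist()
    gm = genotypes.subset_individuals(geno_ids)
    dosages = gm.values.copy()
    # QTL effects act on the true simulated genotypes; fill the rare missing
    # call with the SNP mean so truth stays well defined
    if np.isnan(dosages).any():
        col_mean = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_mean[nan_c]

    qtl_idx = np.sort(
        rng_eff.choice(genotypes.n_snps, size=arch.n_qtl, replace=False)
    )
    qtl_ids = [genotypes.snp_ids[int(j)] for j in qtl_idx]
    X = dosages[:, qtl_idx]
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)  # monomorphic QTLs carry no variance
    X = X[:, keep]
    p = p[keep]
    n_qtl = X.shape[1]

    # home site: alternate within family so both sites contain every family
    fam_series = pd.Series(families)
    home_site = np.empty(len(geno_ids), dtype=int)
    for _, idx in fam_series.groupby(fam_series).groups.items():
        idx = np.asarray(idx)
        perm = rng_design.permutation(len(idx))
        home_site[idx[perm]] = np.arange(len(idx)) % 2
    if len(np.unique(home_site)) < 2:
        raise ValueError("design leaves one site empty; add offspring")
    for fam in fam_series.unique():
        sel = fam_series == fam
        if len(np.unique(home_site[sel])) < 2 and sel.sum() > 1:
            raise ValueError(f"family {fam} missing from one site")

    # additive: centered dosage times site-correlated effect vectors
    Zc = X - 2.0 * p
    bv = _correlated_site_values(Zc, arch.r_a, rng_eff)
    bv = _scale_to_variance(bv, home_site, arch.additive_var)

    # dominance: orthogonal (Vitezica) coding times correlated effects
    q = 1.0 - p
    W = np.where(X == 1.0, 2.0 * p * q,
                 np.where(X == 0.0, -2.0 * p ** 2, -2.0 * q ** 2))
    dv = _correlated_site_values(W, arch.r_d, rng_eff)
    dv = _scale_to_variance(dv, home_site, arch.dominance_var)

    bv -= bv.mean(axis=0)
    dv -= dv.mean(axis=0)
    gv = bv + dv

    # field layout: family row plots dealt into randomized complete blocks
    records = []
    for s in (0, 1):
        ids_at = [g for g, h in zip(geno_ids, home_site) if h == s]
        fam_at = [f for f, h in zip(families, home_site) if h == s]
        block_eff = rng_noise.normal(0.0, np.sqrt(arch.block_var[s]),
                                     design.blocks_per_site)
        plot_counter = 0
        by_family: dict[str, list[str]] = {}
        for g, f in zip(ids_at, fam_at):
            by_family.setdefault(f, []).append(g)
        for f in sorted(by_family):
            members = by_family[f]
            order = rng_design.permutation(len(members))
            for start in range(0, len(members), design.trees_per_plot):
                chunk = [members[i] for i in order[start:start + design.trees_per_plot]]
                plot_counter += 1
                block = int(rng_design.integers(design.blocks_per_site))
                plot_eff = rng_noise.normal(0.0, np.sqrt(arch.plot_var[s]))
                for g in chunk:
                    for ramet in range(design.ramets_per_clone):
                        records.append(
                            {
                                "tree": g if design.ramets_per_clone == 1
                                else f"{g}_r{ramet + 1}",
                                "genotype": g,
                                "family": f,
                                "site": f"S{s + 1}",
                                "block": f"B{block + 1:02d}",
                                "plot": f"PL{plot_counter:05d}",
                                "_site_idx": s,
                                "_block_eff": block_eff[block],
                                "_plot_eff": plot_eff,
                            }
                        )
    pheno = pd.DataFrame.from_records(records)
    gidx = {g: i for i, g in enumerate(geno_ids)}
    rows = pheno["genotype"].map(gidx).to_numpy()
    s_idx = pheno["_site_idx"].to_numpy()
    resid_sd = np.sqrt(np.asarray(arch.residual_var))[s_idx]
    resid = rng_noise.normal(0.0, 1.0, len(pheno)) * resid_sd
    pheno["y"] = (
        np.asarray(arch.site_means)[s_idx]
        + pheno["_block_eff"].to_numpy()
        + pheno["_plot_eff"].to_numpy()
        + bv[rows, s_idx]
        + dv[rows, s_idx]
        + resid
    )
    pheno = pheno.drop(columns=["_site_idx", "_block_eff", "_plot_eff"])

    true_rows = []
    for s in (0, 1):
        for i, g in enumerate(geno_ids):
            true_rows.append(
                {
                    "genotype": g,
                    "site": f"S{s + 1}",
                    "true_bv": bv[i, s],
                    "true_dv": dv[i, s],
                    "true_gv": gv[i, s],
                    "home_site": f"S{home_site[i] + 1}",
                }
            )
    true_values = pd.DataFrame(true_rows)

    realized = {
        "additive_var": tuple(
            float(bv[home_site == s, s].var(ddof=1)) for s in (0, 1)
        ),
        "dominance_var": tuple(
            float(dv[home_site == s, s].var(ddof=1)) for s in (0, 1)
        ),
        "r_a": float(np.corrcoef(bv[:, 0], bv[:, 1])[0, 1])
        if bv.std(axis=0).min() > 0 else float("nan"),
        "r_d": float(np.corrcoef(dv[:, 0], dv[:, 1])[0, 1])
        if dv.std(axis=0).min() > 0 else float("nan"),
        "block_var": tuple(arch.block_var),
        "plot_var": tuple(arch.plot_var),
        "residual_var": tuple(arch.residual_var),
    }
    return SimulatedTrial(
        pedigree=pedigree,
        genotypes=genotypes,
        phenotypes=pheno,
        true_values=true_values,
        realized=realized,
        qtl_ids=qtl_ids,
    )


def simulate_trial(
    n_parents: int = 40,
    n_families: int = 30,
    offspring_per_family: int = 20,
    n_snps: int = 4000,
    snps_per_locus: float = 1.5,
    maf_bounds: tuple[float, float] = (0.05, 0.5),
    arch: TraitArchitecture | None = None,
    design: TrialDesign | None = None,
    map_config: GenomeMap | None = None,
    seed: int = 0,
) -> SimulatedTrial:
    """One-call convenience wrapper: pedigree -> genotypes -> phenotypes."""
    if arch is None:
        # default QTL count adapts to small panels (a quarter of the SNPs,
        # capped at 200)
        arch = TraitArchitecture(n_qtl=min(200, max(10, n_snps // 4)))
    design = design or TrialDesign()
    ped = make_diallel_pedigree(n_parents, n_families, offspring_per_family, seed)
    geno = simulate_genotypes(
        ped,
        n_snps,
        snps_per_locus=snps_per_locus,
        maf_bounds=maf_bounds,
        map_config=map_config,
        missing_rate=design.missing_genotype_rate,
        seed=seed,
    )
    return simulate_phenotypes(geno, ped, arch, design, seed=seed)
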