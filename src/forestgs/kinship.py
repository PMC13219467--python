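"""Pedigree- and marker-based relationship matrices.

* ``build_A``  — numerator relationship matrix by the tabular recursion.
* ``build_D``  — pedigree dominance matrix from coancestry products.
* ``build_Ga`` — VanRaden genomic additive matrix (dosages centered at 2p,
  denominator 2*sum(p*q)).
* ``build_Gd`` — genomic dominance matrix under the orthogonal (Vitezica)
  parametrization.
* ``blend_and_invert`` — convex blend of a genomic matrix with its pedigree
  counterpart, G_blended = (1-w)*G + w*P, then a symmetric positive-definite
  inverse with an explicit product check.

Missing genotypes are mean-imputed only inside the G construction; the
matrix provenance records how many cells were imputed.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigvalsh

from .containers import UNKNOWN_PARENT, GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = ["build_A", "build_D", "build_Ga", "build_Gd", "blend_and_invert"]


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator (additive) relationship matrix.

    Tabular method: a_ii = 1 + 0.5*a(sire, dam), a_ij = 0.5*(a(j, sire_i) +
    a(j, dam_i)); founders are unrelated and non-inbred.  The pedigree is
    already topologically ordered (validated on construction).
    """
    ids = pedigree.ids
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    parents = pedigree.parents_of()
    for i, ind in enumerate(ids):
        sire, dam = parents[ind]
        si = index[sire] if sire != UNKNOWN_PARENT else -1
        di = index[dam] if dam != UNKNOWN_PARENT else -1
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
        elif si >= 0 or di >= 0:
            k = max(si, di)
            A[i, i] = 1.0
            A[i, :i] = 0.5 * A[k, :i]
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(values=A, ids=ids, kind="A",
                              provenance={"n_individuals": n})


def build_D(pedigree: Pedigree) -> RelationshipMatrix:
    """Pedigree dominance relationship matrix (non-inbred parametrization).

    d_ij = f(s_i, s_j) f(d_i, d_j) + f(s_i, d_j) f(d_i, s_j), with f the
    pedigree coancestry (A/2); individuals with unknown parents contribute
    zero off-diagonal dominance and d_ii = 1.
    """
    ids = pedigree.ids
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    f = build_A(pedigree).values / 2.0
    parents = pedigree.parents_of()
    sire_idx = np.full(n, -1)
    dam_idx = np.full(n, -1)
    for i, ind in enumerate(ids):
        sire, dam = parents[ind]
        if sire != UNKNOWN_PARENT:
            sire_idx[i] = index[sire]
        if dam != UNKNOWN_PARENT:
            dam_idx[i] = index[dam]
    known = (sire_idx >= 0) & (dam_idx >= 0)
    D = np.zeros((n, n))
    k = np.nonzero(known)[0]
    if k.size:
        s, d = sire_idx[k], dam_idx[k]
        D[np.ix_(k, k)] = f[np.ix_(s, s)] * f[np.ix_(d, d)] \
            + f[np.ix_(s, d)] * f[np.ix_(d, s)]
    np.fill_diagonal(D, 1.0)
    return RelationshipMatrix(values=D, ids=ids, kind="D",
                              provenance={"n_individuals": n})


def _prepare_markers(genotypes: GenotypeMatrix):
    """Shared preprocessing: observed-call allele frequencies, polymorphic
    mask, imputation count."""
    M = genotypes.values
    with np.errstate(invalid="ignore"):
        p = np.nanmean(M, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; no genomic matrix possible")
    n_imputed = int(np.isnan(M[:, poly]).sum())
    return M, p, poly, n_imputed


def build_Ga(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic additive relationship matrix.

    Dosages are centered by 2p per SNP (p from observed calls; missing cells
    mean-imputed, i.e. centered to zero), Ga = Z Z' / (2 * sum(p_k q_k)).
    Monomorphic SNPs are excluded from numerator and denominator.
    """
    M, p, poly, n_imputed = _prepare_markers(genotypes)
    Z = M[:, poly] - 2.0 * p[poly]
    Z = np.nan_to_num(Z, nan=0.0)
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(
        values=G,
        ids=list(genotypes.ids),
        kind="Ga",
        provenance={"n_snps": int(poly.sum()), "n_imputed": n_imputed},
    )


def build_Gd(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic dominance matrix, orthogonal (Vitezica) parametrization.

    Per SNP the codes {0, 1, 2} map to {-2p^2, 2pq, -2q^2} (zero-mean under
    HWE; missing cells imputed at zero), Gd = W W' / sum((2 p_k q_k)^2).
    """
    M, p, poly, n_imputed = _prepare_markers(genotypes)
    Mp = M[:, poly]
    pp = p[poly]
    qq = 1.0 - pp
    W = np.where(Mp == 1.0, 2.0 * pp * qq,
                 np.where(Mp == 0.0, -2.0 * pp ** 2, -2.0 * qq ** 2))
    W = np.where(np.isnan(Mp), 0.0, W)
    denom = float(np.sum((2.0 * pp * qq) ** 2))
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(
        values=G,
        ids=list(genotypes.ids),
        kind="Gd",
        provenance={"n_snps": int(poly.sum()), "n_imputed": n_imputed},
    )


def blend_and_invert(
    G: RelationshipMatrix,
    P: RelationshipMatrix,
    weight: float = 0.02,
) -> tuple[RelationshipMatrix, np.ndarray]:
    """Blend a genomic matrix with its pedigree counterpart and invert.

    G_blended = (1 - weight) * G + weight * P, elementwise on matching id
    order.  The inverse comes from a Cholesky factorization; the product
    check ``max|G_blended @ inv - I| < 1e-8`` is enforced.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("blend weight must lie in [0, 1]")
    if G.ids != P.ids:
        if set(G.ids) != set(P.ids):
            raise ValueError("genomic and pedigree matrices cover different ids")
        P = RelationshipMatrix(values=P.align(G.ids), ids=list(G.ids),
                               kind=P.kind, provenance=dict(P.provenance))
    B = (1.0 - weight) * G.values + weight * P.values
    B = (B + B.T) / 2.0
    try:
        c = cho_factor(B, lower=True)
    except np.linalg.LinAlgError as exc:
        smallest = float(eigvalsh(B, subset_by_index=(0, 0))[0])
        raise ValueError(
            f"blended matrix not positive definite (smallest eigenvalue "
            f"{smallest:.3e}); increase the blend weight"
        ) from exc
    inv = cho_solve(c, np.eye(B.shape[0]))
    inv = (inv + inv.T) / 2.0
    resid = float(np.abs(B @ inv - np.eye(B.shape[0])).max())
    if resid > 1e-8:
        raise ValueError(
            f"inverse check failed: max|B @ inv - I| = {resid:.2e} > 1e-8"
        )
    blended = RelationshipMatrix(
        values=B,
        ids=list(G.ids),
        kind=f"{G.kind}_blended",
        provenance={**G.provenance, "blend_weight": weight,
                    "pedigree_kind": P.kind},
    )
    return blended, inv
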