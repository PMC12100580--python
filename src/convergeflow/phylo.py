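"""Phylogenetic regression of gene expression on oviposition preference.

Cross-species expression comparisons first rescale TPM by the size of each
species' reference (TPM10K = TPM * N / 1e4, N the number of orthogroups
containing the species), making abundances comparable across
species-specific transcriptome references. Genes expressed in every
species are summarised by their per-species median and regressed on the
logit-transformed preference index with phylogenetic generalized least
squares (PGLS): residuals covary according to shared branch lengths under
Brownian motion, i.e. Cov(i,j) = depth of the most recent common ancestor
of tips i and j. Fold-change of the slope's t-test p-values across genes
is controlled with BH FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .de_convergence import bh_fdr


class PglsError(ValueError):
    """Degenerate regression input (constant predictor, singular covariance)."""


def tpm10k(tpm, n_ref: int):
    """Rescale TPM by reference size: TPM * N / 10^4. Linear in TPM."""
    if n_ref <= 0:
        raise ValueError("reference size must be positive")
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = arr * n_ref / 1e4
    return float(out) if np.isscalar(tpm) or arr.ndim == 0 else out


def apply_tpm10k(matrix: pd.DataFrame, sample_species: dict[str, str],
                 n_ref: dict[str, int]) -> pd.DataFrame:
    """Column-wise TPM10K conversion of a gene x sample TPM matrix."""
    cols = {}
    for sample in matrix.columns:
        sp = sample_species[sample]
        cols[sample] = tpm10k(matrix[sample].to_numpy(), n_ref[sp])
    return pd.DataFrame(cols, index=matrix.index)


def species_medians(matrix: pd.DataFrame, sample_species: dict[str, str],
                    require_all: bool = True, min_expr: float = 0.0) -> pd.DataFrame:
    """Per-gene per-species median expression.

    With ``require_all`` a gene is kept only if it is expressed (value >
    ``min_expr``) in at least one sample of *every* species; this is the
    "expressed in all species" filter applied before the PGLS screen.
    """
    species = sorted(set(sample_species.values()))
    groups = {sp: [s for s in matrix.columns if sample_species[s] == sp] for sp in species}
    for sp, ss in groups.items():
        if not ss:
            raise ValueError(f"species {sp!r} has no samples in the matrix")
    med = pd.DataFrame(
        {sp: matrix[ss].median(axis=1) for sp, ss in groups.items()},
        index=matrix.index,
    )
    if require_all:
        keep = np.ones(len(matrix), dtype=bool)
        for sp, ss in groups.items():
            keep &= (matrix[ss].to_numpy() > min_expr).any(axis=1)
        med = med.loc[keep]
    return med


def bm_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-tip path length per pair.

    C[i][i] is the root-to-tip distance of taxon i; C[i][j] the depth of
    the MRCA of i and j. Symmetric positive semi-definite for any tree
    with nonnegative branch lengths.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(taxa) - labels
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    # node depths from the root
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    tip = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    n = len(taxa)
    cov = np.zeros((n, n))
    for i, a in enumerate(taxa):
        cov[i, i] = depth[tip[a]]
        for j in range(i + 1, n):
            mrca = dendropy.Tree.mrca(tree, taxa=[tip[a].taxon, tip[taxa[j]].taxon])
            cov[i, j] = cov[j, i] = depth[mrca]
    return cov


@dataclass(frozen=True)
class PglsFit:
    gene: str
    intercept: float
    slope: float
    adj_r2: float
    pvalue: float  # slope t-test, n-2 df
    padj: float = float("nan")


def pgls_fit(y, x, cov: np.ndarray, gene: str = "") -> PglsFit:
    """Generalized least squares of y on [1, x] with error covariance ``cov``.

    beta = (X' C^-1 X)^-1 X' C^-1 y, slope tested with t on n-2 df;
    R^2 is computed in the whitened space about the GLS mean and adjusted
    as 1 - (1-R^2)(n-1)/(n-2).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3 or len(x) != n or cov.shape != (n, n):
        raise PglsError("need >=3 matched observations and an n x n covariance")
    if np.ptp(x) == 0:
        raise PglsError("constant predictor")
    if np.ptp(y) == 0:
        raise PglsError("constant response")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise PglsError("covariance matrix is not positive definite") from exc
    design = np.column_stack([np.ones(n), x])
    wx = np.linalg.solve(chol, design)
    wy = np.linalg.solve(chol, y)
    xtx = wx.T @ wx
    beta = np.linalg.solve(xtx, wx.T @ wy)
    resid = wy - wx @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    se_slope = np.sqrt(sigma2 * np.linalg.inv(xtx)[1, 1])
    if se_slope == 0:
        pval = 0.0 if beta[1] != 0 else 1.0
    else:
        tstat = beta[1] / se_slope
        pval = float(2 * stats.t.sf(abs(tstat), df=n - 2))
    # GLS-weighted total sum of squares about the GLS mean of y
    wone = np.linalg.solve(chol, np.ones(n))
    mu = float(wone @ wy) / float(wone @ wone)
    tss = float((wy - mu * wone) @ (wy - mu * wone))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return PglsFit(gene=gene, intercept=float(beta[0]), slope=float(beta[1]),
                   adj_r2=float(adj_r2), pvalue=pval)


def pgls_screen(medians: pd.DataFrame, logit_pis: dict[str, float],
                tree: dendropy.Tree, alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene PGLS of median expression (response) on logit PI (predictor).

    Species are the intersection of the medians' columns, the PI map and the
    tree tips; at least 3 are required. Genes with a degenerate fit
    (constant expression) are reported with NA statistics and excluded from
    the FDR family. Returns a table with a ``significant`` flag at
    padj < alpha_fdr.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    species = sorted(set(medians.columns) & set(logit_pis) & tips)
    if len(species) < 3:
        raise PglsError(f"need >=3 shared species, have {species}")
    cov = bm_covariance(tree, species)
    x = np.array([logit_pis[sp] for sp in species])
    rows = []
    for gene, row in medians[species].iterrows():
        try:
            fit = pgls_fit(row.to_numpy(), x, cov, gene=str(gene))
            rows.append({"gene": str(gene), "adj_r2": fit.adj_r2,
                         "intercept": fit.intercept, "slope": fit.slope,
                         "pvalue": fit.pvalue})
        except PglsError:
            rows.append({"gene": str(gene), "adj_r2": np.nan, "intercept": np.nan,
                         "slope": np.nan, "pvalue": np.nan})
    out = pd.DataFrame(rows)
    out["padj"] = bh_fdr(out["pvalue"])
    out["significant"] = out["padj"].notna() & (out["padj"] < alpha_fdr)
    return out


def substitute_missing_pi(logit_pis: dict[str, float],
                          substitutions: dict[str, str]) -> dict[str, float]:
    """Fill species without a measured PI from a stated donor species.

    Used for the second obligate parasite, whose preference was not assayed
    and is assumed equal to the first's; the rule is explicit configuration,
    never a silent default.
    """
    out = dict(logit_pis)
    for target, donor in substitutions.items():
        if target not in out:
            if donor not in out:
                raise KeyError(f"PI donor species {donor!r} not available")
            out[target] = out[donor]
    return out
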