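"""Species x gene presence-expression correlation matrix and its PCA.

Each entry is the Pearson correlation, across CD spots, between the binary
presence of a species (>= 1 read, the same exposure definition used in the
risk screen) and the normalised expression of a gene.  Entries where either
vector is constant are undefined; they are masked in the output and imputed
as 0 (the no-association neutral value) before PCA.  The correlation matrix
is centred gene-wise and decomposed by SVD; species scores on the leading
components separate species groups that drive distinct expression programs,
and the top-|loading| genes per component name the programs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ParameterError
from .io import logger
from .stats import rank_sum_test


@dataclass
class CorrelationMatrix:
    """Pearson r between species presence and gene expression."""

    r: pd.DataFrame      # species x genes
    mask: pd.DataFrame   # True where r is undefined (constant vector)


def presence_expression_correlation(
    expression: pd.DataFrame,
    exposure_counts: pd.DataFrame,
    species: Optional[Iterable[str]] = None,
    exposure_min_count: int = 1,
) -> CorrelationMatrix:
    """Correlate binary species presence with expression across spots.

    ``expression`` (spots x genes) and ``exposure_counts`` (spots x species)
    must share their spot index; restrict them to CD spots before calling
    when reproducing the CD-only analysis.
    """
    if expression.shape[0] < 3:
        raise ParameterError("need >= 3 spots to correlate")
    species = list(species) if species is not None \
        else list(exposure_counts.columns)
    presence = (
        exposure_counts.loc[expression.index, species].to_numpy()
        >= exposure_min_count
    ).astype(float)
    X = expression.to_numpy(dtype=float)
    n = X.shape[0]
    pc = presence - presence.mean(axis=0, keepdims=True)
    xc = X - X.mean(axis=0, keepdims=True)
    sd_p = pc.std(axis=0)
    sd_x = xc.std(axis=0)
    cov = pc.T @ xc / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sd_p, sd_x)
    undefined = (sd_p[:, None] == 0) | (sd_x[None, :] == 0)
    r[undefined] = np.nan
    r_df = pd.DataFrame(r, index=pd.Index(species, name="species"),
                        columns=expression.columns)
    mask = pd.DataFrame(undefined, index=r_df.index, columns=r_df.columns)
    if undefined.any():
        logger.info("correlation matrix: %d undefined entries masked",
                    int(undefined.sum()))
    return CorrelationMatrix(r=r_df, mask=mask)


@dataclass
class PCAResult:
    """Species scores, gene loadings and variance shares of the
    correlation-matrix PCA."""

    scores: pd.DataFrame              # species x components
    loadings: pd.DataFrame            # genes x components
    explained_variance_ratio: pd.Series
    top_genes: pd.DataFrame           # component, rank, gene, loading


def pca_on_correlations(
    corr: CorrelationMatrix,
    n_components: int = 10,
    top_k: int = 20,
) -> PCAResult:
    """Centred PCA of the correlation matrix.

    Masked entries are imputed as 0.  The sign of each component is fixed
    deterministically: the gene with the largest absolute loading gets a
    positive loading.  ``top_genes`` lists the ``top_k`` genes by absolute
    loading per component (the conventional "contribution" bar chart).
    """
    filled = corr.r.where(~corr.mask, 0.0)
    n_sp, n_g = filled.shape
    if n_sp < 2 or n_g < 2:
        raise ParameterError("PCA needs >= 2 species and >= 2 genes")
    max_rank = min(n_sp - 1, n_g)
    if n_components > max_rank:
        logger.warning("n_components clipped from %d to %d",
                       n_components, max_rank)
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(filled.to_numpy())
    loadings = pca.components_.T  # genes x components
    # deterministic sign: dominant gene loading positive per component
    for j in range(n_components):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    scores_df = pd.DataFrame(scores, index=filled.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=filled.columns,
                               columns=comp_names)
    rows = []
    for comp in comp_names:
        order = loadings_df[comp].abs().sort_values(ascending=False)
        for rank, gene in enumerate(order.index[:top_k], start=1):
            rows.append(
                {"component": comp, "rank": rank, "gene": gene,
                 "loading": loadings_df.loc[gene, comp]}
            )
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=pd.Series(
            pca.explained_variance_ratio_, index=comp_names
        ),
        top_genes=pd.DataFrame(rows),
    )


def component_separation_report(
    pca: PCAResult,
    labels: pd.Series,
    group_a: str = "beneficial",
    group_b: str = "pathogenic",
) -> pd.DataFrame:
    """Rank-sum separation of two species groups along each component.

    ``labels`` maps species to group names; species outside the two groups
    are ignored.  Each group needs >= 2 members, otherwise separation is
    not computable (empty frame with a logged warning).  The component with
    the smallest p is flagged ``best``.
    """
    labels = labels.reindex(pca.scores.index)
    a_idx = labels.index[labels == group_a]
    b_idx = labels.index[labels == group_b]
    if len(a_idx) < 2 or len(b_idx) < 2:
        logger.warning(
            "separation not computable: %d %s vs %d %s species",
            len(a_idx), group_a, len(b_idx), group_b,
        )
        return pd.DataFrame(
            columns=["mean_" + group_a, "mean_" + group_b, "p", "best"]
        )
    rows = []
    for comp in pca.scores.columns:
        sa = pca.scores.loc[a_idx, comp]
        sb = pca.scores.loc[b_idx, comp]
        _, p = rank_sum_test(sa, sb)
        rows.append(
            {"component": comp, "mean_" + group_a: float(sa.mean()),
             "mean_" + group_b: float(sb.mean()), "p": p}
        )
    out = pd.DataFrame(rows).set_index("component")
    out["best"] = False
    out.loc[out["p"].idxmin(), "best"] = True
    return out
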