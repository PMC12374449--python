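"""Differential expression by bacterial exposure and its consistency
across species.

For every species, spots are split into exposed (>= 1 read of the species)
and unexposed, and each gene is tested with a two-sided rank-sum test on
depth-normalised log1p expression; the signed normal-scale z statistic
(positive = up with exposure) and BH-adjusted q-values form a genes x
species response matrix.  Consistency summaries ask how often a gene
responds across species and whether the significant responses agree in
sign.  The beneficial-vs-pathogenic comparison enumerates every
(beneficial, pathogenic) species pair and contrasts spots exposed to
exactly one member of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

from .containers import ParameterError, SpatialDataset
from .io import logger
from .stats import bh_adjust, rank_sum_matrix


def normalize_expression(
    dataset: SpatialDataset,
    target_sum: float = 1e4,
    min_spots: int = 10,
) -> ad.AnnData:
    """Depth-normalise host counts to ``target_sum`` per spot and log1p.

    Genes detected in fewer than ``min_spots`` spots are dropped (logged),
    as are spots with zero total counts.
    """
    adata = dataset.host.copy()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    empty = totals == 0
    if empty.any():
        logger.warning("dropping %d spots with zero host counts",
                       int(empty.sum()))
        adata = adata[~empty].copy()
    n_before = adata.n_vars
    sc.pp.filter_genes(adata, min_cells=min_spots)
    if adata.n_vars < n_before:
        logger.info("dropped %d genes detected in < %d spots",
                    n_before - adata.n_vars, min_spots)
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


def expression_frame(adata: ad.AnnData) -> pd.DataFrame:
    """Dense spots x genes frame of the normalised expression."""
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return pd.DataFrame(np.asarray(X), index=adata.obs_names,
                        columns=adata.var_names)


def dge_by_exposure(
    expression: pd.DataFrame,
    exposed,
    min_group_size: int = 10,
    alpha: float = 0.05,
) -> Optional[pd.DataFrame]:
    """Per-gene rank-sum test between exposed and unexposed spots.

    Returns a frame indexed by gene with columns ``z`` (positive = higher
    with exposure), ``p``, ``q`` (BH over genes) and ``significant``
    (q < ``alpha``); or None when either group is smaller than
    ``min_group_size`` (the comparison is skipped and logged).
    """
    exposed = np.asarray(exposed, dtype=bool)
    if exposed.shape[0] != expression.shape[0]:
        raise ParameterError("exposure vector length must match spots")
    n1, n0 = int(exposed.sum()), int((~exposed).sum())
    if min(n1, n0) < min_group_size:
        logger.warning(
            "comparison skipped: group sizes %d vs %d below %d",
            n1, n0, min_group_size,
        )
        return None
    X = expression.to_numpy()
    z, p = rank_sum_matrix(X[exposed], X[~exposed])
    out = pd.DataFrame(
        {"z": z, "p": p, "q": bh_adjust(p)}, index=expression.columns
    )
    out["significant"] = out["q"] < alpha
    out.index.name = "gene"
    return out


@dataclass
class ResponseMatrix:
    """Genes x species response summary from per-species DGE."""

    z: pd.DataFrame               # genes x species signed z
    significant: pd.DataFrame     # genes x species, q < alpha per species
    consistency_rate: pd.Series   # fraction of tested species significant
    direction_agreement: pd.Series  # share of significant hits on majority sign
    consistent_up: List[str]
    consistent_down: List[str]
    skipped_species: List[str] = field(default_factory=list)


def consistency_screen(
    expression: pd.DataFrame,
    exposure_counts: pd.DataFrame,
    species: Optional[Iterable[str]] = None,
    min_group_size: int = 10,
    alpha: float = 0.05,
    r_min: float = 0.5,
    d_min: float = 0.9,
    exposure_min_count: int = 1,
) -> ResponseMatrix:
    """Per-species DGE and cross-species consistency.

    A gene is called *consistently up* (down) when at least ``r_min`` of
    the evaluable species flag it significant, at least ``d_min`` of those
    significant flags share the majority sign, and the majority sign is
    positive (negative).
    """
    species = list(species) if species is not None \
        else list(exposure_counts.columns)
    if len(species) < 2:
        raise ParameterError("consistency screen needs >=2 species")
    z_cols, sig_cols, skipped = {}, {}, []
    for s in species:
        exp_vec = (
            exposure_counts[s].reindex(expression.index).to_numpy()
            >= exposure_min_count
        )
        res = dge_by_exposure(expression, exp_vec,
                              min_group_size=min_group_size, alpha=alpha)
        if res is None:
            skipped.append(s)
            continue
        z_cols[s] = res["z"]
        sig_cols[s] = res["significant"]
    if len(z_cols) < 2:
        raise ParameterError(
            "fewer than 2 species evaluable in this stratum"
        )
    z = pd.DataFrame(z_cols)
    sig = pd.DataFrame(sig_cols)
    rate = sig.mean(axis=1)
    pos = (sig & (z > 0)).sum(axis=1)
    neg = (sig & (z < 0)).sum(axis=1)
    total = pos + neg
    with np.errstate(invalid="ignore"):
        agreement = np.maximum(pos, neg) / total.where(total > 0)
    up = list(rate.index[(rate >= r_min) & (agreement >= d_min)
                         & (pos > neg)])
    down = list(rate.index[(rate >= r_min) & (agreement >= d_min)
                           & (neg > pos)])
    return ResponseMatrix(
        z=z, significant=sig, consistency_rate=rate,
        direction_agreement=agreement, consistent_up=up,
        consistent_down=down, skipped_species=skipped,
    )


@dataclass
class PairComparison:
    """Beneficial-vs-pathogenic DGE across all species pairs."""

    pairs: List[Tuple[str, str]]          # every (beneficial, pathogenic)
    z: pd.DataFrame                       # genes x evaluated pairs
    significant: pd.DataFrame
    pair_consistency_rate: pd.Series      # per gene, over evaluated pairs
    skipped_pairs: List[Tuple[str, str]] = field(default_factory=list)


def pair_comparison(
    expression: pd.DataFrame,
    exposure_counts: pd.DataFrame,
    beneficial: Iterable[str],
    pathogenic: Iterable[str],
    min_group_size: int = 10,
    alpha: float = 0.05,
    exposure_min_count: int = 1,
) -> PairComparison:
    """Contrast expression between beneficial- and pathogenic-exposed spots.

    For each pair (b, p) the groups are spots exposed to b but not p versus
    exposed to p but not b (doubly-exposed and unexposed spots drop out);
    positive z means higher expression with the beneficial species.  The
    pair list is the full product — with 16 beneficial and 9 pathogenic
    members, 144 pairs.
    """
    beneficial = list(beneficial)
    pathogenic = list(pathogenic)
    if not beneficial or not pathogenic:
        raise ParameterError("both species sets must be non-empty")
    pairs = [(b, p) for b in beneficial for p in pathogenic]
    exp = (
        exposure_counts.reindex(expression.index) >= exposure_min_count
    )
    z_cols, sig_cols, skipped = {}, {}, []
    for b, p in pairs:
        grp_b = exp[b].to_numpy() & ~exp[p].to_numpy()
        grp_p = exp[p].to_numpy() & ~exp[b].to_numpy()
        if min(grp_b.sum(), grp_p.sum()) < min_group_size:
            skipped.append((b, p))
            continue
        X = expression.to_numpy()
        z, pv = rank_sum_matrix(X[grp_b], X[grp_p])
        key = f"{b}|{p}"
        z_cols[key] = pd.Series(z, index=expression.columns)
        q = bh_adjust(pv)
        sig_cols[key] = pd.Series(q < alpha, index=expression.columns)
    if not z_cols:
        raise ParameterError("all beneficial-pathogenic pairs were skipped")
    if skipped:
        logger.warning("%d of %d pairs skipped for small groups",
                       len(skipped), len(pairs))
    z = pd.DataFrame(z_cols)
    sig = pd.DataFrame(sig_cols)
    return PairComparison(
        pairs=pairs, z=z, significant=sig,
        pair_consistency_rate=sig.mean(axis=1),
        skipped_pairs=skipped,
    )


def ranked_gene_list(response: ResponseMatrix) -> pd.DataFrame:
    """Genes ranked for external enrichment: mean z across species with the
    consistency summaries alongside (plain TSV-ready frame)."""
    mean_z = response.z.mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_z": mean_z,
            "consistency_rate": response.consistency_rate,
            "direction_agreement": response.direction_agreement,
        }
    ).sort_values("mean_z", ascending=False)
    out.index.name = "gene"
    return out
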