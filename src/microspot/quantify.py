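"""Bacterial load per spot, per tissue group, per area, per patient, and
cell-type co-localization.

Bacterial load is always expressed in CPM: a spot's bacterial reads of the
retained species divided by the spot's total sequencing reads, times 1e6.
Group and area contrasts use the two-sided rank-sum test with the star
convention * p<0.05, ** p<0.005, *** p<0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ParameterError, SpatialDataset, SpeciesCounts, counts_to_cpm
from .io import logger
from .stats import bh_adjust, rank_sum_test


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.0005 else "**" if p < 0.005 else \
        "*" if p < 0.05 else ""


def per_spot_load(
    dataset: SpatialDataset,
    retained: Optional[SpeciesCounts] = None,
) -> pd.Series:
    """Total bacterial CPM per spot over retained species."""
    counts = (retained or dataset.species_single).counts
    cpm = counts_to_cpm(counts, dataset.total_reads)
    load = cpm.sum(axis=1)
    load.name = "bacterial_cpm"
    return load


def group_compare(
    loads: pd.Series, groups: pd.Series
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- SEM of bacterial load per group, with pairwise rank-sum tests.

    Returns (summary, pairwise): ``summary`` has one row per non-empty group
    (mean, SEM — reported missing below 2 spots — and spot count);
    ``pairwise`` one row per group pair with the two-sided p and its stars.
    """
    groups = groups.reindex(loads.index)
    present = []
    rows = []
    for g, vals in loads.groupby(groups, observed=False):
        if len(vals) == 0:
            logger.warning("group %s has no spots; excluded", g)
            continue
        present.append(g)
        rows.append(
            {
                "group": g,
                "n_spots": len(vals),
                "mean_cpm": float(vals.mean()),
                "sem_cpm": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) >= 2 else np.nan,
            }
        )
    if len(present) < 2:
        raise ParameterError("group_compare needs >=2 non-empty groups")
    summary = pd.DataFrame(rows).set_index("group")
    pair_rows = []
    for g1, g2 in combinations(present, 2):
        _, p = rank_sum_test(loads[groups == g1], loads[groups == g2])
        pair_rows.append(
            {"group1": g1, "group2": g2, "p": p,
             "stars": significance_stars(p)}
        )
    return summary, pd.DataFrame(pair_rows)


def area_compare(
    loads: pd.Series, area_labels: pd.Series
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Same contrast structure as :func:`group_compare`, stratified by
    cell-type-enriched area instead of tissue group."""
    return group_compare(loads, area_labels)


def patient_prognosis_table(
    loads: pd.Series, obs: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient mean bacterial load next to prognosis metadata.

    Returns (table, correlations).  Spearman rank correlations are computed
    for mean CPM vs the Rutgeerts score (all patients with a score) and vs
    time to relapse (relapse patients only); fewer than 3 paired values
    leaves the correlation not-computable (NaN, with n reported).
    """
    df = obs.copy()
    df["load"] = loads.reindex(df.index)
    per_patient = (
        df.groupby("patient_id", observed=True)
        .agg(
            group=("group", "first"),
            n_spots=("load", "size"),
            mean_cpm=("load", "mean"),
            time_to_relapse_months=("time_to_relapse_months", "first"),
            rutgeerts_score=("rutgeerts_score", "first"),
        )
        .sort_values("mean_cpm")
    )
    corr_rows = []
    for target in ("rutgeerts_score", "time_to_relapse_months"):
        sub = per_patient[["mean_cpm", target]].dropna()
        if len(sub) >= 3:
            rho, p = sps.spearmanr(sub["mean_cpm"], sub[target])
        else:
            rho, p = np.nan, np.nan
        corr_rows.append(
            {"against": target, "spearman_rho": rho, "p": p, "n": len(sub)}
        )
    return per_patient, pd.DataFrame(corr_rows)


@dataclass
class Colocalization:
    """Species x cell-type co-existence weights and derived summaries."""

    weights: pd.DataFrame        # sum over spots of fraction x count
    probabilities: pd.DataFrame  # weights row-normalised; NaN for 0-read rows
    group_fc: Optional[pd.DataFrame] = None  # per cell type, beneficial vs
    #                                          pathogenic log2FC + p + q


def colocalization(
    dataset: SpatialDataset,
    retained: Optional[SpeciesCounts] = None,
    beneficial: Optional[Iterable[str]] = None,
    pathogenic: Optional[Iterable[str]] = None,
) -> Colocalization:
    """Co-existence of species with cell types.

    ``weights[s, c] = sum_i fractions[i, c] * counts[i, s]``; because the
    fraction rows sum to one, each species' weights sum exactly to its total
    read count.  The probability variant row-normalises each species; rows
    with zero reads are reported missing.  Given beneficial and pathogenic
    species sets, a per-cell-type log2 fold change of mean co-localization
    probability (beneficial over pathogenic, half-minimum pseudo-probability
    against zeros) is computed with a rank-sum p across the two species
    groups, BH-adjusted over cell types.
    """
    counts = (retained or dataset.species_single).counts
    frac = dataset.cell_fractions
    weights = pd.DataFrame(
        counts.to_numpy().T @ frac.to_numpy(),
        index=counts.columns, columns=frac.columns,
    )
    totals = weights.sum(axis=1)
    prob = weights.div(totals.where(totals > 0), axis=0)

    group_fc = None
    if beneficial is not None and pathogenic is not None:
        bset = [s for s in beneficial if s in prob.index]
        pset = [s for s in pathogenic if s in prob.index]
        if bset and pset:
            bp = prob.loc[bset].dropna(how="all")
            pp = prob.loc[pset].dropna(how="all")
            nonzero = prob.to_numpy()
            nonzero = nonzero[np.isfinite(nonzero) & (nonzero > 0)]
            pseudo = nonzero.min() / 2.0 if nonzero.size else 0.5
            rows = []
            for ct in prob.columns:
                b_vals = bp[ct].dropna()
                p_vals = pp[ct].dropna()
                fc = np.log2(
                    (b_vals.mean() + pseudo) / (p_vals.mean() + pseudo)
                ) if len(b_vals) and len(p_vals) else np.nan
                if len(b_vals) >= 2 and len(p_vals) >= 2:
                    _, pval = rank_sum_test(b_vals, p_vals)
                else:
                    pval = np.nan
                rows.append({"cell_type": ct, "log2_fc": fc, "p": pval})
            group_fc = pd.DataFrame(rows).set_index("cell_type")
            group_fc["q"] = bh_adjust(group_fc["p"].to_numpy())
    return Colocalization(weights=weights, probabilities=prob,
                          group_fc=group_fc)
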