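"""Four-rule stepwise decontamination of species-level spatial counts.

Spatial capture chemistry plus read classification produces false-positive
species calls; the cascade removes a species when any of four conjunctive
rules fails:

1. spatial floor    — fewer than ``min_spatial_reads`` reads summed over all
                      spots of all samples;
2. bulk floor       — fewer than ``min_bulk_reads`` reads in the matched
                      bulk metagenome;
3. spatial/bulk     — the species' share of classified spatial bacterial
   over-representation  reads exceeds ``max_spatial_bulk_ratio`` times its
                      share of bulk bacterial reads;
4. double-removal   — read counts after the second human-read removal pass
   survival            drop below ``min_double_survival`` of the single-pass
                      counts (human-read artifacts collapse; genuine gut
                      species only shrink moderately).

All inequality directions are strict, exactly as stated by the thresholds'
semantics (49 reads fail a floor of 50; a ratio of exactly 1.5 and a
survival of exactly 0.02 pass).  Every rule is evaluated for every species
so the report supports auditing; the verdict is the conjunction.  Retained
downstream counts come from the single-removal variant, which is gentler on
genuine species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .containers import ParameterError, SpatialDataset, SpeciesCounts
from .io import logger

RULES = (
    "spatial_floor",
    "bulk_floor",
    "spatial_bulk_ratio",
    "double_removal_survival",
)


@dataclass(frozen=True)
class DecontamThresholds:
    min_spatial_reads: float = 50
    min_bulk_reads: float = 50
    max_spatial_bulk_ratio: float = 1.5
    min_double_survival: float = 0.02


# -- individual rules (True = pass) -----------------------------------------

def rule_spatial_floor(spatial_totals: pd.Series,
                       min_reads: float = 50) -> pd.Series:
    """Fail species with total spatial reads strictly below ``min_reads``."""
    return ~(spatial_totals < min_reads)


def rule_bulk_floor(bulk_totals: pd.Series,
                    min_reads: float = 50) -> pd.Series:
    """Fail species with total bulk reads strictly below ``min_reads``;
    species absent from the bulk table count as zero."""
    return ~(bulk_totals.fillna(0) < min_reads)


def rule_spatial_bulk_ratio(spatial_pct: pd.Series, bulk_pct: pd.Series,
                            max_ratio: float = 1.5) -> pd.Series:
    """Fail species whose spatial read share exceeds ``max_ratio`` times
    their bulk read share.  A species seen spatially but absent from bulk has
    an infinite ratio (fail); a species absent from both leaves the ratio
    undefined and passes this rule (the floors already catch it)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = spatial_pct / bulk_pct
    fail = (ratio > max_ratio) | ((bulk_pct == 0) & (spatial_pct > 0))
    return ~fail.fillna(False)


def rule_double_removal_survival(single_totals: pd.Series,
                                 double_totals: pd.Series,
                                 min_survival: float = 0.02) -> pd.Series:
    """Fail species whose double-removal counts drop strictly below
    ``min_survival`` of their single-removal counts.  Species with zero
    single-removal reads are not evaluable here (the spatial floor already
    fails them) and pass."""
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = double_totals / single_totals
    return ~(survival < min_survival).where(single_totals > 0, False)


def read_percentages(totals: pd.Series) -> pd.Series:
    """Each species' share of all classified bacterial reads (sums to 1)."""
    grand = totals.fillna(0).sum()
    if grand == 0:
        return totals * 0.0
    return totals.fillna(0) / grand


# -- cascade ----------------------------------------------------------------

def decontaminate_counts(
    single: pd.DataFrame,
    bulk_counts: pd.Series,
    double: Optional[pd.DataFrame] = None,
    thresholds: DecontamThresholds = DecontamThresholds(),
    sample_ids: Optional[pd.Series] = None,
    percentage_basis: str = "pooled",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the four-rule cascade on raw tables.

    Parameters
    ----------
    single, double
        Spots x species read counts after single / double human-read
        removal.  A missing double table skips rule 4 with a prominent
        warning recorded in the report.
    bulk_counts
        Per-species bulk metagenome totals (absent species = 0 reads).
    sample_ids, percentage_basis
        With ``percentage_basis="per_sample_mean"`` the spatial share of a
        species is the mean of its per-sample shares (requires
        ``sample_ids`` aligned to the spot index); the default pools reads
        across all samples.

    Returns
    -------
    (retained, report)
        ``retained``: single-removal counts restricted to retained species.
        ``report``: one row per species with all intermediate quantities,
        one pass flag per rule, the verdict, and the first failing rule.
    """
    if percentage_basis not in ("pooled", "per_sample_mean"):
        raise ParameterError(
            f"unknown percentage_basis {percentage_basis!r}"
        )
    species = single.columns
    spatial_totals = single.sum(axis=0)
    bulk_totals = bulk_counts.reindex(species)
    n_missing_bulk = int(bulk_totals.isna().sum())
    if n_missing_bulk:
        logger.warning(
            "%d species absent from bulk table; treated as 0 bulk reads",
            n_missing_bulk,
        )
    bulk_totals = bulk_totals.fillna(0)

    if percentage_basis == "pooled":
        spatial_pct = read_percentages(spatial_totals)
    else:
        if sample_ids is None:
            raise ParameterError(
                "per_sample_mean percentage basis requires sample_ids"
            )
        per_sample = single.groupby(sample_ids.reindex(single.index)).sum()
        shares = per_sample.div(per_sample.sum(axis=1).replace(0, np.nan),
                                axis=0)
        spatial_pct = shares.mean(axis=0).fillna(0)
    bulk_pct = read_percentages(bulk_totals)

    flags = pd.DataFrame(index=species)
    flags["spatial_floor"] = rule_spatial_floor(
        spatial_totals, thresholds.min_spatial_reads
    )
    flags["bulk_floor"] = rule_bulk_floor(
        bulk_totals, thresholds.min_bulk_reads
    )
    flags["spatial_bulk_ratio"] = rule_spatial_bulk_ratio(
        spatial_pct, bulk_pct, thresholds.max_spatial_bulk_ratio
    )
    rule4_skipped = double is None
    if rule4_skipped:
        logger.warning(
            "double-removal table missing: survival rule SKIPPED — "
            "human-read artifacts may pass the cascade"
        )
        double_totals = pd.Series(np.nan, index=species)
        flags["double_removal_survival"] = True
    else:
        double_totals = double.sum(axis=0).reindex(species).fillna(0)
        flags["double_removal_survival"] = rule_double_removal_survival(
            spatial_totals, double_totals, thresholds.min_double_survival
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (spatial_pct / bulk_pct).where(
            ~((spatial_pct == 0) & (bulk_pct == 0)), np.nan
        )
        survival = (double_totals / spatial_totals).where(spatial_totals > 0)

    verdict = flags.all(axis=1)
    failing = flags.apply(
        lambda row: next((r for r in RULES if not row[r]), None), axis=1
    ) if len(flags) else pd.Series(dtype=object)

    report = pd.DataFrame(
        {
            "total_spatial_reads": spatial_totals,
            "total_bulk_reads": bulk_totals,
            "spatial_pct": spatial_pct,
            "bulk_pct": bulk_pct,
            "spatial_bulk_ratio": ratio,
            "double_single_survival": survival,
            **{f"pass_{r}": flags[r] for r in RULES},
            "verdict": np.where(verdict, "retained", "excluded"),
            "failing_rule": failing,
        }
    )
    report.index = report.index.rename("species")  # non-mutating: the
    # index object is shared with the caller's counts frame
    report.attrs["rule4_skipped"] = rule4_skipped
    retained = single.loc[:, species[verdict]]
    logger.info(
        "decontamination retained %d / %d species", retained.shape[1],
        len(species),
    )
    return retained, report


def decontaminate(
    dataset: SpatialDataset,
    thresholds: DecontamThresholds = DecontamThresholds(),
    percentage_basis: str = "pooled",
) -> Tuple[SpeciesCounts, pd.DataFrame]:
    """Cascade on a joined dataset; returns retained single-removal counts."""
    retained, report = decontaminate_counts(
        dataset.species_single.counts,
        dataset.bulk_counts,
        None if dataset.species_double is None
        else dataset.species_double.counts,
        thresholds=thresholds,
        sample_ids=dataset.obs["sample_id"],
        percentage_basis=percentage_basis,
    )
    return SpeciesCounts(retained, "single"), report
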