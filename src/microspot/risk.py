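"""Relative risk of reduced spot viability under bacterial exposure.

A spot is *viable* when at most 10% of its reads are mitochondrial and
*damaged* above that, mirroring the standard mitochondrial-stress QC marker.
For each species the spots (CD tissue only, by default) are tabulated into
the 2x2 exposure/damage table

====================  ==========  ==========
..                     damaged     viable
exposed                a           b
unexposed              c           d
====================  ==========  ==========

and the relative risk is the ratio of damage proportions,
``RR = (a/(a+b)) / (c/(c+d))``.  Confidence intervals use the Katz
log-normal method, ``exp(ln RR +/- 1.96 * SE)`` with
``SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))``; a zero in ``a`` or ``c``
triggers the Haldane-Anscombe 0.5 correction of all four cells (flagged).
P-values come from the z statistic ``ln RR / SE``, adjusted across species
by Benjamini-Hochberg.  The population attributable risk percent combines
RR with the exposure prevalence ``P = (a+b)/(a+b+c+d)``:

``PARP = 100 * P*(RR-1) / (P*(RR-1) + 1)``

— negative for protective species (RR < 1), positive for harmful ones.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ParameterError, SpatialDataset, SpeciesCounts
from .io import logger
from .stats import bh_adjust

Z95 = 1.96


def classify_viability(
    dataset: SpatialDataset, mito_cutoff: float = 0.10
) -> pd.Series:
    """Per-spot damage indicator: True when mito fraction exceeds the cutoff
    (a fraction of exactly the cutoff is viable)."""
    if not 0 <= mito_cutoff <= 1:
        raise ParameterError("mito_cutoff must be in [0, 1]")
    damaged = dataset.obs["mito_fraction"] > mito_cutoff
    damaged.name = "damaged"
    return damaged


def relative_risk(exposed, damaged) -> pd.Series:
    """RR of damage given exposure from two aligned boolean vectors.

    Returns a Series with the 2x2 cells, RR, the 95% Katz CI, the two-sided
    p, the exposure prevalence P, the PARP, and bookkeeping flags.  If
    either margin (exposed or unexposed) is empty the species is not
    evaluable and the estimate fields are NaN.
    """
    exposed = np.asarray(exposed, dtype=bool)
    damaged = np.asarray(damaged, dtype=bool)
    if exposed.shape != damaged.shape:
        raise ParameterError("exposed and damaged must have equal length")
    a = int(np.sum(exposed & damaged))
    b = int(np.sum(exposed & ~damaged))
    c = int(np.sum(~exposed & damaged))
    d = int(np.sum(~exposed & ~damaged))
    out = {
        "a": a, "b": b, "c": c, "d": d,
        "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "p": np.nan, "prevalence": np.nan, "parp": np.nan,
        "continuity_corrected": False, "evaluable": True,
    }
    n = a + b + c + d
    if a + b == 0 or c + d == 0:
        out["evaluable"] = False
        return pd.Series(out)
    out["prevalence"] = (a + b) / n
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if a == 0 or c == 0:
        aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
        out["continuity_corrected"] = True
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se2 = 1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd)
    se = np.sqrt(max(se2, 0.0))
    out["rr"] = rr
    if se > 0:
        out["ci_low"] = float(np.exp(np.log(rr) - Z95 * se))
        out["ci_high"] = float(np.exp(np.log(rr) + Z95 * se))
        z = np.log(rr) / se
        out["p"] = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    else:  # degenerate: everyone damaged (or viable) in both arms
        out["ci_low"] = out["ci_high"] = rr
        out["p"] = 1.0
    if 0 < out["prevalence"] < 1:
        out["parp"] = parp(rr, out["prevalence"])
    return pd.Series(out)


def parp(rr: float, prevalence: float) -> float:
    """Population attributable risk percent,
    ``100 * P*(RR-1) / (P*(RR-1) + 1)``."""
    if rr <= 0:
        raise ParameterError("rr must be > 0")
    if not 0 < prevalence < 1:
        raise ParameterError("prevalence must be in (0, 1)")
    x = prevalence * (rr - 1.0)
    if x <= -1.0:  # unreachable for rr > 0, prevalence < 1; guarded anyway
        raise ParameterError("PARP undefined: P*(RR-1) <= -1")
    return 100.0 * x / (x + 1.0)


def risk_table(
    counts: pd.DataFrame,
    damaged: pd.Series,
    exposure_min_count: int = 1,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-species RR screen on a counts table and aligned damage vector.

    Exposure means at least ``exposure_min_count`` reads of the species in
    the spot.  q-values are BH-adjusted over evaluable species; significant
    species (q < ``fdr``) are labelled beneficial (RR < 1) or pathogenic
    (RR > 1).
    """
    if exposure_min_count < 1:
        raise ParameterError("exposure_min_count must be >= 1")
    damaged = damaged.reindex(counts.index)
    dmg = damaged.to_numpy(dtype=bool)
    columns = ["a", "b", "c", "d", "rr", "ci_low", "ci_high", "p",
               "prevalence", "parp", "continuity_corrected", "evaluable"]
    if counts.shape[1] == 0:
        table = pd.DataFrame(columns=columns + ["q", "direction"])
        table.index.name = "species"
        return table
    rows = {}
    for s in counts.columns:
        exp_vec = counts[s].to_numpy() >= exposure_min_count
        rows[s] = relative_risk(exp_vec, dmg)
    table = pd.DataFrame(rows).T.loc[:, columns]
    table.index.name = "species"
    for col in ("a", "b", "c", "d"):
        table[col] = table[col].astype(int)
    for col in ("rr", "ci_low", "ci_high", "p", "prevalence", "parp"):
        table[col] = table[col].astype(float)
    for col in ("continuity_corrected", "evaluable"):
        table[col] = table[col].astype(bool)
    table["q"] = bh_adjust(table["p"].to_numpy(dtype=float))
    sig = table["q"] < fdr
    table["direction"] = np.where(
        sig & (table["rr"] < 1), "beneficial",
        np.where(sig & (table["rr"] > 1), "pathogenic", ""),
    )
    return table


def risk_screen(
    dataset: SpatialDataset,
    retained: Optional[SpeciesCounts] = None,
    mito_cutoff: float = 0.10,
    exposure_min_count: int = 1,
    fdr: float = 0.05,
    population: str = "cd_only",
) -> pd.DataFrame:
    """Viability classification plus per-species RR screen on a dataset.

    ``population="cd_only"`` (default) restricts to CD spots; ``"all"``
    includes controls for sensitivity analysis.
    """
    if population not in ("cd_only", "all"):
        raise ParameterError(f"unknown population {population!r}")
    counts = (retained or dataset.species_single).counts
    if population == "cd_only":
        sub = dataset.subset(dataset.cd_mask())
        counts = counts.loc[sub.barcodes]
    else:
        sub = dataset
    damaged = classify_viability(sub, mito_cutoff)
    table = risk_table(counts, damaged,
                       exposure_min_count=exposure_min_count, fdr=fdr)
    logger.info(
        "risk screen: %d species, %d significant at q<%.2f",
        len(table), int((table["q"] < fdr).sum()), fdr,
    )
    return table


def beneficial_pathogenic(
    risk: pd.DataFrame,
) -> Tuple[list, list]:
    """Significant species split by direction, for downstream modules."""
    ben = list(risk.index[risk["direction"] == "beneficial"])
    pat = list(risk.index[risk["direction"] == "pathogenic"])
    return ben, pat


def strain_level_screen(
    dataset: SpatialDataset,
    strain_counts: SpeciesCounts | pd.DataFrame,
    species_counts: Optional[SpeciesCounts] = None,
    min_exposed: int = 10,
    **kwargs,
) -> Tuple[pd.DataFrame, float]:
    """RR screen at strain resolution.

    Identical computation to :func:`risk_screen` with strain labels; also
    reports the fraction of species-level reads resolved to strain level
    and flags strains observed in fewer than ``min_exposed`` spots
    (``low_exposure``), whose intervals are necessarily wide.
    """
    if isinstance(strain_counts, SpeciesCounts):
        strain_df = strain_counts.counts
    else:
        strain_df = strain_counts
    table = risk_screen(
        dataset,
        retained=SpeciesCounts(strain_df, "single"),
        **kwargs,
    )
    table["low_exposure"] = (table["a"] + table["b"]) < min_exposed
    ref = (species_counts or dataset.species_single).counts
    total_species = float(ref.to_numpy().sum())
    resolved = float(strain_df.to_numpy().sum()) / total_species \
        if total_species > 0 else np.nan
    return table, resolved
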