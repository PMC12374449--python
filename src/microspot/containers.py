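"""Shared in-memory containers for spot-resolved host-microbiome data.

The unit of observation throughout is the *spot*: a barcoded capture location
on a spatial transcriptomics slide holding a handful of cells.  A joined
dataset couples, on a common barcode index,

* host gene counts (an :class:`anndata.AnnData`, spots x genes, with spot
  metadata in ``.obs`` and a boolean mitochondrial flag in ``.var["mito"]``),
* per-spot per-species bacterial read counts in two human-read-removal
  variants (``single``: one alignment pass; ``double``: two passes, which
  depresses human-read artifacts far more than genuine gut species),
* deconvolved cell-type fractions per spot (rows sum to one),
* bulk metagenome species totals from the same tissue, used only by the
  decontamination cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd

GROUPS = ("control", "CD_noninflamed", "CD_inflamed")
CD_GROUPS = ("CD_noninflamed", "CD_inflamed")

#: spot metadata columns expected in ``host.obs``
OBS_COLUMNS = (
    "sample_id",
    "patient_id",
    "group",
    "x",
    "y",
    "total_sequencing_reads",
    "mito_fraction",
)


class ParameterError(ValueError):
    """An argument or configuration value is out of its documented range."""


class FormatError(ValueError):
    """An input table violates the documented file contract."""


def counts_to_cpm(
    counts: pd.DataFrame, total_reads: pd.Series
) -> pd.DataFrame:
    """Counts-per-million: reads of each species divided by the spot's total
    sequencing reads, times 1e6.  Spots with zero total reads yield 0."""
    totals = total_reads.reindex(counts.index).to_numpy(dtype=float)
    safe = np.where(totals > 0, totals, np.inf)
    return counts.div(safe, axis=0) * 1e6


@dataclass
class SpeciesCounts:
    """Spots x species bacterial read counts for one removal variant."""

    counts: pd.DataFrame
    removal_variant: str  # "single" | "double"

    def __post_init__(self) -> None:
        if self.removal_variant not in ("single", "double"):
            raise ParameterError(
                f"removal_variant must be 'single' or 'double', "
                f"got {self.removal_variant!r}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative bacterial counts")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate species labels")

    @property
    def species(self) -> pd.Index:
        return self.counts.columns

    def total_per_species(self) -> pd.Series:
        """Reads summed over all spots of all samples."""
        return self.counts.sum(axis=0)

    def cpm(self, total_reads: pd.Series) -> pd.DataFrame:
        return counts_to_cpm(self.counts, total_reads)

    def subset_spots(self, barcodes: Sequence[str]) -> "SpeciesCounts":
        return replace(self, counts=self.counts.loc[list(barcodes)])

    def subset_species(self, species: Sequence[str]) -> "SpeciesCounts":
        return replace(self, counts=self.counts.loc[:, list(species)])


@dataclass
class SpatialDataset:
    """The joined analysis object all pipeline stages consume."""

    host: ad.AnnData
    species_single: SpeciesCounts
    species_double: Optional[SpeciesCounts]
    cell_fractions: pd.DataFrame
    bulk_counts: pd.Series

    @property
    def barcodes(self) -> pd.Index:
        return self.host.obs_names

    @property
    def obs(self) -> pd.DataFrame:
        return self.host.obs

    @property
    def n_spots(self) -> int:
        return self.host.n_obs

    @property
    def total_reads(self) -> pd.Series:
        return self.host.obs["total_sequencing_reads"]

    def cd_mask(self) -> np.ndarray:
        return self.host.obs["group"].isin(CD_GROUPS).to_numpy()

    def subset(self, mask: np.ndarray) -> "SpatialDataset":
        """Restrict every table to the spots selected by ``mask``."""
        keep = self.host.obs_names[np.asarray(mask)]
        return SpatialDataset(
            host=self.host[list(keep)].copy(),
            species_single=self.species_single.subset_spots(keep),
            species_double=(
                self.species_double.subset_spots(keep)
                if self.species_double is not None
                else None
            ),
            cell_fractions=self.cell_fractions.loc[list(keep)],
            bulk_counts=self.bulk_counts,
        )

    def validate(self, atol: float = 1e-6) -> None:
        obs = self.host.obs
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise FormatError(f"missing spot metadata columns: {missing}")
        for sample, sub in obs.groupby("sample_id", observed=True):
            if sub.index.duplicated().any():
                raise FormatError(f"duplicate barcodes in sample {sample}")
        bad = set(obs["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        mf = obs["mito_fraction"].to_numpy(dtype=float)
        if ((mf < 0) | (mf > 1)).any():
            raise FormatError("mito_fraction outside [0, 1]")
        for sc in (self.species_single, self.species_double):
            if sc is not None and not sc.counts.index.equals(self.barcodes):
                raise FormatError(
                    f"{sc.removal_variant}-removal table barcodes do not "
                    "match host table"
                )
        if not self.cell_fractions.index.equals(self.barcodes):
            raise FormatError("cell-fraction barcodes do not match host table")
        fr = self.cell_fractions.to_numpy(dtype=float)
        if (fr < -atol).any():
            raise FormatError("negative cell-type fractions")
        rowsum = fr.sum(axis=1)
        if np.abs(rowsum - 1.0).max(initial=0.0) > atol:
            raise FormatError("cell-type fraction rows do not sum to 1")


def mito_fraction_from_counts(host: ad.AnnData) -> np.ndarray:
    """Mitochondrial read fraction per spot from counts and ``var['mito']``."""
    X = host.X
    mito = host.var["mito"].to_numpy(dtype=bool)
    if hasattr(X, "toarray"):
        total = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel()
    else:
        total = X.sum(axis=1)
        mito_counts = X[:, mito].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    return frac
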