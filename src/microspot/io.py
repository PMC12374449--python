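"""Reading, writing, spot QC, and area labelling for joined datasets.

On-disk layout (all plain text, one directory per dataset)::

    matrix.mtx                genes x spots host counts (MatrixMarket)
    barcodes.tsv              one spot barcode per line
    features.tsv              one gene symbol per line
    spot_metadata.csv         barcode, sample_id, patient_id, group, x, y,
                              total_sequencing_reads[, time_to_relapse_months,
                              rutgeerts_score]
    species_single.tsv        long format: barcode, species, count
    species_double.tsv        same, after double human-read removal (optional)
    bulk_species.tsv          species, reads (Kraken-report-like totals)
    cell_type_fractions.tsv   barcode + one column per cell type (rows sum 1)

Mitochondrial genes are recognised by a case-insensitive ``MT-`` symbol
prefix unless an explicit gene list is supplied.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import (
    GROUPS,
    FormatError,
    ParameterError,
    SpatialDataset,
    SpeciesCounts,
    mito_fraction_from_counts,
)

logger = logging.getLogger("microspot")

METADATA_REQUIRED = (
    "sample_id", "patient_id", "group", "x", "y", "total_sequencing_reads",
)

#: default aggregation of fine cell types into named tissue areas
DEFAULT_AREA_MAP = {
    "enterocyte": "enterocyte-rich",
    "goblet": "goblet cell-rich",
    "stem": "stem cell-rich",
    "tuft": "tuft cell-rich",
    "M_cell": "M cell-rich",
    "B_cell": "immune cell-rich",
    "T_cell": "immune cell-rich",
    "myeloid": "immune cell-rich",
}


def configure_logging(level: int = logging.INFO) -> None:
    """Send pipeline logs to stderr (used by the CLI entry points)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# writers

def write_dataset(dataset: SpatialDataset, directory: str | Path) -> Path:
    """Write every table of ``dataset`` to ``directory`` (created if absent)."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    host = dataset.host
    X = host.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    scipy_io.mmwrite(str(out / "matrix.mtx"), X.T.astype(np.int64))
    pd.Series(host.obs_names).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(host.var_names).to_csv(
        out / "features.tsv", sep="\t", header=False, index=False
    )
    meta_cols = [c for c in host.obs.columns
                 if c not in ("mito_fraction",)]
    host.obs[meta_cols].to_csv(out / "spot_metadata.csv",
                               index_label="barcode")
    for sc in (dataset.species_single, dataset.species_double):
        if sc is None:
            continue
        long = (
            sc.counts.stack()
            .rename_axis(["barcode", "species"])
            .rename("count")
            .reset_index()
        )
        long = long[long["count"] > 0]
        long.to_csv(out / f"species_{sc.removal_variant}.tsv",
                    sep="\t", index=False)
    dataset.bulk_counts.rename("reads").rename_axis("species").to_csv(
        out / "bulk_species.tsv", sep="\t"
    )
    dataset.cell_fractions.to_csv(out / "cell_type_fractions.tsv",
                                  sep="\t", index_label="barcode")
    logger.info("wrote dataset with %d spots to %s", dataset.n_spots, out)
    return out


# ---------------------------------------------------------------------------
# readers

def _read_species_long(path: Path, barcodes: pd.Index,
                       variant: str) -> Optional[SpeciesCounts]:
    if not path.exists():
        return None
    long = pd.read_csv(path, sep="\t")
    expected = {"barcode", "species", "count"}
    if not expected.issubset(long.columns):
        raise FormatError(f"{path.name}: expected columns {sorted(expected)}")
    if (long["count"] < 0).any():
        raise FormatError(f"{path.name}: negative counts")
    known = long["barcode"].isin(barcodes)
    dropped = int((~known).sum())
    if dropped:
        logger.warning("%s: dropped %d rows with unknown barcodes",
                       path.name, dropped)
    long = long[known]
    wide = (
        long.pivot_table(index="barcode", columns="species", values="count",
                         aggfunc="sum", fill_value=0)
        .reindex(barcodes, fill_value=0)
        .astype(np.int64)
    )
    wide.columns.name = None
    return SpeciesCounts(wide, variant)


def load_dataset(
    directory: str | Path,
    mito_genes: Optional[Sequence[str]] = None,
    mito_prefix: str = "MT-",
) -> SpatialDataset:
    """Load and join all tables under ``directory``.

    Barcodes present in one table but not another are dropped with a logged
    count; a mismatch above 50% between the host matrix and the metadata or
    fraction tables raises (almost certainly a wrong file pairing).
    """
    d = Path(directory)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv",
                 "spot_metadata.csv", "species_single.tsv",
                 "bulk_species.tsv", "cell_type_fractions.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(d / name)

    X = scipy_io.mmread(str(d / "matrix.mtx")).T.tocsr()
    barcodes = pd.Index(
        pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0], name="barcode"
    )
    genes = pd.Index(
        pd.read_csv(d / "features.tsv", sep="\t", header=None)[0], name="gene"
    )
    if X.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"matrix.mtx shape {X.shape} does not match "
            f"{len(barcodes)} barcodes x {len(genes)} features"
        )
    if X.data.size and X.data.min() < 0:
        raise FormatError("matrix.mtx: negative counts")

    meta = pd.read_csv(d / "spot_metadata.csv").set_index("barcode")
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise FormatError(f"spot_metadata.csv missing columns {missing}")
    frac = pd.read_csv(d / "cell_type_fractions.tsv", sep="\t").set_index(
        "barcode"
    )

    common = barcodes.intersection(meta.index).intersection(frac.index)
    for other, name in ((meta.index, "spot_metadata.csv"),
                        (frac.index, "cell_type_fractions.tsv")):
        overlap = barcodes.intersection(other)
        if len(overlap) < 0.5 * max(len(barcodes), 1):
            raise FormatError(
                f"{name}: <50% barcode overlap with host matrix — "
                "likely a wrong file pairing"
            )
    n_drop = len(barcodes) - len(common)
    if n_drop:
        logger.warning("dropping %d spots absent from metadata or fractions",
                       n_drop)
    keep = barcodes.get_indexer(common)
    X = X[keep]
    barcodes = common

    var = pd.DataFrame(index=genes)
    if mito_genes is not None:
        var["mito"] = genes.isin(set(mito_genes))
    else:
        var["mito"] = genes.str.upper().str.startswith(mito_prefix.upper())

    obs = meta.loc[barcodes].copy()
    obs["group"] = pd.Categorical(obs["group"], categories=list(GROUPS))
    if obs["group"].isna().any():
        raise FormatError("spot_metadata.csv: unknown group labels")
    host = ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)
    host.obs["mito_fraction"] = mito_fraction_from_counts(host)

    species_single = _read_species_long(d / "species_single.tsv", barcodes,
                                        "single")
    species_double = _read_species_long(d / "species_double.tsv", barcodes,
                                        "double")
    bulk = pd.read_csv(d / "bulk_species.tsv", sep="\t").set_index(
        "species"
    )["reads"]

    dataset = SpatialDataset(
        host=host,
        species_single=species_single,
        species_double=species_double,
        cell_fractions=frac.loc[barcodes],
        bulk_counts=bulk,
    )
    dataset.validate()
    logger.info(
        "loaded %d spots, %d genes, %d species from %s",
        dataset.n_spots, host.n_vars, len(species_single.species), d,
    )
    return dataset


# ---------------------------------------------------------------------------
# spot QC

def qc_filter_spots(
    dataset: SpatialDataset, mito_threshold: float = 0.40
) -> Tuple[SpatialDataset, pd.DataFrame]:
    """Drop low-quality spots with mito fraction strictly above the threshold.

    Returns the filtered dataset and a per-removed-spot report
    (barcode, sample_id, mito_fraction).
    """
    if not 0 <= mito_threshold <= 1:
        raise ParameterError("mito_threshold must be in [0, 1]")
    mf = dataset.obs["mito_fraction"].to_numpy(dtype=float)
    removed = mf > mito_threshold
    report = dataset.obs.loc[removed, ["sample_id", "mito_fraction"]].copy()
    report.index.name = "barcode"
    logger.info("QC removed %d / %d spots (mito fraction > %.2f)",
                int(removed.sum()), dataset.n_spots, mito_threshold)
    return dataset.subset(~removed), report.reset_index()


# ---------------------------------------------------------------------------
# area labels

def normalize_area_map(
    area_map: Mapping[str, object],
) -> dict[str, str]:
    """Accept either ``cell_type -> area`` or ``area -> [cell types]`` and
    return the former; a cell type mapped to two areas is a config error."""
    out: dict[str, str] = {}
    for key, value in area_map.items():
        if isinstance(value, str):
            pairs = [(key, value)]
        else:
            pairs = [(ct, key) for ct in value]
        for ct, area in pairs:
            if ct in out and out[ct] != area:
                raise ParameterError(
                    f"cell type {ct!r} mapped to both {out[ct]!r} and {area!r}"
                )
            out[ct] = area
    return out


def assign_area_labels(
    dataset: SpatialDataset,
    area_map: Optional[Mapping[str, object]] = None,
) -> SpatialDataset:
    """Label each spot with its dominant cell-type area.

    Fine cell-type fractions are summed within area groups and the spot is
    labelled by the argmax; ties break lexicographically by area name (and
    are logged).  The label lands in ``obs["area_label"]``.
    """
    cmap = normalize_area_map(area_map if area_map is not None
                              else DEFAULT_AREA_MAP)
    frac = dataset.cell_fractions
    unmapped = [c for c in frac.columns if c not in cmap]
    if unmapped:
        # unmapped fine types keep their own name as an area
        cmap = {**cmap, **{c: c for c in unmapped}}
    grouped = frac.T.groupby(frac.columns.map(cmap)).sum().T
    grouped = grouped.reindex(sorted(grouped.columns), axis=1)
    arr = grouped.to_numpy()
    best = arr.argmax(axis=1)  # argmax takes the first = lexicographic min
    n_ties = int((np.isclose(arr, arr.max(axis=1, keepdims=True)).sum(axis=1)
                  > 1).sum())
    if n_ties:
        logger.info("area labels: %d ties broken lexicographically", n_ties)
    labels = grouped.columns.to_numpy()[best]
    out = dataset.subset(np.ones(dataset.n_spots, dtype=bool))
    out.host.obs["area_label"] = pd.Categorical(
        labels, categories=list(grouped.columns)
    )
    return out
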