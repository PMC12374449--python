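import numpy as np
import pytest

import microspot as ms


@pytest.fixture(scope="session")
def worked():
    """The deterministic hand-checkable fixture dataset + ground truth."""
    return ms.worked_fixture()


@pytest.fixture(scope="session")
def planted_sim():
    """Mid-size simulation with planted risk and expression effects,
    shared by the quantification / risk / expression tests."""
    config = ms.SimulationConfig(
        n_samples=6,
        n_spots_per_sample=1200,
        n_genes=80,
        n_species=10,
        n_contaminant_species=4,
        planted_rr={"sp_001": 0.45, "sp_002": 2.2},
        planted_log_fold_change={
            ("sp_001", "GENE0001"): 2.0,
            ("sp_002", "GENE0002"): -2.0,
        },
        seed=11,
    )
    dataset, truth = ms.simulate_dataset(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def planted_analysis(planted_sim):
    """QC-filtered, area-labelled, decontaminated view of planted_sim."""
    _, dataset, truth = planted_sim
    dataset, _ = ms.qc_filter_spots(dataset)
    dataset = ms.assign_area_labels(dataset)
    retained, report = ms.decontaminate(dataset)
    return dataset, retained, report, truth


def brute_force_retained(single, double, bulk, thresholds=None):
    """Independent re-evaluation of the four printed inequalities, species
    by species, with plain Python arithmetic."""
    thresholds = thresholds or ms.DecontamThresholds()
    spatial_tot = {s: int(single[s].sum()) for s in single.columns}
    double_tot = {s: int(double[s].sum()) for s in double.columns}
    bulk_tot = {s: int(bulk.get(s, 0)) for s in single.columns}
    grand_sp = sum(spatial_tot.values())
    grand_bulk = sum(bulk_tot.values())
    kept = []
    for s in single.columns:
        sp_pct = spatial_tot[s] / grand_sp if grand_sp else 0.0
        bk_pct = bulk_tot[s] / grand_bulk if grand_bulk else 0.0
        if spatial_tot[s] < thresholds.min_spatial_reads:
            continue
        if bulk_tot[s] < thresholds.min_bulk_reads:
            continue
        if bk_pct == 0:
            if sp_pct > 0:
                continue
        elif sp_pct / bk_pct > thresholds.max_spatial_bulk_ratio:
            continue
        if spatial_tot[s] > 0 and \
                double_tot[s] / spatial_tot[s] < thresholds.min_double_survival:
            continue
        kept.append(s)
    return kept
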