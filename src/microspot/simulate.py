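"""Synthetic spot-resolved host-microbiome datasets with planted ground truth.

Every pipeline stage in this package is verified against data generated here:
the generator plants (i) contaminant species that each violate exactly one
decontamination rule, (ii) per-species relative risks of spot damage, and
(iii) expression shifts conditional on bacterial presence, and returns the
ground truth alongside the dataset so recovery can be tested.

Generative model
----------------
* Spots belong to samples; samples cycle through the three tissue groups
  (control, non-inflamed CD, inflamed CD).  A non-inflamed/inflamed pair in
  the same cycle shares a patient, mirroring two sections from one biopsy.
* Cell-type fractions are symmetric Dirichlet draws; a small "M-cell
  stratum" of CD spots draws from a Dirichlet concentrated on M cells and
  carries elevated bacterial exposure.
* Species exposure is Bernoulli per spot with a per-species base rate scaled
  by tissue group (inflamed > non-inflamed > control), patient severity, and
  the M-cell stratum; exposed spots receive 1 + Poisson read counts.
* A spot's damage probability is the baseline rate times the product of
  per-species risk multipliers over the species it is exposed to, capped
  at 1.  The multipliers are calibrated (fixed point on the drawn exposure
  matrix) so that each species' *marginal* relative risk equals its planted
  value even though heterogeneous exposure rates correlate exposures; risk
  estimates are therefore directly checkable against ``planted_rr``.
* The mitochondrial read fraction is drawn from a high-mean Beta for damaged
  spots and a low-mean Beta for viable ones, with overlap: the downstream
  10% classifier is informative but deliberately noisy.
* Host counts: per-spot totals are negative binomial; the mitochondrial
  share is binomial at the spot's target fraction; counts are multinomial
  over fixed log-normal gene weights, with weights of planted
  (species, gene) pairs multiplied by 2**log2FC in exposed spots.
* Bulk metagenome totals are Poisson around the spatial totals (equal
  sequencing depth), so genuine species have a spatial/bulk percentage
  ratio near 1.  Double-removal counts are binomial thinnings of the
  single-removal counts at a per-species survival factor: >=0.5 for genuine
  species, <0.02 in expectation for planted human-read artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .containers import (
    GROUPS,
    ParameterError,
    SpatialDataset,
    SpeciesCounts,
)

# Canonical human mitochondrial gene symbols; extended with synthetic
# "MT-X.." symbols if a config asks for more.
MITO_SYMBOLS = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

DEFAULT_CELL_TYPES = (
    "enterocyte",
    "goblet",
    "stem",
    "tuft",
    "M_cell",
    "B_cell",
    "T_cell",
    "myeloid",
)

#: decontamination-rule identifiers used for planted contaminants
RULE_SPATIAL_FLOOR = "spatial_floor"
RULE_BULK_FLOOR = "bulk_floor"
RULE_RATIO = "spatial_bulk_ratio"
RULE_SURVIVAL = "double_removal_survival"
CONTAMINANT_RULES = (RULE_SPATIAL_FLOOR, RULE_BULK_FLOOR, RULE_RATIO,
                     RULE_SURVIVAL)

GROUP_EXPOSURE_SCALE = {
    "control": 0.3,
    "CD_noninflamed": 1.0,
    "CD_inflamed": 2.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset.

    ``planted_rr`` maps genuine species names (``sp_001`` ...) to the risk
    ratio of spot damage given exposure; unnamed species get 1.0 (null).
    ``planted_log_fold_change`` maps ``(species, gene)`` to a log2
    expression shift applied in exposed spots.  ``exposure_rate`` is either
    a scalar base exposure probability or a per-species map; the realized
    per-spot probability also depends on tissue group and stratum.
    """

    n_samples: int = 6
    n_spots_per_sample: int = 300
    n_genes: int = 200
    n_mito_genes: int = 13
    n_species: int = 20
    n_contaminant_species: int = 4
    planted_rr: Optional[Mapping[str, float]] = None
    planted_log_fold_change: Optional[Mapping[Tuple[str, str], float]] = None
    baseline_damage_rate: float = 0.08
    exposure_rate: float | Mapping[str, float] = 0.15
    dirichlet_alpha: Optional[np.ndarray] = None
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    nb_mean: float = 2000.0
    nb_dispersion: float = 2.0
    mean_reads_per_exposure: float = 4.0
    m_cell_fraction: float = 0.10
    m_cell_exposure_boost: float = 2.0
    read_depth_scale: float = 50.0
    calibrate_marginal_rr: bool = True
    seed: int = 0

    # -- derived labels ---------------------------------------------------
    @property
    def n_genuine_species(self) -> int:
        return self.n_species - self.n_contaminant_species

    def genuine_species_names(self) -> list[str]:
        return [f"sp_{i + 1:03d}" for i in range(self.n_genuine_species)]

    def contaminant_species_names(self) -> list[str]:
        names = []
        for j in range(self.n_contaminant_species):
            rule = CONTAMINANT_RULES[j % len(CONTAMINANT_RULES)]
            names.append(f"contam_{rule}_{j + 1}")
        return names

    def species_names(self) -> list[str]:
        return self.genuine_species_names() + self.contaminant_species_names()

    def gene_names(self) -> list[str]:
        if self.n_mito_genes <= len(MITO_SYMBOLS):
            mito = list(MITO_SYMBOLS[: self.n_mito_genes])
        else:
            mito = list(MITO_SYMBOLS) + [
                f"MT-X{i}" for i in range(self.n_mito_genes - len(MITO_SYMBOLS))
            ]
        body = [f"GENE{i + 1:04d}" for i in range(self.n_genes - self.n_mito_genes)]
        return body + mito

    def validate(self) -> None:
        for fld in ("n_samples", "n_spots_per_sample", "n_genes", "n_species"):
            if getattr(self, fld) <= 0:
                raise ParameterError(f"{fld} must be positive")
        if not 0 <= self.n_mito_genes < self.n_genes:
            raise ParameterError("n_mito_genes must be in [0, n_genes)")
        if not 0 <= self.n_contaminant_species <= self.n_species:
            raise ParameterError("n_contaminant_species must be <= n_species")
        if not 0 <= self.baseline_damage_rate <= 1:
            raise ParameterError("baseline_damage_rate must be in [0, 1]")
        if not 0 <= self.m_cell_fraction <= 1:
            raise ParameterError("m_cell_fraction must be in [0, 1]")
        genuine = set(self.genuine_species_names())
        if self.planted_rr is not None:
            for name, rr in self.planted_rr.items():
                if name not in genuine:
                    raise ParameterError(
                        f"planted_rr refers to unknown species {name!r}"
                    )
                if rr <= 0:
                    raise ParameterError(f"planted_rr[{name!r}] must be > 0")
        rates = self.exposure_rate
        if isinstance(rates, Mapping):
            items = rates.items()
        else:
            items = [("<scalar>", rates)]
        for name, p in items:
            if not 0 <= p <= 1:
                raise ParameterError(
                    f"exposure_rate[{name!r}] must be in [0, 1]"
                )
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ParameterError("nb_mean and nb_dispersion must be positive")
        if self.dirichlet_alpha is not None:
            alpha = np.asarray(self.dirichlet_alpha, dtype=float)
            if alpha.shape != (len(self.cell_types),):
                raise ParameterError(
                    "dirichlet_alpha length must match cell_types"
                )
            if (alpha <= 0).any():
                raise ParameterError("dirichlet_alpha entries must be > 0")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests and sidecar export."""

    contaminant_rules: Dict[str, str]  # species -> violated rule id
    beneficial_species: set
    pathogenic_species: set
    damage_state: pd.Series  # per-spot boolean, barcode-indexed
    planted_rr: Dict[str, float]
    planted_log_fold_change: Dict[Tuple[str, str], float]
    m_cell_stratum: pd.Index
    survival_factors: Dict[str, float]

    def __post_init__(self) -> None:
        if self.beneficial_species & self.pathogenic_species:
            raise ParameterError(
                "beneficial and pathogenic sets must be disjoint"
            )

    @property
    def contaminant_species(self) -> set:
        return set(self.contaminant_rules)

    def to_jsonable(self) -> dict:
        return {
            "contaminant_rules": dict(self.contaminant_rules),
            "beneficial_species": sorted(self.beneficial_species),
            "pathogenic_species": sorted(self.pathogenic_species),
            "damage_state": {
                b: bool(v) for b, v in self.damage_state.items()
            },
            "planted_rr": dict(self.planted_rr),
            "planted_log_fold_change": {
                f"{s}::{g}": v
                for (s, g), v in self.planted_log_fold_change.items()
            },
            "m_cell_stratum": list(self.m_cell_stratum),
            "survival_factors": dict(self.survival_factors),
        }


# ---------------------------------------------------------------------------
# spot frame

def _build_spot_frame(config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_samples):
        sample = f"S{i + 1:02d}"
        group = GROUPS[i % 3]
        cycle = i // 3
        patient = f"CTRL{cycle + 1:02d}" if group == "control" \
            else f"CD{cycle + 1:02d}"
        side = max(1, int(math.ceil(math.sqrt(config.n_spots_per_sample))))
        for j in range(config.n_spots_per_sample):
            rows.append(
                (f"{sample}_BC{j + 1:05d}", sample, patient, group,
                 j % side, j // side)
            )
    obs = pd.DataFrame(
        rows, columns=["barcode", "sample_id", "patient_id", "group", "x", "y"]
    ).set_index("barcode")

    # patient-level severity drives exposure, Rutgeerts score and relapse
    severity, rutgeerts, relapse_months = {}, {}, {}
    for patient in pd.unique(obs["patient_id"]):
        is_cd = patient.startswith("CD")
        u = float(rng.uniform(0.5, 1.5)) if is_cd else 1.0
        severity[patient] = u
        if is_cd:
            rutgeerts[patient] = int(np.clip(round(u * 2.5 +
                                                   rng.normal(0, 0.5)), 0, 4))
            if rng.uniform() < 0.6:  # relapse: shorter time at higher load
                relapse_months[patient] = float(
                    np.clip(round(40.0 / u + rng.normal(0, 2.0)), 3, 96)
                )
    obs["severity"] = obs["patient_id"].map(severity)
    obs["rutgeerts_score"] = obs["patient_id"].map(rutgeerts)
    obs["time_to_relapse_months"] = obs["patient_id"].map(relapse_months)
    return obs


# ---------------------------------------------------------------------------
# main generator

def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[SpatialDataset, GroundTruth]:
    """Draw one complete dataset plus its ground truth from ``config``.

    Identical configs (same ``seed``) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    obs = _build_spot_frame(config, rng)
    n_spots = len(obs)
    genuine = config.genuine_species_names()
    contaminants = config.contaminant_species_names()
    species = genuine + contaminants
    genes = config.gene_names()
    n_body = config.n_genes - config.n_mito_genes

    # --- cell-type fractions with an M-cell stratum in CD tissue ----------
    cell_types = list(config.cell_types)
    alpha = (np.asarray(config.dirichlet_alpha, dtype=float)
             if config.dirichlet_alpha is not None
             else np.ones(len(cell_types)))
    fractions = rng.dirichlet(alpha, size=n_spots)
    cd = obs["group"].isin(("CD_noninflamed", "CD_inflamed")).to_numpy()
    stratum = np.zeros(n_spots, dtype=bool)
    if "M_cell" in cell_types and config.m_cell_fraction > 0:
        candidates = np.flatnonzero(cd)
        k = int(round(config.m_cell_fraction * candidates.size))
        chosen = rng.choice(candidates, size=k, replace=False)
        stratum[chosen] = True
        alpha_m = alpha.copy()
        alpha_m[cell_types.index("M_cell")] += 8.0
        fractions[chosen] = rng.dirichlet(alpha_m, size=k)
    frac_df = pd.DataFrame(fractions, index=obs.index, columns=cell_types)

    # --- exposure and read counts for genuine species ---------------------
    if isinstance(config.exposure_rate, Mapping):
        base_rate = np.array(
            [config.exposure_rate.get(s, 0.15) for s in genuine]
        )
    else:
        base_rate = np.full(len(genuine), float(config.exposure_rate))
    scale = (obs["group"].map(GROUP_EXPOSURE_SCALE).to_numpy(dtype=float)
             * obs["severity"].to_numpy(dtype=float)
             * np.where(stratum, config.m_cell_exposure_boost, 1.0))
    prob = np.clip(scale[:, None] * base_rate[None, :], 0.0, 0.95)
    exposed = rng.uniform(size=prob.shape) < prob
    extra = rng.poisson(max(config.mean_reads_per_exposure - 1.0, 0.0),
                        size=prob.shape)
    counts = exposed * (1 + extra)

    # --- damage via multiplicative planted risk ---------------------------
    # planted_rr specifies the *marginal* relative risk of each species.
    # Exposure probabilities vary across spots (tissue group, patient
    # severity, M-cell stratum), which correlates exposures and would
    # attenuate every marginal RR if the planted values were applied as raw
    # conditional multipliers; the per-species multipliers are therefore
    # calibrated by fixed point on the drawn exposure matrix so that the
    # infinite-sample marginal risk ratio equals the planted value.
    planted_rr = {s: 1.0 for s in genuine}
    if config.planted_rr:
        planted_rr.update({k: float(v) for k, v in config.planted_rr.items()})
    rr_vec = np.array([planted_rr[s] for s in genuine])
    log_u = np.log(rr_vec)
    b = config.baseline_damage_rate
    exp_f = exposed.astype(float)
    # target population: the CD spots the risk screen analyses
    pop = exp_f[cd] if cd.any() else exp_f
    n_exp = pop.sum(axis=0)
    n_unexp = len(pop) - n_exp
    solvable = (n_exp > 0) & (n_unexp > 0) & (rr_vec != 1.0)
    if config.calibrate_marginal_rr and solvable.any():
        for _ in range(200):
            p = np.clip(b * np.exp(pop @ log_u), 0.0, 1.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                marg = (pop.T @ p / n_exp) / ((1 - pop).T @ p / n_unexp)
            step = np.where(solvable & np.isfinite(marg) & (marg > 0),
                            np.log(rr_vec) - np.log(marg), 0.0)
            log_u += 0.5 * step  # damped: species' marginals are coupled
            if np.abs(step).max(initial=0.0) < 1e-10:
                break
    risk = b * np.exp(exp_f @ log_u)
    damaged = rng.uniform(size=n_spots) < np.clip(risk, 0.0, 1.0)

    # --- mitochondrial fraction targets -----------------------------------
    # Overlap sits almost entirely on the damaged side: damaged spots that
    # read as viable lower both arms of a risk ratio proportionally and
    # cancel, while viable spots misread as damaged would bias every RR
    # toward 1, so the viable tail above the 10% cutoff is kept negligible.
    mito_target = np.where(
        damaged,
        rng.beta(8.0, 32.0, size=n_spots),    # mean 0.20, ~5% below 10%
        rng.beta(8.0, 192.0, size=n_spots),   # mean 0.04, ~0.1% above 10%
    )

    # --- host counts -------------------------------------------------------
    p_nb = config.nb_dispersion / (config.nb_dispersion + config.nb_mean)
    totals = rng.negative_binomial(config.nb_dispersion, p_nb, size=n_spots)
    totals = np.maximum(totals, 20)  # avoid empty spots
    mito_totals = rng.binomial(totals, mito_target)
    body_weights = rng.lognormal(0.0, 1.0, size=n_body)
    mito_weights = rng.lognormal(0.0, 0.5, size=config.n_mito_genes)
    mito_weights /= mito_weights.sum()

    lfc = dict(config.planted_log_fold_change or {})
    gene_pos = {g: i for i, g in enumerate(genes)}
    sp_pos = {s: i for i, s in enumerate(genuine)}
    # per-species list of (gene body index, multiplier)
    effects: Dict[int, list] = {}
    for (s, g), value in lfc.items():
        if s not in sp_pos or g not in gene_pos:
            raise ParameterError(
                f"planted_log_fold_change key ({s!r}, {g!r}) is unknown"
            )
        if gene_pos[g] >= n_body:
            raise ParameterError(
                f"planted_log_fold_change cannot target mito gene {g!r}"
            )
        effects.setdefault(sp_pos[s], []).append((gene_pos[g], 2.0 ** value))

    X = np.zeros((n_spots, config.n_genes), dtype=np.int64)
    base_w = body_weights / body_weights.sum()
    for i in range(n_spots):
        if effects:
            w = body_weights.copy()
            for s_idx, pairs in effects.items():
                if exposed[i, s_idx]:
                    for g_idx, mult in pairs:
                        w[g_idx] *= mult
            w = w / w.sum()
        else:
            w = base_w
        X[i, :n_body] = rng.multinomial(totals[i] - mito_totals[i], w)
        if config.n_mito_genes:
            X[i, n_body:] = rng.multinomial(mito_totals[i], mito_weights)

    obs = obs.copy()
    obs["mito_fraction"] = mito_totals / totals

    # --- contaminant species ----------------------------------------------
    contam_counts = np.zeros((n_spots, len(contaminants)), dtype=np.int64)
    contam_rules: Dict[str, str] = {}
    cd_spots = np.flatnonzero(cd)
    for j, name in enumerate(contaminants):
        rule = CONTAMINANT_RULES[j % len(CONTAMINANT_RULES)]
        contam_rules[name] = rule
        if rule == RULE_SPATIAL_FLOOR:
            total = int(rng.integers(10, 50))     # < 50 spatial reads
        elif rule == RULE_BULK_FLOOR:
            total = int(rng.integers(52, 66))     # small but above floor
        elif rule == RULE_RATIO:
            total = int(rng.integers(400, 900))   # sizeable spatial presence
        else:
            total = int(rng.integers(500, 1200))
        where = rng.choice(cd_spots if cd_spots.size else np.arange(n_spots),
                           size=total, replace=True)
        np.add.at(contam_counts[:, j], where, 1)

    single = np.concatenate([counts, contam_counts], axis=1)
    single_df = pd.DataFrame(single, index=obs.index, columns=species)
    spatial_totals = single_df.sum(axis=0)

    # --- bulk counts: Poisson at equal depth, rule-specific deviations -----
    bulk = {}
    for s in genuine:
        bulk[s] = int(rng.poisson(max(spatial_totals[s], 60)))
    for name in contaminants:
        rule = contam_rules[name]
        t = spatial_totals[name]
        if rule == RULE_SPATIAL_FLOOR:
            bulk[name] = int(rng.poisson(200))          # healthy bulk signal
        elif rule == RULE_BULK_FLOOR:
            bulk[name] = int(rng.integers(42, 50))      # < 50 bulk reads
        elif rule == RULE_RATIO:
            bulk[name] = max(int(rng.poisson(t / 3.0)), 60)  # ~3x over-rep
        else:
            bulk[name] = int(rng.poisson(max(t, 60)))
    bulk_series = pd.Series(bulk, name="reads").loc[species]

    # --- double-removal thinning -------------------------------------------
    survival: Dict[str, float] = {}
    for s in species:
        if contam_rules.get(s) == RULE_SURVIVAL:
            survival[s] = float(rng.uniform(0.002, 0.008))
        else:
            survival[s] = float(rng.uniform(0.5, 0.85))
    surv_vec = np.array([survival[s] for s in species])
    double = rng.binomial(single, surv_vec[None, :])
    double_df = pd.DataFrame(double, index=obs.index, columns=species)

    # --- totals, container assembly ----------------------------------------
    bact_total = single_df.sum(axis=1).to_numpy()
    obs["total_sequencing_reads"] = (
        np.round(totals * config.read_depth_scale).astype(np.int64)
        + bact_total
    )
    obs["group"] = pd.Categorical(obs["group"], categories=list(GROUPS))
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["mito"] = [g.upper().startswith("MT-") for g in genes]
    host = ad.AnnData(
        X=sparse.csr_matrix(X), obs=obs.drop(columns=["severity"]), var=var
    )

    dataset = SpatialDataset(
        host=host,
        species_single=SpeciesCounts(single_df, "single"),
        species_double=SpeciesCounts(double_df, "double"),
        cell_fractions=frac_df,
        bulk_counts=bulk_series,
    )
    dataset.validate()

    truth = GroundTruth(
        contaminant_rules=contam_rules,
        beneficial_species={s for s, r in planted_rr.items() if r < 1},
        pathogenic_species={s for s, r in planted_rr.items() if r > 1},
        damage_state=pd.Series(damaged, index=obs.index, name="damaged"),
        planted_rr=planted_rr,
        planted_log_fold_change=lfc,
        m_cell_stratum=obs.index[stratum],
        survival_factors=survival,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# worked fixture

def _spread(total: int, n_all: int, active: np.ndarray) -> np.ndarray:
    """Distribute ``total`` reads over ``active`` spot indices: an equal base
    share plus one extra read for the first ``total % len(active)`` spots."""
    out = np.zeros(n_all, dtype=np.int64)
    base, rem = divmod(total, active.size)
    out[active] = base
    out[active[:rem]] += 1
    return out


#: hand-set decontamination block of the worked fixture:
#: species -> (spatial total, bulk total, double-removal total)
WORKED_SPECIES = {
    "g01": (600, 606, 360),                 # tops up bulk so depths match
    **{f"g{i:02d}": (600, 601, 360) for i in range(2, 11)},
    "boundary_low_reads": (50, 100, 30),    # exactly at the 50-read floor
    "boundary_ratio": (150, 100, 90),       # spatial/bulk ratio exactly 1.50
    "boundary_survival": (1000, 1000, 20),  # survival exactly 0.020
    "contam_low_reads": (49, 100, 29),      # fails the spatial floor only
    "contam_absent_bulk": (60, 49, 36),     # fails the bulk floor only
    "contam_ratio": (155, 100, 93),         # ratio 1.55, fails rule 3 only
    "contam_artifact": (1000, 1000, 19),    # survival 0.019, fails rule 4
}

WORKED_CONTAMINANT_RULES = {
    "contam_low_reads": RULE_SPATIAL_FLOOR,
    "contam_absent_bulk": RULE_BULK_FLOOR,
    "contam_ratio": RULE_RATIO,
    "contam_artifact": RULE_SURVIVAL,
}


def worked_fixture() -> Tuple[SpatialDataset, GroundTruth]:
    """A deterministic 180-spot, 18-species, 120-gene dataset whose
    decontamination block is hand-set.

    Spatial and bulk grand totals are equal (8464 reads each), so each
    species' spatial/bulk percentage ratio equals its spatial/bulk read
    ratio and can be checked by eye.  Four contaminants each violate exactly
    one rule (49 spatial reads; 49 bulk reads; ratio 1.55; survival 0.019)
    and three boundary species sit exactly on the thresholds (50 reads;
    ratio 1.50; survival 0.020) on the retained side.  Genuine species have
    double/single survival exactly 0.60.
    """
    config = SimulationConfig(
        n_samples=3,
        n_spots_per_sample=60,
        n_genes=120,
        n_mito_genes=13,
        n_species=17,
        n_contaminant_species=0,
        seed=20_260_101,
    )
    dataset, _ = simulate_dataset(config)
    obs = dataset.host.obs
    n = len(obs)
    cd_spots = np.flatnonzero(
        obs["group"].isin(("CD_noninflamed", "CD_inflamed")).to_numpy()
    )

    names = list(WORKED_SPECIES)
    single = np.column_stack(
        [_spread(sp, n, cd_spots) for sp, _, _ in WORKED_SPECIES.values()]
    )
    double = np.column_stack(
        [_spread(dbl, n, cd_spots) for _, _, dbl in WORKED_SPECIES.values()]
    )
    single_df = pd.DataFrame(single, index=obs.index, columns=names)
    double_df = pd.DataFrame(double, index=obs.index, columns=names)
    bulk = pd.Series({s: b for s, (_, b, _) in WORKED_SPECIES.items()},
                     name="reads").loc[names]

    host = dataset.host.copy()
    host.obs["total_sequencing_reads"] = (
        host.obs["total_sequencing_reads"].to_numpy()
        - dataset.species_single.counts.sum(axis=1).to_numpy()
        + single_df.sum(axis=1).to_numpy()
    )
    fixture = SpatialDataset(
        host=host,
        species_single=SpeciesCounts(single_df, "single"),
        species_double=SpeciesCounts(double_df, "double"),
        cell_fractions=dataset.cell_fractions,
        bulk_counts=bulk,
    )
    fixture.validate()
    truth = GroundTruth(
        contaminant_rules=dict(WORKED_CONTAMINANT_RULES),
        beneficial_species=set(),
        pathogenic_species=set(),
        damage_state=pd.Series(
            host.obs["mito_fraction"].to_numpy() > 0.10,
            index=host.obs.index, name="damaged",
        ),
        planted_rr={},
        planted_log_fold_change={},
        m_cell_stratum=pd.Index([], dtype=object),
        survival_factors={
            s: (d / sp if sp else float("nan"))
            for s, (sp, _, d) in WORKED_SPECIES.items()
        },
    )
    return fixture, truth
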