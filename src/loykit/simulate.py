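"""Synthetic single-cell cohorts and digital-PCR plates.

The generator emulates the statistical structure the downstream LOY
analysis assumes: a bimodal chrY coverage distribution with a
donor-varying LOY fraction, cell-type-specific chrY accessibility
offsets, donor random intercepts plus age / CNV-burden / disease effects
on the LOY odds, per-cell sequencing-depth variation, sporadic
whole-chromosome gains, and microwell dPCR plates with Poisson
partitioning. Every cell carries a ground-truth genotype so estimator
recovery can be measured exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import CellCoverageTable, CnvBinMatrix, DISEASE_LEVELS
from .genome import GenomeBins, chromosome_lengths, make_bins, AUTOSOMES


@dataclass
class CellTypeSpec:
    """One cell type: abundance, LOY log-odds offset, chrY accessibility.

    ``y_accessibility`` scales the expected chrY coverage of intact-Y
    cells of this type (cell-type-specific chromatin accessibility or
    expression of chrY), the nuisance the median-ratio correction is
    designed to remove.
    """

    name: str
    abundance: float
    loy_logit_offset: float = 0.0
    y_accessibility: float = 1.0


def default_celltype_specs() -> list[CellTypeSpec]:
    """Kidney-cortex-like cell type mix.

    Proximal tubule (PT) is the reference and most abundant type; the
    injured PT_VCAM1 state has elevated LOY odds; podocytes (PODO) have
    strongly reduced odds; accessibility factors vary moderately around 1.
    """
    return [
        CellTypeSpec("PT", 0.40, 0.0, 1.0),
        CellTypeSpec("PT_VCAM1", 0.10, math.log(1.46), 0.90),
        CellTypeSpec("TAL", 0.20, math.log(1.05), 1.10),
        CellTypeSpec("DCT", 0.15, math.log(0.70), 1.00),
        CellTypeSpec("PODO", 0.05, math.log(0.17), 0.80),
        CellTypeSpec("ENDO", 0.10, math.log(0.50), 1.05),
    ]


@dataclass
class CohortConfig:
    """Parameters of the generative model for one synthetic cohort.

    The per-cell genotype is drawn from
    ``logit P(LOY) = baseline + celltype_offset + age_effect*age
    + cnv_effect*true_burden + disease_effect*1[CKD] + u_donor`` with
    ``u_donor ~ Normal(0, donor_random_intercept_sd^2)``. Counts are
    Poisson given each cell's expected per-chromosome fractions.
    """

    n_donors: int = 8
    n_cells_per_donor: int = 1000
    donor_ages: list[float] | None = None
    donor_disease: list[str] | None = None
    donor_random_intercept_sd: float = 0.5
    baseline_loy_logit: float = -3.0
    celltype_specs: list[CellTypeSpec] = field(default_factory=default_celltype_specs)
    age_effect: float = 0.02  # log-odds per year
    cnv_effect: float = 2.0  # log-odds per unit burden
    disease_effect: float = 0.4  # log-odds for the CKD indicator
    # (log-mean, log-sd) of the per-cell total count, per modality
    depth_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "RNA": (math.log(3000.0), 0.4),
            "ATAC": (math.log(15000.0), 0.4),
        }
    )
    # expected fraction of an intact-Y male cell's counts mapping to chrY
    y_fraction_xy: dict[str, float] = field(
        default_factory=lambda: {"RNA": 0.005, "ATAC": 0.004}
    )
    ambient_y_rate: float = 0.0
    gain_spec: tuple[str, float, float] = ("chr7", 0.02, 1.5)
    include_females: bool = False
    female_fraction: float = 0.0
    bin_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if not self.celltype_specs:
            raise ValueError("celltype_specs must be non-empty")
        ab = sum(s.abundance for s in self.celltype_specs)
        if abs(ab - 1.0) > 1e-8:
            raise ValueError(f"cell type abundances must sum to 1 (got {ab})")
        if any(s.y_accessibility <= 0 for s in self.celltype_specs):
            raise ValueError("y_accessibility factors must be > 0")
        if not (0.0 <= self.ambient_y_rate < 1.0):
            raise ValueError("ambient_y_rate must lie in [0, 1)")
        if self.donor_ages is None:
            self.donor_ages = list(
                np.linspace(40, 80, self.n_donors)
            )
        if len(self.donor_ages) != self.n_donors:
            raise ValueError("donor_ages length must equal n_donors")
        if any(a < 0 for a in self.donor_ages):
            raise ValueError("ages must be non-negative")
        if self.donor_disease is None:
            self.donor_disease = [
                "CKD" if i % 2 else "control" for i in range(self.n_donors)
            ]
        if len(self.donor_disease) != self.n_donors:
            raise ValueError("donor_disease length must equal n_donors")
        if any(d not in DISEASE_LEVELS for d in self.donor_disease):
            raise ValueError(f"disease must be one of {DISEASE_LEVELS}")
        for mod, (mu, sd) in self.depth_model.items():
            if sd < 0:
                raise ValueError(f"negative depth log-sd for {mod}")
        if any(f < 0 for f in self.y_fraction_xy.values()):
            raise ValueError("y_fraction_xy must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


@dataclass
class SyntheticCohort:
    """Output bundle of :func:`simulate_cohort`."""

    tables: dict[str, CellCoverageTable]
    bin_matrix: CnvBinMatrix | None
    truth: pd.DataFrame
    genome_bins: GenomeBins
    config: CohortConfig


def _copy_weighted_lengths(sex: str) -> dict[str, float]:
    """Length x (copy number / 2) weights for non-Y chromosomes."""
    lengths = chromosome_lengths()
    weights = {c: float(lengths[c]) for c in AUTOSOMES}
    weights["chrX"] = lengths["chrX"] * (1.0 if sex == "F" else 0.5)
    return weights


def simulate_cohort(
    config: CohortConfig,
    make_bin_matrix: bool = True,
    genome_bins: GenomeBins | None = None,
) -> SyntheticCohort:
    """Draw a full synthetic cohort (RNA + ATAC tables, bins, truth).

    The seed in ``config`` fully determines the output. Returns a
    :class:`SyntheticCohort` whose ``truth`` table has one row per cell
    with true genotype, gained chromosome, true CNV burden and metadata.
    """
    rng = np.random.default_rng(config.seed)
    if genome_bins is None:
        genome_bins = make_bins(bin_size=config.bin_size)
    retained_bins = genome_bins.retained.reset_index(drop=True)
    n_bins = len(retained_bins)
    chrom_of_bin = retained_bins["chrom"].to_numpy()

    n_cells = config.n_donors * config.n_cells_per_donor
    donor_idx = np.repeat(np.arange(config.n_donors), config.n_cells_per_donor)
    donor_ids = np.array([f"D{i:02d}" for i in range(config.n_donors)])
    ages = np.asarray(config.donor_ages, dtype=float)
    disease = np.asarray(config.donor_disease, dtype=object)
    u_donor = rng.normal(0.0, config.donor_random_intercept_sd, config.n_donors)

    specs = config.celltype_specs
    ct_idx = rng.choice(
        len(specs), size=n_cells, p=[s.abundance for s in specs]
    )
    ct_names = np.array([s.name for s in specs])
    ct_offsets = np.array([s.loy_logit_offset for s in specs])
    ct_access = np.array([s.y_accessibility for s in specs])

    sex = np.full(n_cells, "M", dtype=object)
    if config.include_females and config.female_fraction > 0:
        sex[rng.random(n_cells) < config.female_fraction] = "F"
    male = sex == "M"

    # sporadic whole-chromosome gains
    gain_chrom, gain_prob, gain_fold = config.gain_spec
    gained = rng.random(n_cells) < gain_prob
    gain_bin_mask = chrom_of_bin == gain_chrom
    n_gain_bins = int(gain_bin_mask.sum())
    if gain_prob > 0 and n_gain_bins == 0:
        raise ValueError(f"gain chromosome {gain_chrom!r} has no retained bins")
    true_burden = np.where(gained, n_gain_bins / n_bins, 0.0)

    # genotype from the logistic mixed model (males only; females are XX)
    eta = (
        config.baseline_loy_logit
        + ct_offsets[ct_idx]
        + config.age_effect * ages[donor_idx]
        + config.cnv_effect * true_burden
        + config.disease_effect * (disease[donor_idx] == "CKD").astype(float)
        + u_donor[donor_idx]
    )
    loy = (rng.random(n_cells) < expit(eta)) & male
    genotype = np.where(~male, "XX", np.where(loy, "LOY", "XY"))

    cell_ids = pd.Index(
        [f"{donor_ids[d]}_c{i:06d}" for i, d in enumerate(donor_idx)], name="cell_id"
    )
    meta = pd.DataFrame(
        {
            "donor_id": donor_ids[donor_idx],
            "sex": sex,
            "age": ages[donor_idx],
            "cell_type": ct_names[ct_idx],
            "disease": disease[donor_idx],
        },
        index=cell_ids,
    )

    lengths = chromosome_lengths()
    tables: dict[str, CellCoverageTable] = {}
    bin_matrix: CnvBinMatrix | None = None
    for modality in ("RNA", "ATAC"):
        mu, sd = config.depth_model[modality]
        depth = rng.lognormal(mu, sd, n_cells)
        y_frac = config.y_fraction_xy[modality]
        access = ct_access[ct_idx]
        y_expect_intact = depth * y_frac * access
        has_y = male & ~loy
        y_expect = np.where(
            has_y, y_expect_intact, config.ambient_y_rate * y_expect_intact
        )
        rest = np.maximum(depth - y_expect, 0.0)

        # distribute non-Y expectation over autosomes and X by
        # copy-number-weighted length, with the gain fold applied to the
        # gained chromosome
        chroms = list(AUTOSOMES) + ["chrX"]
        w = np.tile(
            np.array([float(lengths[c]) for c in AUTOSOMES] + [lengths["chrX"] * 0.5]),
            (n_cells, 1),
        )
        w[sex == "F", -1] = lengths["chrX"]
        gcol = chroms.index(gain_chrom)
        w[gained, gcol] *= gain_fold
        frac = w / w.sum(axis=1, keepdims=True)
        expect = frac * rest[:, None]

        counts = pd.DataFrame(0, index=cell_ids, columns=list(AUTOSOMES) + ["chrX", "chrY"], dtype=np.int64)
        counts["chrY"] = rng.poisson(y_expect)
        if modality == "ATAC" and make_bin_matrix:
            # per-bin expectation: chromosome expectation spread uniformly
            # over its retained bins; chromosome count = sum of bin counts
            bins_per_chrom = pd.Series(chrom_of_bin).groupby(chrom_of_bin).size()
            per_bin_expect = np.empty((n_cells, n_bins))
            for j, chrom in enumerate(chroms):
                if chrom == "chrX":
                    continue
                mask = chrom_of_bin == chrom
                per_bin_expect[:, mask] = (expect[:, j] / bins_per_chrom[chrom])[:, None]
            bin_counts = rng.poisson(per_bin_expect)
            bin_df = pd.DataFrame(bin_counts, index=cell_ids)
            bin_matrix = CnvBinMatrix(counts=bin_df, bins=retained_bins)
            for j, chrom in enumerate(chroms):
                if chrom == "chrX":
                    counts[chrom] = rng.poisson(expect[:, j])
                else:
                    counts[chrom] = bin_counts[:, chrom_of_bin == chrom].sum(axis=1)
        else:
            for j, chrom in enumerate(chroms):
                counts[chrom] = rng.poisson(expect[:, j])
        tables[modality] = CellCoverageTable(
            modality=modality, counts=counts, meta=meta.copy()
        )

    truth = meta.copy()
    truth["true_genotype"] = genotype
    truth["gained_chrom"] = np.where(gained, gain_chrom, "")
    truth["true_burden"] = true_burden
    truth["eta"] = eta

    return SyntheticCohort(
        tables=tables,
        bin_matrix=bin_matrix,
        truth=truth,
        genome_bins=genome_bins,
        config=config,
    )


@dataclass
class DpcrPlate:
    """One microwell digital-PCR plate: totals and positive-well counts."""

    n_wells: int = 20_000
    k_y: int = 0
    k_x: int = 0
    sample_id: str = ""
    replicate: int = 1
    batch: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.k_y <= self.n_wells and 0 <= self.k_x <= self.n_wells):
            raise ValueError("positive-well counts must lie in [0, n_wells]")


def simulate_dpcr_plate(
    copy_ratio: float,
    lambda_x: float,
    n_wells: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> DpcrPlate:
    """Simulate one microwell plate under Poisson partitioning.

    Each well receives Poisson numbers of chrX and chrY template
    molecules with means ``lambda_x`` and ``copy_ratio * lambda_x``; a
    well is positive when it received at least one molecule, so positive
    counts are Binomial(n_wells, 1 - exp(-lambda)).
    """
    if copy_ratio < 0:
        raise ValueError("copy_ratio must be >= 0")
    if lambda_x <= 0:
        raise ValueError("lambda_x must be > 0")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p_x = 1.0 - math.exp(-lambda_x)
    p_y = 1.0 - math.exp(-copy_ratio * lambda_x)
    return DpcrPlate(
        n_wells=n_wells,
        k_x=int(rng.binomial(n_wells, p_x)),
        k_y=int(rng.binomial(n_wells, p_y)),
    )
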