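"""Digital-PCR LOY quantification.

A sample is dispersed into ~20,000 microwells; each well end-point
amplifies a chrY target and a chrX reference. Two copy-ratio estimators
are provided: the raw positive-well ratio k_y / k_x (as the assay text
defines it), and the Poisson-corrected ratio lambda_y / lambda_x with
lambda = -ln(1 - k/N), which removes the nonlinearity of well occupancy
and is the default for simulation work. The LOY fraction is
1 - chrY/chrX, clamped to [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DpcrPlate, simulate_dpcr_plate

logger = logging.getLogger(__name__)


@dataclass
class CopyRatioResult:
    ratio_raw: float
    lambda_y: float
    lambda_x: float
    ratio_poisson: float
    loy_fraction: float
    estimator: str


def expected_mixture_ratio(male_mass_fraction: float) -> float:
    """Expected chrY:chrX copy ratio of a male:female DNA mixture.

    Per genome-equivalent of mass, male DNA contributes one Y and one X
    while female DNA contributes two X copies, so a mixture with male
    mass fraction m has ratio m / (2 - m); a 50:50 mixture gives 1 Y per
    3 X, ratio 1/3.
    """
    m = float(male_mass_fraction)
    if not (0.0 <= m <= 1.0):
        raise ValueError("male mass fraction must lie in [0, 1]")
    return m / (2.0 - m)


def copy_ratio(plate: DpcrPlate, estimator: str = "poisson") -> CopyRatioResult:
    """Copy ratio of one plate; both estimators are always recorded."""
    if estimator not in ("raw", "poisson"):
        raise ValueError("estimator must be 'raw' or 'poisson'")
    if plate.k_x < 1:
        raise ValueError("reference failure: no chrX-positive wells")
    ratio_raw = plate.k_y / plate.k_x
    if plate.k_x >= plate.n_wells or plate.k_y >= plate.n_wells:
        if estimator == "poisson":
            raise ValueError("occupancy too high: saturated plate")
        lam_y = lam_x = ratio_poisson = math.nan
    else:
        lam_y = -math.log1p(-plate.k_y / plate.n_wells)
        lam_x = -math.log1p(-plate.k_x / plate.n_wells)
        ratio_poisson = lam_y / lam_x
    ratio = ratio_raw if estimator == "raw" else ratio_poisson
    return CopyRatioResult(
        ratio_raw=ratio_raw,
        lambda_y=lam_y,
        lambda_x=lam_x,
        ratio_poisson=ratio_poisson,
        loy_fraction=loy_fraction(ratio),
        estimator=estimator,
    )


def loy_fraction(ratio: float) -> float:
    """LOY fraction 1 - chrY/chrX, clamped to [0, 1]."""
    if ratio < 0:
        raise ValueError("copy ratio must be >= 0")
    if ratio > 1.0:
        logger.warning("copy ratio %.4f > 1; LOY fraction clamped to 0", ratio)
        return 0.0
    return 1.0 - ratio


def mixing_curve_check(
    mixtures,
    lambda_x: float = 0.5,
    n_wells: int = 20_000,
    replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated male:female mixing series with estimator diagnostics.

    For each male mass fraction m, ``replicates`` plates are simulated at
    the expected ratio m/(2-m), the Poisson estimator is applied per
    plate, and the mean measured ratio, relative error vs expectation and
    CV across replicates are reported.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for m in mixtures:
        expected = expected_mixture_ratio(m)
        measured = []
        for _ in range(replicates):
            plate = simulate_dpcr_plate(expected, lambda_x, n_wells, seed=rng)
            if plate.k_y == 0:
                measured.append(0.0)
            else:
                lam_y = -math.log1p(-plate.k_y / plate.n_wells)
                lam_x = -math.log1p(-plate.k_x / plate.n_wells)
                measured.append(lam_y / lam_x)
        measured = np.asarray(measured)
        mean = float(measured.mean())
        rel_err = abs(mean - expected) / expected if expected > 0 else abs(mean)
        cv = float(measured.std(ddof=1) / mean) if mean > 0 else math.nan
        rows.append((m, expected, mean, rel_err, cv))
    return pd.DataFrame(
        rows, columns=["m", "expected_ratio", "mean_ratio", "rel_error", "cv"]
    )


def read_plates(path) -> list[DpcrPlate]:
    """Read plates from CSV: sample_id, replicate, batch, n_wells, k_y, k_x."""
    df = pd.read_csv(path)
    return [
        DpcrPlate(
            n_wells=int(r.n_wells), k_y=int(r.k_y), k_x=int(r.k_x),
            sample_id=str(r.sample_id), replicate=int(r.replicate),
            batch=int(r.batch),
        )
        for r in df.itertuples()
    ]


def summarize_plates(plates: list[DpcrPlate]) -> pd.DataFrame:
    """Per-sample summary over replicate plates (both estimators)."""
    rows = []
    for p in plates:
        res = copy_ratio(p, "poisson")
        rows.append(
            (p.sample_id, p.replicate, p.batch, res.ratio_raw,
             res.ratio_poisson, res.loy_fraction)
        )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "replicate", "batch", "ratio_raw",
                 "ratio_poisson", "loy_fraction"],
    )
    out = df.groupby("sample_id").agg(
        n_plates=("ratio_poisson", "size"),
        ratio_raw=("ratio_raw", "mean"),
        ratio_poisson=("ratio_poisson", "mean"),
        loy_fraction=("loy_fraction", "mean"),
        cv=("ratio_poisson", lambda x: x.std(ddof=1) / x.mean()),
    )
    return out.reset_index()
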