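"""Charge-balanced synthetic groundwater cohorts.

The study's raw per-sample table is unpublished; only per-parameter
min/max/mean/SD summaries are available.  This module draws cohorts whose
marginals are moment-matched to those summaries (truncated lognormal for
concentrations, truncated normal for pH), couples the salinity block through
a Gaussian copula, and repairs each sample's ion balance so |CBE| stays
within tolerance — giving every downstream stage a realistic, fully
reproducible input.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import hydrochem
from .data_model import ION_NAMES, PTE_NAMES, SampleTable, WaterSample
from .monte_carlo import (
    DistributionSpec,
    fit_truncated_lognormal,
    fit_truncated_normal,
)

__all__ = [
    "ParamStats",
    "TABLE2_STATS",
    "SALINITY_BLOCK",
    "GeneratorConfig",
    "SyntheticCohort",
    "sample_parameter",
    "generate_cohort",
    "verify_stats",
]


@dataclass(frozen=True)
class ParamStats:
    """Target summary statistics for one parameter."""

    min: float
    max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValueError("need min <= mean <= max")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


#: Published cohort summaries (min, max, mean, SD) for the 69-sample study.
TABLE2_STATS: dict[str, ParamStats] = {
    "pH": ParamStats(6.5, 8.39, 7.71, 0.3),
    "EC": ParamStats(296.0, 8504.0, 1755.0, 1458.4),
    "TDS": ParamStats(225.0, 4930.0, 982.0, 800.7),
    "TH": ParamStats(50.0, 2288.0, 345.0, 397.2),
    "Cl": ParamStats(13.0, 2799.0, 258.0, 432.3),
    "SO4": ParamStats(0.05, 985.0, 141.0, 156.9),
    "HCO3": ParamStats(65.0, 851.0, 387.5, 183.6),
    "NO3": ParamStats(0.001, 158.0, 7.39, 19.4),
    "Ca": ParamStats(2.0, 697.0, 83.0, 101.5),
    "Mg": ParamStats(8.06, 133.0, 52.0, 21.1),
    "Na": ParamStats(14.0, 1600.0, 209.0, 220.3),
    "K": ParamStats(1.0, 74.0, 15.0, 16.1),
    "Fe": ParamStats(0.0002, 0.62, 0.152, 0.160),
    "Mn": ParamStats(0.002, 1.71, 0.422, 0.421),
    "Cu": ParamStats(0.002, 0.16, 0.049, 0.038),
    "Zn": ParamStats(0.003, 0.88, 0.081, 0.113),
}

#: Parameters coupled through the copula (salinity / water-rock interaction
#: block).  NO3 and HCO3 are left independent: their spatial pattern is
#: anthropogenic, not salinity-driven.
SALINITY_BLOCK: tuple[str, ...] = ("TDS", "EC", "TH", "Na", "K", "Ca", "Cl", "SO4")


@dataclass
class GeneratorConfig:
    n_samples: int = 69
    seed: int = 0
    targets: dict[str, ParamStats] = field(
        default_factory=lambda: dict(TABLE2_STATS)
    )
    correlation_groups: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: [(SALINITY_BLOCK, 0.8)]
    )
    cbe_tolerance: float = 5.0
    emit_coordinates: bool = True

    def __post_init__(self) -> None:
        for params, rho in self.correlation_groups:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation target {rho} outside [-1, 1]")

    def digest(self) -> str:
        payload = {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "targets": {k: vars(v) for k, v in sorted(self.targets.items())},
            "correlation_groups": [
                [sorted(p), rho] for p, rho in self.correlation_groups
            ],
            "cbe_tolerance": self.cbe_tolerance,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticCohort:
    table: SampleTable
    seed: int
    config_hash: str
    achieved: pd.DataFrame
    repair_factors: pd.DataFrame


def _spec_for(name: str, st: ParamStats) -> DistributionSpec:
    if st.sd == 0 or st.min == st.max:
        return DistributionSpec(name=name, family="point",
                                params={"value": st.mean})
    if name == "pH":
        return fit_truncated_normal(st.mean, st.sd, st.min, st.max, name=name)
    return fit_truncated_lognormal(st.mean, st.sd, st.min, st.max, name=name)


def sample_parameter(
    stats: ParamStats,
    family: str,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Draw n values moment-matched to *stats* and confined to [min, max].

    ``family`` is ``"lognormal"`` (concentrations) or ``"normal"`` (pH-like);
    infeasible stats (sd unattainable within the bounds) raise.
    """
    if stats.sd == 0 or stats.min == stats.max:
        return np.full(n, stats.mean)
    if family == "normal":
        spec = fit_truncated_normal(stats.mean, stats.sd, stats.min, stats.max)
    elif family == "lognormal":
        spec = fit_truncated_lognormal(stats.mean, stats.sd, stats.min, stats.max)
    else:
        raise ValueError("family must be 'normal' or 'lognormal'")
    return spec.sample(n, rng)


def _substream(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"synthetic:{name}".encode()).digest()[:8]
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    )


_CATION_NAMES = ("Ca", "Mg", "Na", "K")
_ANION_NAMES = ("Cl", "SO4", "HCO3", "NO3")
_REPAIR_FIRST = ("Cl", "HCO3")  # largest anion pools, adjusted before cations


def _repair_balance(
    ions: dict[str, float], tolerance: float, max_iter: int = 10
) -> tuple[dict[str, float], float, float]:
    """Scale ions until |CBE| <= tolerance; returns (ions, f_anion, f_cation).

    Cl and HCO3 are scaled first; cations are only touched when the anion
    side cannot absorb the remaining imbalance.  The adjusted sample lands
    just inside the tolerance band (minimal perturbation).
    """
    eq = hydrochem.EQUIVALENT_WEIGHTS
    ions = dict(ions)
    f_anion = f_cation = 1.0
    target = 0.9 * tolerance / 100.0
    for _ in range(max_iter):
        cat = sum(ions[i] / eq[i] for i in _CATION_NAMES)
        an = sum(ions[i] / eq[i] for i in _ANION_NAMES)
        cbe = (cat - an) / (cat + an)
        if abs(cbe) <= tolerance / 100.0:
            return ions, f_anion, f_cation
        t = math.copysign(target, cbe)
        desired_an = cat * (1.0 - t) / (1.0 + t)
        pool = sum(ions[i] / eq[i] for i in _REPAIR_FIRST)
        f = 1.0 + (desired_an - an) / pool
        if f < 0.1:
            f = 0.1
        for ion in _REPAIR_FIRST:
            ions[ion] *= f
        f_anion *= f
        if f == 0.1:
            # anion floor hit: raise the cation side instead
            an = sum(ions[i] / eq[i] for i in _ANION_NAMES)
            g = an * (1.0 + t) / (cat * (1.0 - t))
            for ion in _CATION_NAMES:
                ions[ion] *= g
            f_cation *= g
    cat = sum(ions[i] / eq[i] for i in _CATION_NAMES)
    an = sum(ions[i] / eq[i] for i in _ANION_NAMES)
    cbe = 100.0 * (cat - an) / (cat + an)
    raise RuntimeError(f"charge balance unattainable: residual CBE {cbe:.2f}%")


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Draw a fully validated cohort.

    Marginals come from per-parameter named substreams (so output is
    invariant to target ordering); the salinity block is coupled by mixing
    those same standard-normal scores through the Cholesky factor of the
    target equicorrelation matrix before the quantile transform.
    """
    config = config or GeneratorConfig()
    n = config.n_samples
    names = sorted(config.targets)
    specs = {name: _spec_for(name, config.targets[name]) for name in names}

    z = {
        name: _substream(config.seed, name).standard_normal(n)
        for name in names
    }
    for params, rho in config.correlation_groups:
        block = [p for p in params if p in z]
        k = len(block)
        if k < 2 or rho == 0.0:
            continue
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
        z0 = np.column_stack([z[p] for p in block])
        mixed = z0 @ chol.T
        for j, p in enumerate(block):
            z[p] = mixed[:, j]

    values = {
        name: specs[name].ppf(sps.norm.cdf(z[name])) for name in names
    }

    coords_rng = _substream(config.seed, "coordinates")
    eastings = coords_rng.uniform(0.0, 100_000.0, size=n)
    northings = coords_rng.uniform(0.0, 100_000.0, size=n)

    samples = []
    repair_rows = []
    for i in range(n):
        ions = {ion: float(values[ion][i]) for ion in ION_NAMES if ion in values}
        ions["CO3"] = 0.0
        ions, f_anion, f_cation = _repair_balance(ions, config.cbe_tolerance)
        repair_rows.append({"f_anion": f_anion, "f_cation": f_cation})
        samples.append(
            WaterSample(
                sample_id=f"S{i + 1:02d}",
                ph=float(values["pH"][i]),
                ec=float(values["EC"][i]),
                tds=float(values["TDS"][i]),
                th=float(values["TH"][i]),
                ions=ions,
                ptes={m: float(values[m][i]) for m in PTE_NAMES},
                easting=float(eastings[i]) if config.emit_coordinates else None,
                northing=float(northings[i]) if config.emit_coordinates else None,
            )
        )
    table = SampleTable(samples)
    matrix = table.matrix(names)
    achieved = pd.DataFrame(
        {
            "min": matrix.min(), "max": matrix.max(),
            "mean": matrix.mean(), "sd": matrix.std(ddof=1),
        }
    )
    return SyntheticCohort(
        table=table,
        seed=config.seed,
        config_hash=config.digest(),
        achieved=achieved,
        repair_factors=pd.DataFrame(
            repair_rows, index=[s.sample_id for s in samples]
        ),
    )


def verify_stats(
    cohort: SyntheticCohort,
    config: GeneratorConfig,
    mean_tol_sds: float = 5.0,
    sd_tol_sds: float = 6.0,
) -> pd.DataFrame:
    """Compare achieved cohort statistics to the configured targets.

    Mean tolerance scales as ``mean_tol_sds * sd / sqrt(n)``; the SD
    tolerance uses the asymptotic standard error ``sd / sqrt(2(n-1))``
    inflated by ``sd_tol_sds`` (skewed marginals).  The ion-balance repair
    deliberately rescales Cl and HCO3 (and, rarely, the cations), so those
    columns are exempt from the strict [min, max] bound check and get a wider
    mean/sd band instead.  Returns one row per parameter with a ``passed``
    flag.
    """
    n = cohort.table.m
    adjusted = set(_REPAIR_FIRST)
    if (cohort.repair_factors["f_cation"] != 1.0).any():
        adjusted |= set(_CATION_NAMES)
    rows = []
    for name, target in sorted(config.targets.items()):
        if name not in cohort.achieved.index:
            continue
        ach = cohort.achieved.loc[name]
        mean_tol = mean_tol_sds * target.sd / math.sqrt(n) + 1e-9
        # the n-1 SD estimator's own SE grows with tail weight; inflate the
        # normal-theory SE by the marginal's coefficient of variation
        cv = target.sd / target.mean if target.mean else 0.0
        inflate = max(1.0, cv)
        sd_tol = sd_tol_sds * inflate * target.sd / math.sqrt(2 * (n - 1)) + 1e-9
        ok_bounds = name in adjusted or (
            ach["min"] >= target.min - 1e-12
            and ach["max"] <= target.max + 1e-12
        )
        wide = 0.5 * target.sd if name in adjusted else 0.0
        ok_mean = abs(ach["mean"] - target.mean) <= max(mean_tol, wide)
        ok_sd = abs(ach["sd"] - target.sd) <= max(sd_tol, wide)
        rows.append(
            {
                "parameter": name,
                "achieved_min": ach["min"], "achieved_max": ach["max"],
                "achieved_mean": ach["mean"], "achieved_sd": ach["sd"],
                "target_mean": target.mean, "target_sd": target.sd,
                "bounds_ok": ok_bounds, "mean_ok": ok_mean, "sd_ok": ok_sd,
                "passed": bool(ok_bounds and ok_mean and ok_sd),
            }
        )
    columns = ["parameter", "achieved_min", "achieved_max", "achieved_mean",
               "achieved_sd", "target_mean", "target_sd", "bounds_ok",
               "mean_ok", "sd_ok", "passed"]
    return pd.DataFrame(rows, columns=columns).set_index("parameter")
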