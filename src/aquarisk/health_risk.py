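"""Deterministic USEPA-style non-carcinogenic risk chain.

Chronic daily intake (CDI) for the oral and dermal routes, hazard quotients
(HQ = CDI / RfD) and hazard indices (HI) for adult and child cohorts.  All
kernels accept scalars or numpy arrays so the Monte Carlo stage can reuse
them unchanged.

Averaging time follows the non-carcinogenic convention AT = ED x 365 days
(adult 25,550 d; child 2,190 d), which back-reproduces the published HQ
range endpoints to 2 significant figures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .pollution_indices import ToxicityTable

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import SampleTable

__all__ = [
    "ExposureProfile",
    "ADULT",
    "CHILD",
    "cdi_oral",
    "cdi_dermal",
    "hazard_quotient",
    "rfd_dermal",
    "hazard_index",
    "assess",
    "cohort_summary",
]


@dataclass(frozen=True)
class ExposureProfile:
    """Cohort-specific exposure constants.

    ir L/day; ed years; ef days/year; et h/day; sa cm^2; cf L/cm^3; bw kg;
    at days (non-carcinogenic default: ed * 365).
    """

    cohort: str
    ir: float
    ed: float
    ef: float
    et: float
    sa: float
    cf: float
    bw: float
    at: float

    def __post_init__(self) -> None:
        for name in ("ir", "ed", "ef", "et", "sa", "cf", "bw", "at"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **fields: float) -> "ExposureProfile":
        return dataclasses.replace(self, **fields)


ADULT = ExposureProfile(cohort="adult", ir=2.2, ed=70.0, ef=350.0, et=0.58,
                        sa=18000.0, cf=1e-3, bw=70.0, at=70.0 * 365.0)
CHILD = ExposureProfile(cohort="child", ir=1.8, ed=6.0, ef=350.0, et=1.0,
                        sa=6600.0, cf=1e-3, bw=15.0, at=6.0 * 365.0)


def cdi_oral(c, profile: ExposureProfile, *, ir=None, ed=None, bw=None, at=None):
    """Ingestion chronic daily intake: C * EF * IR * ED / (AT * BW) in mg/kg/day.

    Keyword overrides allow per-draw values in Monte Carlo sampling.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    ir = profile.ir if ir is None else ir
    ed = profile.ed if ed is None else ed
    bw = profile.bw if bw is None else bw
    at = profile.at if at is None else at
    out = c * profile.ef * ir * ed / (at * bw)
    return float(out) if out.ndim == 0 else out


def cdi_dermal(c, profile: ExposureProfile, kp,
               *, ed=None, sa=None, bw=None, at=None):
    """Dermal intake: C * ET * EF * Kp * SA * CF * ED / (BW * AT) in mg/kg/day."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(np.asarray(kp) <= 0):
        raise ValueError("kp must be positive")
    ed = profile.ed if ed is None else ed
    sa = profile.sa if sa is None else sa
    bw = profile.bw if bw is None else bw
    at = profile.at if at is None else at
    out = c * profile.et * profile.ef * kp * sa * profile.cf * ed / (bw * at)
    return float(out) if out.ndim == 0 else out


def hazard_quotient(cdi, rfd: float):
    """HQ = CDI / RfD; above 1 flags potential non-carcinogenic risk."""
    if rfd <= 0:
        raise ValueError("rfd must be positive")
    out = np.asarray(cdi, dtype=float) / rfd
    return float(out) if out.ndim == 0 else out


def rfd_dermal(rfd_oral: float, abs_gi: float) -> float:
    """Dermal reference dose: oral RfD scaled by GI absorption fraction."""
    if not 0.0 < abs_gi <= 1.0:
        raise ValueError(f"abs_gi must be in (0, 1], got {abs_gi}")
    return rfd_oral * abs_gi


def hazard_index(hq_by_metal: Mapping[str, float]) -> float:
    """Route-wise hazard index: sum of the per-metal hazard quotients."""
    if not hq_by_metal:
        raise ValueError("need at least one hazard quotient")
    return float(sum(hq_by_metal.values()))


def assess(
    samples: "SampleTable",
    toxicity: ToxicityTable | None = None,
    profiles: Sequence[ExposureProfile] = (ADULT, CHILD),
    metals: Sequence[str] = ("Fe", "Mn", "Cu", "Zn"),
) -> pd.DataFrame:
    """Per-sample deterministic risk table.

    One row per sample x cohort carrying CDI and HQ per metal and route,
    the per-metal oral+dermal totals, and the route-wise hazard indices
    with their > 1 flags.
    """
    toxicity = toxicity or ToxicityTable.default()
    rows = []
    for sample in samples:
        for profile in profiles:
            row: dict[str, object] = {
                "sample_id": sample.sample_id,
                "cohort": profile.cohort,
            }
            hq_oral_map, hq_dermal_map = {}, {}
            for metal in metals:
                constants = toxicity[metal]
                c = sample.ptes[metal]
                cdi_o = cdi_oral(c, profile)
                cdi_d = cdi_dermal(c, profile, constants.kp)
                hq_o = hazard_quotient(cdi_o, constants.rfd_oral)
                hq_d = hazard_quotient(cdi_d, constants.rfd_dermal)
                hq_oral_map[metal] = hq_o
                hq_dermal_map[metal] = hq_d
                row[f"cdi_oral_{metal}"] = cdi_o
                row[f"cdi_dermal_{metal}"] = cdi_d
                row[f"hq_oral_{metal}"] = hq_o
                row[f"hq_dermal_{metal}"] = hq_d
                row[f"hi_{metal}"] = hq_o + hq_d
            row["hi_oral"] = hazard_index(hq_oral_map)
            row["hi_dermal"] = hazard_index(hq_dermal_map)
            row["hi_oral_flag"] = row["hi_oral"] > 1.0
            row["hi_dermal_flag"] = row["hi_dermal"] > 1.0
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(results: pd.DataFrame, metals: Sequence[str] = ("Fe", "Mn", "Cu", "Zn")) -> pd.DataFrame:
    """Min/max/mean and strict HQ > 1 exceedance share per metal/route/cohort."""
    if results.empty:
        raise ValueError("no results to summarise")
    rows = []
    for cohort, group in results.groupby("cohort"):
        for route in ("oral", "dermal"):
            for metal in metals:
                col = group[f"hq_{route}_{metal}"]
                rows.append(
                    {
                        "cohort": cohort,
                        "route": route,
                        "metal": metal,
                        "min": col.min(),
                        "max": col.max(),
                        "mean": col.mean(),
                        "exceedance_percent": 100.0 * (col > 1.0).mean(),
                    }
                )
            hi = group[f"hi_{route}"]
            rows.append(
                {
                    "cohort": cohort,
                    "route": route,
                    "metal": "HI",
                    "min": hi.min(),
                    "max": hi.max(),
                    "mean": hi.mean(),
                    "exceedance_percent": 100.0 * (hi > 1.0).mean(),
                }
            )
    return pd.DataFrame(rows)
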