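"""Ion-balance QA, chloro-alkaline indices, facies/origin classification.

All equivalent arithmetic is done in meq/L with a pinned equivalent-weight
table so results are bit-reproducible.  Undefined quantities (zero
denominators) are returned as NaN markers rather than raised, except where a
computation is meaningless for the whole sample (all-zero composition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import SampleTable, WaterSample

__all__ = [
    "EQUIVALENT_WEIGHTS",
    "MeqComposition",
    "FaciesResult",
    "QAStats",
    "to_meq",
    "charge_balance_error",
    "cai_indices",
    "piper_facies",
    "gibbs_point",
    "sulin_class",
    "ionic_ratio_table",
    "qa_stats",
    "hydrochem_panel",
]

#: Equivalent weights (g/eq) = molar mass / |charge|.
EQUIVALENT_WEIGHTS: dict[str, float] = {
    "Ca": 20.04,
    "Mg": 12.15,
    "Na": 22.99,
    "K": 39.10,
    "Cl": 35.45,
    "SO4": 48.03,
    "HCO3": 61.02,
    "CO3": 30.00,
    "NO3": 62.00,
}

_CATIONS = ("Ca", "Mg", "Na", "K")
_ANIONS = ("Cl", "SO4", "HCO3", "CO3", "NO3")


@dataclass(frozen=True)
class MeqComposition:
    """Per-ion concentrations in meq/L plus the two side sums."""

    meq: dict[str, float]
    cation_sum: float
    anion_sum: float

    def __getitem__(self, ion: str) -> float:
        return self.meq.get(ion, 0.0)


@dataclass(frozen=True)
class FaciesResult:
    facies_label: str
    gibbs_zone: str
    sulin_class: str
    cai1: float
    cai2: float


@dataclass(frozen=True)
class QAStats:
    lod: float
    loq: float
    rsd_percent: float


def to_meq(composition: Mapping[str, float]) -> MeqComposition:
    """Convert a mg/L ion map to meq/L; unknown ion names are an error."""
    meq = {}
    for ion, mg_l in composition.items():
        if ion not in EQUIVALENT_WEIGHTS:
            raise KeyError(f"unknown ion {ion!r}; known: {sorted(EQUIVALENT_WEIGHTS)}")
        meq[ion] = mg_l / EQUIVALENT_WEIGHTS[ion]
    cation_sum = sum(meq.get(i, 0.0) for i in _CATIONS)
    anion_sum = sum(meq.get(i, 0.0) for i in _ANIONS)
    return MeqComposition(meq=meq, cation_sum=cation_sum, anion_sum=anion_sum)


def charge_balance_error(sample: "WaterSample") -> float:
    """Signed charge-balance error in percent.

    Positive when cations exceed anions; |CBE| <= 5 marks the analysis as
    acceptable.  An all-zero composition is undefined and raises.
    """
    comp = to_meq(sample.ions)
    total = comp.cation_sum + comp.anion_sum
    if total == 0:
        raise ValueError(f"{sample.sample_id}: all-zero composition, CBE undefined")
    return (comp.cation_sum - comp.anion_sum) / total * 100.0


def cai_indices(sample: "WaterSample", numerator: str = "schoeller") -> tuple[float, float]:
    """Chloro-alkaline indices (index 1, index 2) in meq/L terms.

    ``numerator='schoeller'`` (default) uses Cl - (Na + K); ``'as_printed'``
    uses Cl - (Na - Ca), preserving the source's typographic variant.
    Negative values indicate direct ion exchange.  A zero denominator yields
    NaN for that index only.
    """
    comp = to_meq(sample.ions)
    cl = comp["Cl"]
    if numerator == "schoeller":
        num = cl - (comp["Na"] + comp["K"])
    elif numerator == "as_printed":
        num = cl - (comp["Na"] - comp["Ca"])
    else:
        raise ValueError("numerator must be 'schoeller' or 'as_printed'")
    denom2 = comp["SO4"] + comp["HCO3"] + comp["CO3"] + comp["NO3"]
    cai1 = num / cl if cl > 0 else math.nan
    cai2 = num / denom2 if denom2 > 0 else math.nan
    return cai1, cai2


def _percentages(comp: MeqComposition) -> tuple[dict[str, float], dict[str, float]]:
    if comp.cation_sum <= 0 or comp.anion_sum <= 0:
        raise ValueError("zero ion sums: facies undefined")
    cat = {i: 100.0 * comp[i] / comp.cation_sum for i in _CATIONS}
    an = {i: 100.0 * comp[i] / comp.anion_sum for i in _ANIONS}
    return cat, an


def piper_facies(sample: "WaterSample") -> str:
    """Facies label from cation/anion meq%% dominance.

    A single ion is clearly dominant at > 50%% with the runner-up below 25%%;
    Ca+Mg (resp. Cl+SO4) are grouped above 66%% of their side; otherwise the
    two largest members form a mixed label.  Labels outside the recognised
    set collapse to ``"other"``.
    """
    cat, an = _percentages(to_meq(sample.ions))

    # cation side: clear Na dominance, grouped/mixed alkaline earths, or a
    # Na-Ca mix; anything else (e.g. K-dominated, exact ties) is "other"
    ordered = sorted(cat.items(), key=lambda kv: -kv[1])
    (top, top_pct), (second, second_pct) = ordered[0], ordered[1]
    if top == "Na" and top_pct > 50.0 and second_pct < 25.0:
        cation = "Na"
    elif cat["Ca"] + cat["Mg"] > 66.0 or {top, second} == {"Ca", "Mg"}:
        cation = "Ca-Mg"
    elif {top, second} == {"Na", "Ca"} and top_pct > second_pct:
        cation = "Na-Ca"
    else:
        # K-dominated or exactly tied mixes have no recognised facies
        cation = "other"

    # anion side: carbonate alkalinity counts with HCO3; mixed waters fall to
    # whichever of HCO3 vs Cl+SO4 dominates
    alk = an["HCO3"] + an["CO3"]
    if an["Cl"] > 50.0 and max(alk, an["SO4"], an["NO3"]) < 25.0:
        anion = "Cl"
    elif alk > 50.0 and max(an["Cl"], an["SO4"], an["NO3"]) < 25.0:
        anion = "HCO3"
    elif an["Cl"] + an["SO4"] > 66.0:
        anion = "Cl/SO4"
    elif alk == an["Cl"] + an["SO4"]:
        anion = "other"
    else:
        anion = "HCO3" if alk > an["Cl"] + an["SO4"] else "Cl/SO4"

    mapping = {
        ("Na", "Cl"): "Na-Cl",
        ("Na", "Cl/SO4"): "Na-Cl",
        ("Ca-Mg", "HCO3"): "Ca-Mg-HCO3",
        ("Ca-Mg", "Cl"): "Ca-Mg-Cl/SO4",
        ("Ca-Mg", "Cl/SO4"): "Ca-Mg-Cl/SO4",
        ("Na-Ca", "HCO3"): "Na-Ca-HCO3",
        ("Na-Ca", "Cl"): "Na-Cl",
        ("Na-Ca", "Cl/SO4"): "other",
        ("Na", "HCO3"): "Na-HCO3",
    }
    return mapping.get((cation, anion), "other")


_GIBBS_BOXES = {
    # zone -> (tds_lo, tds_hi, ratio_lo, ratio_hi); digitised boomerang
    "rock-weathering": (70.0, 1000.0, 0.0, 0.75),
    "evaporation/crystallization": (1000.0, 100000.0, 0.5, 1.0),
    "precipitation": (1.0, 70.0, 0.5, 1.0),
}


def gibbs_point(sample: "WaterSample") -> tuple[float, float, str]:
    """(Na/(Na+Ca), Cl/(Cl+HCO3), zone) in meq/L; NaN ratio when undefined."""
    comp = to_meq(sample.ions)
    na_den = comp["Na"] + comp["Ca"]
    cl_den = comp["Cl"] + comp["HCO3"]
    na_ratio = comp["Na"] / na_den if na_den > 0 else math.nan
    cl_ratio = comp["Cl"] / cl_den if cl_den > 0 else math.nan

    ratios = [r for r in (na_ratio, cl_ratio) if not math.isnan(r)]
    if not ratios or sample.tds <= 0:
        return na_ratio, cl_ratio, "undefined"
    ratio = float(np.mean(ratios))
    # normalised coordinates: ratio on [0,1], log10(TDS) on [1,5]
    y = (math.log10(sample.tds) - 1.0) / 4.0

    def distance(box: tuple[float, float, float, float]) -> float:
        tds_lo, tds_hi, r_lo, r_hi = box
        y_lo = (math.log10(tds_lo) - 1.0) / 4.0
        y_hi = (math.log10(tds_hi) - 1.0) / 4.0
        dy = max(y_lo - y, 0.0, y - y_hi)
        dx = max(r_lo - ratio, 0.0, ratio - r_hi)
        return math.hypot(dx, dy)

    return na_ratio, cl_ratio, min(_GIBBS_BOXES, key=lambda z: distance(_GIBBS_BOXES[z]))


def sulin_class(sample: "WaterSample") -> str:
    """Genetic water-origin class from equivalent ratios.

    Na/Cl >= 1: excess Na over SO4 > 1 -> deep meteoric (Na2SO4 type), else
    shallow meteoric (NaHCO3 type).  Na/Cl < 1: (Cl-Na)/Mg < 1 -> old marine
    (MgCl2 type), else recent marine (CaCl2 type).
    """
    comp = to_meq(sample.ions)
    na, cl, mg, so4 = comp["Na"], comp["Cl"], comp["Mg"], comp["SO4"]
    if cl == 0:
        return "shallow meteoric" if na > 0 else "undefined"
    if na / cl >= 1.0:
        if so4 > 0 and (na - cl) / so4 > 1.0:
            return "deep meteoric"
        return "shallow meteoric"
    if mg == 0:
        return "undefined"
    return "old marine" if (cl - na) / mg < 1.0 else "recent marine"


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def ionic_ratio_table(samples: "SampleTable") -> pd.DataFrame:
    """Per-sample panel of diagnostic meq ratios with 1:1-line side flags."""
    rows = []
    for s in samples:
        c = to_meq(s.ions)
        ratios = {
            "Na/Cl": _ratio(c["Na"], c["Cl"]),
            "Ca/SO4": _ratio(c["Ca"], c["SO4"]),
            "Ca/Mg": _ratio(c["Ca"], c["Mg"]),
            "Ca/HCO3": _ratio(c["Ca"], c["HCO3"]),
            "(Ca+Mg)/(HCO3+SO4)": _ratio(c["Ca"] + c["Mg"], c["HCO3"] + c["SO4"]),
            "Cl/Na": _ratio(c["Cl"], c["Na"]),
            "NO3/Na": _ratio(c["NO3"], c["Na"]),
        }
        row: dict[str, object] = {"sample_id": s.sample_id, **ratios}
        for name, value in ratios.items():
            if math.isnan(value):
                flag = "undefined"
            elif value == 1.0:
                flag = "on 1:1 line"
            elif value > 1.0:
                flag = "numerator-excess side"
            else:
                flag = "denominator-excess side"
            row[f"{name} side"] = flag
        mg_na = _ratio(c["Mg"], c["Na"])
        ca_na = _ratio(c["Ca"], c["Na"])
        row["log10(Mg/Na)"] = math.log10(mg_na) if mg_na and mg_na > 0 else math.nan
        row["log10(Ca/Na)"] = math.log10(ca_na) if ca_na and ca_na > 0 else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def qa_stats(blank_sd: float, replicate_values: list[float] | None = None) -> QAStats:
    """Detection/quantification limits and replicate precision.

    lod = 3 * blank SD, loq = 10 * blank SD; %RSD uses the n-1 sample SD of
    the replicates.  RSD is NaN without replicates and raises on zero mean.
    """
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    rsd = math.nan
    if replicate_values is not None:
        if len(replicate_values) < 2:
            raise ValueError("need >= 2 replicates for RSD")
        mean = float(np.mean(replicate_values))
        if mean == 0:
            raise ValueError("RSD undefined: replicate mean is 0")
        rsd = float(np.std(replicate_values, ddof=1)) / mean * 100.0
    return QAStats(lod=3.0 * blank_sd, loq=10.0 * blank_sd, rsd_percent=rsd)


def hydrochem_panel(samples: "SampleTable", cai_numerator: str = "schoeller") -> pd.DataFrame:
    """Full per-sample hydrochemical screening table."""
    rows = []
    for s in samples:
        cbe = charge_balance_error(s)
        cai1, cai2 = cai_indices(s, numerator=cai_numerator)
        na_ratio, cl_ratio, zone = gibbs_point(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "cbe_percent": cbe,
                "cbe_acceptable": abs(cbe) <= 5.0,
                "cai1": cai1,
                "cai2": cai2,
                "ion_exchange": "direct" if cai1 < 0 else "reverse",
                "facies": piper_facies(s),
                "gibbs_na_ratio": na_ratio,
                "gibbs_cl_ratio": cl_ratio,
                "gibbs_zone": zone,
                "sulin_class": sulin_class(s),
            }
        )
    panel = pd.DataFrame(rows).set_index("sample_id")
    return panel.join(ionic_ratio_table(samples))
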