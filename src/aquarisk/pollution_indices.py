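"""Heavy-metal pollution index (HPI) and ecological risk index (RI)."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import pandas as pd

from .data_model import HPI_SCHEME, RI_SCHEME, PTE_NAMES

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import SampleTable, WaterSample

__all__ = [
    "MetalConstants",
    "ToxicityTable",
    "PollutionResult",
    "hpi",
    "classify_hpi",
    "ecological_risk",
    "classify_ri",
    "pollution_table",
]

#: Default HPI metal set (the index targets Fe and Mn).
HPI_METALS: tuple[str, ...] = ("Fe", "Mn")


@dataclass(frozen=True)
class MetalConstants:
    """Per-metal standards and toxicity constants.

    si: drinking standard (mg/L) used by HPI; tr: toxic response factor;
    c_bg: site background (mg/L, required for RI, no default); rfd_oral /
    rfd_dermal: reference doses (mg/kg/day); abs_gi: gastrointestinal
    absorption fraction (rfd_dermal = rfd_oral * abs_gi); kp: dermal
    permeability (cm/h).
    """

    si: float
    tr: float
    rfd_oral: float
    abs_gi: float
    kp: float
    c_bg: float | None = None

    @property
    def rfd_dermal(self) -> float:
        return self.rfd_oral * self.abs_gi


_DEFAULTS: dict[str, MetalConstants] = {
    "Fe": MetalConstants(si=0.3, tr=1.0, rfd_oral=0.7, abs_gi=0.2, kp=0.001),
    "Mn": MetalConstants(si=0.1, tr=1.0, rfd_oral=0.024, abs_gi=0.04, kp=0.001),
    "Cu": MetalConstants(si=2.0, tr=5.0, rfd_oral=0.04, abs_gi=0.3, kp=0.001),
    "Zn": MetalConstants(si=3.0, tr=1.0, rfd_oral=0.3, abs_gi=0.2, kp=6e-4),
}


class ToxicityTable:
    """Lookup of :class:`MetalConstants` per metal."""

    def __init__(self, entries: Mapping[str, MetalConstants]):
        self._entries = dict(entries)

    @classmethod
    def default(cls) -> "ToxicityTable":
        return cls(_DEFAULTS)

    def __getitem__(self, metal: str) -> MetalConstants:
        try:
            return self._entries[metal]
        except KeyError:
            raise KeyError(
                f"no constants for metal {metal!r}; known: {sorted(self._entries)}"
            ) from None

    def __contains__(self, metal: str) -> bool:
        return metal in self._entries

    def metals(self) -> list[str]:
        return list(self._entries)

    def with_overrides(self, metal: str, **fields: float) -> "ToxicityTable":
        """Return a copy with some constants of *metal* replaced.

        Accepts the dataclass field names plus ``background`` as an alias for
        ``c_bg`` and ``rfd_dermal`` (converted to the equivalent abs_gi).
        """
        entry = self._entries.get(metal, _DEFAULTS.get(metal))
        if entry is None:
            raise KeyError(f"unknown metal {metal!r}")
        fields = dict(fields)
        if "background" in fields:
            fields["c_bg"] = fields.pop("background")
        if "rfd_dermal" in fields:
            dermal = float(fields.pop("rfd_dermal"))
            oral = float(fields.get("rfd_oral", entry.rfd_oral))
            fields["abs_gi"] = dermal / oral
        entries = dict(self._entries)
        entries[metal] = replace(entry, **{k: float(v) for k, v in fields.items()})
        return ToxicityTable(entries)


@dataclass(frozen=True)
class PollutionResult:
    hpi: float
    hpi_label: str
    er: dict[str, float]
    ri: float
    ri_label: str


def hpi(
    sample: "WaterSample",
    toxicity: ToxicityTable,
    metals: Sequence[str] = HPI_METALS,
) -> float:
    """Weighted heavy-metal pollution index.

    HPI = sum(W_i Q_i) / sum(W_i) with unit weight W_i = 1/S_i and sub-index
    Q_i = 100 C_i / S_i; equals 100 when every metal sits at its standard.
    """
    if not metals:
        raise ValueError("need at least one metal")
    num = den = 0.0
    for metal in metals:
        if metal not in sample.ptes:
            raise KeyError(f"{sample.sample_id}: no concentration for metal {metal!r}")
        si = toxicity[metal].si
        if si <= 0:
            raise ValueError(f"standard S_i must be positive for {metal!r}")
        wi = 1.0 / si
        qi = 100.0 * sample.ptes[metal] / si
        num += wi * qi
        den += wi
    return num / den


def classify_hpi(value: float) -> str:
    return HPI_SCHEME.classify(value)


def ecological_risk(
    sample: "WaterSample",
    toxicity: ToxicityTable,
    metals: Sequence[str] = PTE_NAMES,
) -> tuple[dict[str, float], float]:
    """Per-metal risk factors Er_i = Tr_i * C_i / Cbg_i and their sum RI."""
    er = {}
    for metal in metals:
        constants = toxicity[metal]
        if constants.c_bg is None:
            raise ValueError(
                f"background concentration for {metal!r} is required for RI "
                "(configure toxicity.c_bg; there is no default)"
            )
        if constants.c_bg <= 0:
            raise ValueError(f"background for {metal!r} must be positive")
        er[metal] = constants.tr * sample.ptes[metal] / constants.c_bg
    return er, sum(er.values())


def classify_ri(value: float) -> str:
    return RI_SCHEME.classify(value)


def pollution_table(
    samples: "SampleTable",
    toxicity: ToxicityTable,
    hpi_metals: Sequence[str] = HPI_METALS,
    ri_metals: Sequence[str] = PTE_NAMES,
    include_ri: bool = True,
) -> pd.DataFrame:
    """Per-sample HPI / RI panel with class labels."""
    rows = []
    for s in samples:
        value = hpi(s, toxicity, hpi_metals)
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "hpi": value,
            "hpi_label": classify_hpi(value),
        }
        if include_ri:
            er, ri = ecological_risk(s, toxicity, ri_metals)
            row.update({f"er_{m}": er[m] for m in ri_metals})
            row["ri"] = ri
            row["ri_label"] = classify_ri(ri)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
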