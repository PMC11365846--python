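"""Core record types, configuration loading, CSV I/O and interval classification.

Everything downstream (hydrochemistry, quality indices, risk chain) consumes
the types defined here: :class:`WaterSample`, :class:`SampleTable`,
:class:`StandardsTable` and :class:`ClassificationScheme`.  Units are fixed:
mg/L for every concentration, µS/cm for EC, dimensionless pH.  No automatic
unit conversion is ever attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ION_NAMES",
    "PTE_NAMES",
    "WQI_PARAMETERS",
    "DEFAULT_STANDARDS",
    "DEFAULT_INTEGRATED_WEIGHTS",
    "WQI_SCHEME",
    "HPI_SCHEME",
    "RI_SCHEME",
    "WaterSample",
    "SampleTable",
    "StandardsTable",
    "ClassificationScheme",
    "Config",
    "FormatError",
    "ValidationError",
    "classify",
    "load_samples",
    "write_samples",
    "load_config",
]

#: Major-ion names carried on every sample (mg/L).
ION_NAMES: tuple[str, ...] = ("Ca", "Mg", "Na", "K", "Cl", "SO4", "HCO3", "CO3", "NO3")

#: Potentially toxic elements carried on every sample (mg/L).
PTE_NAMES: tuple[str, ...] = ("Fe", "Mn", "Cu", "Zn")

#: Default parameter set entering the drinking-water quality index.
WQI_PARAMETERS: tuple[str, ...] = (
    "TDS", "pH", "EC", "Na", "K", "Mg", "Ca", "Mn", "Fe",
    "Cl", "SO4", "HCO3", "NO3", "TH",
)

#: WHO-based standards: parameter -> (sj, cjp).  cjp is the ideal value in
#: pure water (0 everywhere except pH, whose ideal is 7 and standard 7.5).
DEFAULT_STANDARDS: dict[str, tuple[float, float]] = {
    "TDS": (1000.0, 0.0),
    "pH": (7.5, 7.0),
    "EC": (1500.0, 0.0),
    "Na": (400.0, 0.0),
    "K": (12.0, 0.0),
    "Mg": (150.0, 0.0),
    "Ca": (200.0, 0.0),
    "Mn": (0.1, 0.0),
    "Fe": (0.3, 0.0),
    "Cl": (600.0, 0.0),
    "SO4": (400.0, 0.0),
    "HCO3": (200.0, 0.0),
    "NO3": (45.0, 0.0),
    "TH": (500.0, 0.0),
}

#: Published integrated weights for the default 14-parameter index; they sum
#: to exactly 1.
DEFAULT_INTEGRATED_WEIGHTS: dict[str, float] = {
    "TDS": 0.042538,
    "pH": 0.085516,
    "EC": 0.038892,
    "Na": 0.038133,
    "K": 0.090798,
    "Mg": 0.04749,
    "Ca": 0.045792,
    "Mn": 0.118172,
    "Fe": 0.154696,
    "Cl": 0.048279,
    "SO4": 0.056017,
    "HCO3": 0.100238,
    "NO3": 0.059186,
    "TH": 0.074253,
}


class FormatError(ValueError):
    """Input file cannot be parsed into the expected structure."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. negative concentration)."""


# ---------------------------------------------------------------------------
# classification schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationScheme:
    """Total, gap-free partition of the real line into labelled bins.

    ``breakpoints`` are strictly increasing; with ``k`` breakpoints there are
    ``k + 1`` labels.  ``edge_rule='left'`` (default) makes bins
    lower-inclusive / upper-exclusive, ``[a, b)``; ``'right'`` the opposite.
    """

    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    edge_rule: str = "left"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError(
                f"need {len(self.breakpoints) + 1} labels for "
                f"{len(self.breakpoints)} breakpoints, got {len(self.labels)}"
            )
        if any(nxt <= prev for prev, nxt in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if self.edge_rule not in ("left", "right"):
            raise ValueError("edge_rule must be 'left' or 'right'")

    def classify(self, value: float) -> str:
        if math.isnan(value):
            raise ValueError("cannot classify NaN")
        import bisect

        if self.edge_rule == "left":
            idx = bisect.bisect_right(self.breakpoints, value)
        else:
            idx = bisect.bisect_left(self.breakpoints, value)
        return self.labels[idx]


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Return the label of the bin containing *value* (total over the reals)."""
    return scheme.classify(value)


WQI_SCHEME = ClassificationScheme(
    (50.0, 100.0, 150.0, 200.0),
    ("excellent", "good", "medium", "poor", "extremely poor"),
)

# Gap-free reconciliation of the published HPI class listings: the 30-51
# band is never named consistently, so it is carried as "intermediate".
HPI_SCHEME = ClassificationScheme(
    (15.0, 30.0, 51.0, 76.0, 100.0),
    ("excellent", "good", "intermediate", "poor", "very poor", "unsuitable"),
)

RI_SCHEME = ClassificationScheme(
    (30.0, 60.0, 120.0),
    ("low", "moderate", "significant", "very high"),
)


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclass
class WaterSample:
    """One well's measured physicochemistry and PTE concentrations."""

    sample_id: str
    ph: float
    ec: float
    tds: float
    th: float
    ions: dict[str, float]
    ptes: dict[str, float]
    easting: float | None = None
    northing: float | None = None

    def __post_init__(self) -> None:
        self.ions = dict(self.ions)
        self.ions.setdefault("CO3", 0.0)
        self.ptes = dict(self.ptes)
        unknown = set(self.ions) - set(ION_NAMES)
        if unknown:
            raise ValidationError(f"{self.sample_id}: unknown ions {sorted(unknown)}")
        unknown = set(self.ptes) - set(PTE_NAMES)
        if unknown:
            raise ValidationError(f"{self.sample_id}: unknown PTEs {sorted(unknown)}")
        if not 0.0 < self.ph < 14.0:
            raise ValidationError(f"{self.sample_id}: pH {self.ph} outside (0, 14)")
        for name, value in (("EC", self.ec), ("TDS", self.tds), ("TH", self.th)):
            if value < 0:
                raise ValidationError(f"{self.sample_id}: negative {name} = {value}")
        for name, value in {**self.ions, **self.ptes}.items():
            if value < 0:
                raise ValidationError(
                    f"{self.sample_id}: negative concentration {name} = {value}"
                )

    def parameter(self, name: str) -> float:
        """Look up any evaluated parameter by canonical name."""
        if name == "pH":
            return self.ph
        if name == "EC":
            return self.ec
        if name == "TDS":
            return self.tds
        if name == "TH":
            return self.th
        if name in self.ions:
            return self.ions[name]
        if name in self.ptes:
            return self.ptes[name]
        raise KeyError(name)


_SCALAR_COLUMNS = ("sample_id", "easting", "northing", "ph", "ec", "tds", "th")
#: Canonical CSV column order.
CSV_COLUMNS: tuple[str, ...] = _SCALAR_COLUMNS + ION_NAMES + PTE_NAMES


class SampleTable:
    """Ordered collection of :class:`WaterSample` with a common parameter set."""

    def __init__(self, samples: Iterable[WaterSample]):
        self.samples: list[WaterSample] = list(samples)

    @property
    def m(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[WaterSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> WaterSample:
        return self.samples[i]

    def matrix(self, parameters: Sequence[str] = WQI_PARAMETERS) -> pd.DataFrame:
        """m × n matrix of evaluated parameters, indexed by sample_id."""
        data = {p: [s.parameter(p) for s in self.samples] for p in parameters}
        return pd.DataFrame(data, index=[s.sample_id for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row: dict[str, object] = {
                "sample_id": s.sample_id,
                "easting": s.easting,
                "northing": s.northing,
                "ph": s.ph,
                "ec": s.ec,
                "tds": s.tds,
                "th": s.th,
            }
            row.update({ion: s.ions.get(ion, 0.0) for ion in ION_NAMES})
            row.update({m: s.ptes[m] for m in PTE_NAMES})
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def load_samples(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SampleTable:
    """Read a per-sample CSV into a :class:`SampleTable`.

    ``column_map`` maps canonical names (``sample_id``, ``ph``, ``ec``,
    ``tds``, ``th``, ion and PTE names as in :data:`CSV_COLUMNS`) to whatever
    headers the file actually uses.  Unparseable numerics raise
    :class:`FormatError`; negative concentrations raise
    :class:`ValidationError` naming the sample.
    """
    path = Path(path)
    try:
        # round_trip parsing: written doubles must reload bit-for-bit
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.empty:
        raise FormatError(f"{path}: no data rows")

    column_map = dict(column_map or {})
    rename = {}
    for canonical in CSV_COLUMNS:
        header = column_map.get(canonical, canonical)
        if header in frame.columns:
            rename[header] = canonical
    frame = frame.rename(columns=rename)

    required = ["sample_id", "ph", "ec", "tds", "th", *ION_NAMES, *PTE_NAMES]
    optional = {"CO3", "easting", "northing"}
    missing = [c for c in required if c not in frame.columns and c not in optional]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    numeric = [c for c in frame.columns if c in CSV_COLUMNS and c != "sample_id"]
    for col in numeric:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna() & frame[col].notna()
        if bad.any():
            offender = frame.loc[bad, col].iloc[0]
            raise FormatError(f"{path}: unparseable value {offender!r} in column {col}")
        frame[col] = parsed

    samples = []
    for _, row in frame.iterrows():
        ions = {ion: float(row[ion]) for ion in ION_NAMES if ion in frame.columns}
        ptes = {m: float(row[m]) for m in PTE_NAMES}

        def _opt(name: str) -> float | None:
            if name not in frame.columns or pd.isna(row[name]):
                return None
            return float(row[name])

        samples.append(
            WaterSample(
                sample_id=str(row["sample_id"]),
                ph=float(row["ph"]),
                ec=float(row["ec"]),
                tds=float(row["tds"]),
                th=float(row["th"]),
                ions=ions,
                ptes=ptes,
                easting=_opt("easting"),
                northing=_opt("northing"),
            )
        )
    return SampleTable(samples)


def write_samples(table: SampleTable, path: str | Path) -> None:
    """Write a :class:`SampleTable` as canonical CSV (repr round-trips floats)."""
    frame = table.to_frame()
    frame.to_csv(path, index=False)  # default shortest-repr formatting round-trips


# ---------------------------------------------------------------------------
# standards / configuration
# ---------------------------------------------------------------------------

class StandardsTable:
    """Per-parameter standard value ``sj`` and pure-water ideal ``cjp``."""

    def __init__(self, entries: Mapping[str, tuple[float, float]]):
        self._entries = {k: (float(s), float(c)) for k, (s, c) in entries.items()}
        for name, (sj, cjp) in self._entries.items():
            if not sj > cjp:
                raise ValidationError(f"standard sj must exceed cjp for {name}")

    def sj(self, parameter: str) -> float:
        return self._entries[parameter][0]

    def cjp(self, parameter: str) -> float:
        return self._entries[parameter][1]

    def parameters(self) -> list[str]:
        return list(self._entries)

    def __contains__(self, parameter: str) -> bool:
        return parameter in self._entries


@dataclass
class Config:
    """Fully resolved run configuration."""

    standards: StandardsTable
    toxicity: "object"
    exposure_profiles: dict[str, "object"]
    schemes: dict[str, ClassificationScheme]
    integrated_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTEGRATED_WEIGHTS)
    )
    wqi_parameters: tuple[str, ...] = WQI_PARAMETERS
    cai_numerator: str = "schoeller"
    weight_integration: str = "product"
    preference_p: float = 0.5


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config, filling every omitted field with package defaults.

    Recognised top-level keys: ``standards`` (parameter -> sj or
    ``{sj, cjp}``), ``toxicity`` (metal -> constant overrides plus
    ``background``), ``exposure`` (cohort -> field overrides),
    ``cai_numerator``, ``weight_integration``, ``preference_p``,
    ``wqi_parameters``.
    """
    from . import health_risk, pollution_indices

    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")

    standards = {k: v for k, v in DEFAULT_STANDARDS.items()}
    for name, value in (raw.get("standards") or {}).items():
        if name not in standards:
            raise ValidationError(
                f"unknown parameter {name!r}; valid: {sorted(standards)}"
            )
        if isinstance(value, Mapping):
            sj = float(value.get("sj", standards[name][0]))
            cjp = float(value.get("cjp", standards[name][1]))
        else:
            sj, cjp = float(value), standards[name][1]
        standards[name] = (sj, cjp)

    toxicity = pollution_indices.ToxicityTable.default()
    for metal, over in (raw.get("toxicity") or {}).items():
        if metal not in PTE_NAMES:
            raise ValidationError(f"unknown metal {metal!r}; valid: {list(PTE_NAMES)}")
        toxicity = toxicity.with_overrides(metal, **(over or {}))

    profiles = {
        "adult": health_risk.ADULT,
        "child": health_risk.CHILD,
    }
    for cohort, over in (raw.get("exposure") or {}).items():
        if cohort not in profiles:
            raise ValidationError(f"unknown cohort {cohort!r}; valid: adult, child")
        profiles[cohort] = profiles[cohort].replace(**(over or {}))

    return Config(
        standards=StandardsTable(standards),
        toxicity=toxicity,
        exposure_profiles=profiles,
        schemes={"wqi": WQI_SCHEME, "hpi": HPI_SCHEME, "ri": RI_SCHEME},
        integrated_weights=dict(DEFAULT_INTEGRATED_WEIGHTS),
        wqi_parameters=tuple(raw.get("wqi_parameters", WQI_PARAMETERS)),
        cai_numerator=raw.get("cai_numerator", "schoeller"),
        weight_integration=raw.get("weight_integration", "product"),
        preference_p=float(raw.get("preference_p", 0.5)),
    )
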