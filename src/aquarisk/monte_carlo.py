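"""Probabilistic hazard-quotient simulation.

Each input variable of the risk chain gets a :class:`DistributionSpec`;
seeded, substreamed sampling feeds the deterministic kernels from
:mod:`aquarisk.health_risk`, and summaries report percentiles and threshold
exceedance per cohort / route / metal.

Distribution families cover point masses, (truncated) normals, (truncated)
lognormals with *truncated-moment* matching, and empirical bootstrap.
Truncation is applied by inverse-CDF restriction, which is exact and keeps
the draw count deterministic.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import health_risk
from .health_risk import ADULT, CHILD, ExposureProfile
from .pollution_indices import ToxicityTable

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import SampleTable

__all__ = [
    "DistributionSpec",
    "SimulationConfig",
    "SimulationResult",
    "fit_truncated_lognormal",
    "fit_truncated_normal",
    "build_distributions",
    "simulate_hq",
    "summarize",
    "calibration_check",
    "DEFAULT_CV",
]

#: Default coefficients of variation for the normally-distributed exposure
#: variables (assumption, recorded in run metadata; EF/ET/CF are point masses).
DEFAULT_CV: dict[str, float] = {"ir": 0.10, "sa": 0.10, "bw": 0.10, "ed": 0.20}

_FAMILIES = (
    "point", "normal", "lognormal", "truncated-normal",
    "truncated-lognormal", "empirical",
)


@dataclass(frozen=True)
class DistributionSpec:
    """One input variable's sampling law.

    ``params`` is family-specific: ``{"value"}`` for point; ``{"mean","sd"}``
    for (truncated) normal; ``{"mu","sigma"}`` (log-scale) for (truncated)
    lognormal; ``{"values"}`` for empirical bootstrap.  ``lower``/``upper``
    bound the truncated families.
    """

    name: str
    family: str
    params: dict = field(default_factory=dict)
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.lower is not None and self.upper is not None:
            if self.lower > self.upper:
                raise ValueError("lower bound exceeds upper bound")
        if "sd" in self.params and self.params["sd"] < 0:
            raise ValueError("sd must be >= 0")

    # -- sampling ----------------------------------------------------------
    def _frozen(self):
        if self.family in ("normal", "truncated-normal"):
            return stats.norm(self.params["mean"], self.params["sd"])
        if self.family in ("lognormal", "truncated-lognormal"):
            return stats.lognorm(
                s=self.params["sigma"], scale=math.exp(self.params["mu"])
            )
        raise AssertionError(self.family)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile transform of uniforms in (0, 1), honouring truncation."""
        u = np.asarray(u, dtype=float)
        if self.family == "point":
            return np.full_like(u, float(self.params["value"]))
        if self.family == "empirical":
            values = np.sort(np.asarray(self.params["values"], dtype=float))
            idx = np.minimum((u * len(values)).astype(int), len(values) - 1)
            return values[idx]
        dist = self._frozen()
        lo = dist.cdf(self.lower) if self.lower is not None else 0.0
        hi = dist.cdf(self.upper) if self.upper is not None else 1.0
        out = dist.ppf(lo + u * (hi - lo))
        if self.lower is not None:
            out = np.maximum(out, self.lower)
        if self.upper is not None:
            out = np.minimum(out, self.upper)
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    def mean(self) -> float:
        """Analytic mean of the (possibly truncated) law."""
        if self.family == "point":
            return float(self.params["value"])
        if self.family == "empirical":
            return float(np.mean(self.params["values"]))
        if self.family in ("normal", "lognormal") and self.lower is None \
                and self.upper is None:
            return float(self._frozen().mean())
        mean, _ = _truncated_moments(self)
        return mean


def _truncated_moments(spec: DistributionSpec) -> tuple[float, float]:
    """Mean and sd of a truncated normal/lognormal spec (analytic)."""
    if spec.family in ("normal", "truncated-normal"):
        mean, sd = spec.params["mean"], spec.params["sd"]
        if sd == 0:
            return mean, 0.0
        a = -np.inf if spec.lower is None else (spec.lower - mean) / sd
        b = np.inf if spec.upper is None else (spec.upper - mean) / sd
        m, v = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
        return float(m), float(np.sqrt(v))
    mu, sigma = spec.params["mu"], spec.params["sigma"]
    lo = spec.lower if spec.lower is not None else 0.0
    hi = spec.upper if spec.upper is not None else np.inf
    a = -np.inf if lo <= 0 else (math.log(lo) - mu) / sigma
    b = np.inf if not np.isfinite(hi) else (math.log(hi) - mu) / sigma
    z = stats.norm.cdf(b) - stats.norm.cdf(a)
    m1 = math.exp(mu + sigma**2 / 2) * (
        stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
    ) / z
    m2 = math.exp(2 * mu + 2 * sigma**2) * (
        stats.norm.cdf(b - 2 * sigma) - stats.norm.cdf(a - 2 * sigma)
    ) / z
    return m1, math.sqrt(max(m2 - m1**2, 0.0))


def _check_feasible(mean: float, sd: float, lo: float, hi: float) -> None:
    if not lo <= mean <= hi:
        raise ValueError(f"mean {mean} outside bounds [{lo}, {hi}]")
    bound = math.sqrt(max((mean - lo) * (hi - mean), 0.0))
    if sd > bound * 1.0000001:
        raise ValueError(
            f"sd {sd} impossible within [{lo}, {hi}] for mean {mean} "
            f"(max attainable {bound:.6g})"
        )


def fit_truncated_lognormal(
    mean: float, sd: float, lower: float, upper: float, name: str = "",
    tol: float = 0.02,
) -> DistributionSpec:
    """Truncated lognormal whose *truncated* mean/sd match the targets.

    ``tol`` is the accepted relative moment residual; sample statistics near
    the feasibility frontier of the family may need a looser tolerance.
    """
    _check_feasible(mean, sd, lower, upper)
    if sd == 0:
        return DistributionSpec(name=name, family="point", params={"value": mean})
    cv = sd / mean
    sigma0 = math.sqrt(math.log(1.0 + cv * cv))
    mu0 = math.log(mean) - sigma0**2 / 2

    def residual(theta: np.ndarray) -> np.ndarray:
        spec = DistributionSpec(name=name, family="truncated-lognormal",
                                params={"mu": theta[0], "sigma": theta[1]},
                                lower=lower, upper=upper)
        m, s = _truncated_moments(spec)
        return np.array([(m - mean) / mean, (s - sd) / sd])

    sol = optimize.least_squares(
        residual, x0=[mu0, sigma0], bounds=([-30.0, 1e-6], [30.0, 8.0])
    )
    if not sol.success or np.max(np.abs(sol.fun)) > tol:
        raise ValueError(
            f"cannot moment-match truncated lognormal for {name or 'variable'} "
            f"(best residual {np.max(np.abs(sol.fun)):.3f} > tol {tol})"
        )
    return DistributionSpec(name=name, family="truncated-lognormal",
                            params={"mu": float(sol.x[0]), "sigma": float(sol.x[1])},
                            lower=lower, upper=upper)


def fit_truncated_normal(
    mean: float, sd: float, lower: float, upper: float, name: str = ""
) -> DistributionSpec:
    """Truncated normal whose truncated mean/sd match the targets."""
    _check_feasible(mean, sd, lower, upper)
    if sd == 0:
        return DistributionSpec(name=name, family="point", params={"value": mean})

    def residual(theta: np.ndarray) -> np.ndarray:
        spec = DistributionSpec(name=name, family="truncated-normal",
                                params={"mean": theta[0], "sd": theta[1]},
                                lower=lower, upper=upper)
        m, s = _truncated_moments(spec)
        return np.array([(m - mean) / max(abs(mean), 1e-12), (s - sd) / sd])

    sol = optimize.least_squares(
        residual, x0=[mean, sd],
        bounds=([lower - 10 * sd, sd * 1e-3], [upper + 10 * sd, sd * 50]),
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 0.02:
        raise ValueError(
            f"cannot moment-match truncated normal for {name or 'variable'}"
        )
    return DistributionSpec(name=name, family="truncated-normal",
                            params={"mean": float(sol.x[0]), "sd": float(sol.x[1])},
                            lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    n_iter: int = 10_000
    seed: int | None = None
    cohorts: tuple[str, ...] = ("adult", "child")
    routes: tuple[str, ...] = ("oral", "dermal")
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if any(not 0.0 < p < 100.0 for p in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100)")


@dataclass
class SimulationResult:
    summary: pd.DataFrame              # indexed by (cohort, route, metal)
    draws: dict[tuple[str, str, str], np.ndarray]
    seed: int
    n_iter: int
    specs: dict


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream: adding variables never perturbs existing draws."""
    digest = hashlib.sha256(name.encode()).digest()[:8]
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(key,)))


_EXPOSURE_VARS = ("ir", "ed", "sa", "bw")
_POINT_VARS = ("ef", "et", "cf")


def build_distributions(
    samples: "SampleTable | None" = None,
    exposure_defaults: Mapping[str, ExposureProfile] | None = None,
    cv_map: Mapping[str, float] | None = None,
    conc_stats: Mapping[str, tuple[float, float, float, float]] | None = None,
    metals: Sequence[str] = ("Fe", "Mn", "Cu", "Zn"),
    empirical: bool = False,
) -> dict:
    """Assemble the spec set for :func:`simulate_hq`.

    Metal concentrations become truncated lognormals moment-matched to the
    cohort mean/sd and truncated to the observed [min, max] (or empirical
    bootstrap of the sample table with ``empirical=True``); ``conc_stats``
    may supply (min, max, mean, sd) tuples instead of raw samples.  IR, ED,
    SA and BW become normals with SD = cv * mean, truncated at 0 and +/-3 SD;
    EF, ET and CF are point masses.
    """
    profiles = dict(exposure_defaults or {"adult": ADULT, "child": CHILD})
    cv_map = {**DEFAULT_CV, **dict(cv_map or {})}

    conc: dict[str, DistributionSpec] = {}
    for metal in metals:
        if conc_stats is not None and metal in conc_stats:
            lo, hi, mean, sd = conc_stats[metal]
            values = None
        elif samples is not None:
            values = np.array([s.ptes[metal] for s in samples], dtype=float)
            if len(values) < 2:
                raise ValueError(f"metal {metal!r} has < 2 observations")
            lo, hi = float(values.min()), float(values.max())
            mean, sd = float(values.mean()), float(values.std(ddof=1))
        else:
            raise ValueError(f"no concentration data for metal {metal!r}")
        name = f"conc_{metal}"
        if empirical and values is not None:
            conc[metal] = DistributionSpec(name=name, family="empirical",
                                           params={"values": values.tolist()})
        elif sd == 0 or lo == hi:
            conc[metal] = DistributionSpec(name=name, family="point",
                                           params={"value": mean})
        else:
            try:
                # small cohorts can sit at the family's feasibility frontier;
                # allow a looser moment residual than the exact-target path
                conc[metal] = fit_truncated_lognormal(mean, sd, lo, hi,
                                                      name=name, tol=0.10)
            except ValueError:
                if values is None:
                    raise
                conc[metal] = DistributionSpec(name=name, family="empirical",
                                               params={"values": values.tolist()})

    exposure: dict[str, dict[str, DistributionSpec]] = {}
    for cohort, profile in profiles.items():
        specs: dict[str, DistributionSpec] = {}
        for var in _EXPOSURE_VARS:
            mean = getattr(profile, var)
            cv = cv_map.get(var, 0.0)
            name = f"{cohort}_{var}"
            if cv == 0.0:
                specs[var] = DistributionSpec(name=name, family="point",
                                              params={"value": mean})
            else:
                sd = cv * mean
                specs[var] = DistributionSpec(
                    name=name, family="truncated-normal",
                    params={"mean": mean, "sd": sd},
                    lower=max(0.0, mean - 3.0 * sd), upper=mean + 3.0 * sd,
                )
        for var in _POINT_VARS:
            specs[var] = DistributionSpec(name=f"{cohort}_{var}", family="point",
                                          params={"value": getattr(profile, var)})
        exposure[cohort] = specs

    return {"concentration": conc, "exposure": exposure, "profiles": profiles}


def simulate_hq(
    specs: Mapping,
    toxicity: ToxicityTable | None = None,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Seeded Monte Carlo hazard quotients per cohort / route / metal.

    Averaging time is tied to the drawn exposure duration (AT = ED * 365).
    An explicit seed is required; identical (seed, n_iter, specs) gives
    bit-identical output.
    """
    toxicity = toxicity or ToxicityTable.default()
    config = config or SimulationConfig()
    if config.seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    n = config.n_iter

    conc_specs: Mapping[str, DistributionSpec] = specs["concentration"]
    exposure_specs: Mapping[str, Mapping[str, DistributionSpec]] = specs["exposure"]
    profiles: Mapping[str, ExposureProfile] = specs.get(
        "profiles", {"adult": ADULT, "child": CHILD}
    )

    conc_draws = {
        metal: spec.sample(n, _substream(config.seed, spec.name))
        for metal, spec in conc_specs.items()
    }
    exp_draws = {
        cohort: {
            var: spec.sample(n, _substream(config.seed, spec.name))
            for var, spec in cohort_specs.items()
        }
        for cohort, cohort_specs in exposure_specs.items()
    }

    draws: dict[tuple[str, str, str], np.ndarray] = {}
    rows = []
    for cohort in config.cohorts:
        profile = profiles[cohort]
        ev = exp_draws[cohort]
        at = ev["ed"] * 365.0
        for route in config.routes:
            for metal, c in conc_draws.items():
                constants = toxicity[metal]
                if route == "oral":
                    cdi = health_risk.cdi_oral(
                        c, profile, ir=ev["ir"], ed=ev["ed"], bw=ev["bw"], at=at
                    )
                    hq = health_risk.hazard_quotient(cdi, constants.rfd_oral)
                elif route == "dermal":
                    cdi = health_risk.cdi_dermal(
                        c, profile, constants.kp,
                        ed=ev["ed"], sa=ev["sa"], bw=ev["bw"], at=at,
                    )
                    hq = health_risk.hazard_quotient(cdi, constants.rfd_dermal)
                else:
                    raise ValueError(f"unknown route {route!r}")
                hq = np.asarray(hq, dtype=float)
                draws[(cohort, route, metal)] = hq
                row = {
                    "cohort": cohort,
                    "route": route,
                    "metal": metal,
                    "mean": hq.mean(),
                    "sd": hq.std(ddof=1) if n > 1 else 0.0,
                    "fraction_above_1": float((hq > 1.0).mean()),
                }
                for p in config.percentiles:
                    row[f"p{p:g}"] = float(np.percentile(hq, p))
                rows.append(row)

    summary = pd.DataFrame(rows).set_index(["cohort", "route", "metal"])
    return SimulationResult(summary=summary, draws=draws, seed=config.seed,
                            n_iter=n, specs=dict(specs))


def summarize(result: SimulationResult, threshold: float = 1.0) -> pd.DataFrame:
    """Flat report: percentiles, mean, and exceedance against *threshold*."""
    if not result.draws:
        raise ValueError("empty simulation result")
    rows = []
    for (cohort, route, metal), hq in result.draws.items():
        row = {
            "cohort": cohort, "route": route, "metal": metal,
            "mean": float(hq.mean()),
            "p5": float(np.percentile(hq, 5)),
            "p50": float(np.percentile(hq, 50)),
            "p95": float(np.percentile(hq, 95)),
            "exceedance_fraction": float((hq > threshold).mean()),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_check(
    deterministic: Mapping[tuple[str, str, str], float],
    simulated: SimulationResult,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Relative difference between deterministic HQs and simulated means.

    Keys are (cohort, route, metal) triples and must match the simulation
    exactly; rows whose |relative difference| exceeds *tolerance* are
    flagged.
    """
    det_keys = set(deterministic)
    sim_keys = set(simulated.draws)
    if det_keys != sim_keys:
        raise KeyError(
            f"key mismatch: only-deterministic {sorted(det_keys - sim_keys)}, "
            f"only-simulated {sorted(sim_keys - det_keys)}"
        )
    rows = []
    for key in sorted(det_keys):
        det = float(deterministic[key])
        sim = float(simulated.draws[key].mean())
        rel = (sim - det) / det if det != 0 else (0.0 if sim == 0 else math.inf)
        rows.append(
            {
                "cohort": key[0], "route": key[1], "metal": key[2],
                "deterministic": det, "simulated_mean": sim,
                "rel_diff": rel, "flag": abs(rel) > tolerance,
            }
        )
    return pd.DataFrame(rows)
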