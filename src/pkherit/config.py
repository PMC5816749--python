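"""Study configuration objects.

Two configuration layers drive the pipeline:

* :class:`PopulationConfig` — the experimental design of the half-sib
  resource population (sires per breed, batches, sampling schedules,
  IV doses).
* :class:`TruthParams` — the generating ("truth") parameters of the
  forward simulation: population disposition curves per drug and
  compound, log-scale variance components (sire / batch / animal),
  measurement noise, and serial correlation.

Defaults reproduce the published resource-population design: 198
crossbred nursery pigs from 20 purebred sires (Duroc 5, Hampshire 4,
Landrace 6, Yorkshire 5) spread across nine batches, dosed IV with
fenbendazole (FBZ, 1 mg/kg) or flunixin meglumine (FLU, 3 mg/kg) and
bled on a 10-draw schedule over 48 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "PopulationConfig",
    "DispositionCurve",
    "TruthParams",
    "load_config",
    "BREEDS",
    "SEXES",
    "DRUGS",
    "COMPOUNDS",
]

BREEDS = ("Duroc", "Hampshire", "Landrace", "Yorkshire")
SEXES = ("castrated male", "female")
DRUGS = ("FBZ", "FLU")
COMPOUNDS = ("parent", "metabolite")

#: Animals per batch in the emulated design (sums to 198).
DEFAULT_BATCH_SIZES = (7, 12, 15, 20, 29, 29, 27, 28, 31)

#: Mean / SD body weight (kg) per batch prior to dosing.
DEFAULT_BATCH_WEIGHTS = (
    (34.15, 4.67), (54.85, 11.13), (31.66, 5.18), (40.66, 5.88),
    (26.03, 4.14), (26.82, 3.78), (33.67, 4.82), (33.13, 5.29),
    (34.06, 5.11),
)


class ConfigurationError(ValueError):
    """Raised for infeasible or internally inconsistent configurations."""


@dataclass
class PopulationConfig:
    """Design of the simulated half-sib resource population."""

    n_batches: int = 9
    sires_per_breed: dict = field(
        default_factory=lambda: {"Duroc": 5, "Hampshire": 4, "Landrace": 6, "Yorkshire": 5}
    )
    progeny_range: tuple = (4, 24)
    n_animals: int = 198
    sex_ratio: float = 0.5
    drugs: tuple = DRUGS
    dose_mg_per_kg: dict = field(default_factory=lambda: {"FBZ": 1.0, "FLU": 3.0})
    schedule_h: dict = field(
        default_factory=lambda: {
            "FBZ": [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 12.0, 24.0, 48.0],
            "FLU": [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 8.0, 12.0, 24.0, 48.0],
        }
    )
    batch_sizes: tuple | None = None
    batch_weights: tuple | None = None
    seed: int = 0

    @property
    def n_sires(self) -> int:
        return sum(self.sires_per_breed.values())

    def resolved_batch_sizes(self) -> list:
        if self.batch_sizes is not None:
            sizes = list(self.batch_sizes)
        elif self.n_batches == 9 and self.n_animals == 198:
            sizes = list(DEFAULT_BATCH_SIZES)
        else:
            base, extra = divmod(self.n_animals, self.n_batches)
            sizes = [base + (1 if i < extra else 0) for i in range(self.n_batches)]
        if len(sizes) != self.n_batches or sum(sizes) != self.n_animals:
            raise ConfigurationError(
                f"batch sizes {sizes} do not partition {self.n_animals} animals "
                f"into {self.n_batches} batches"
            )
        return sizes

    def resolved_batch_weights(self) -> list:
        if self.batch_weights is not None:
            w = list(self.batch_weights)
        elif self.n_batches == 9:
            w = list(DEFAULT_BATCH_WEIGHTS)
        else:
            w = [(33.0, 5.0)] * self.n_batches
        if len(w) != self.n_batches:
            raise ConfigurationError("batch_weights length must equal n_batches")
        return w

    def validate(self) -> None:
        if self.n_animals <= 0:
            raise ConfigurationError("n_animals must be positive")
        lo, hi = self.progeny_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("progeny_range must satisfy 1 <= min <= max")
        n_sires = self.n_sires
        if n_sires < 1:
            raise ConfigurationError("at least one sire is required")
        if not (n_sires * lo <= self.n_animals <= n_sires * hi):
            raise ConfigurationError(
                f"n_animals={self.n_animals} unreachable with {n_sires} sires and "
                f"progeny_range={self.progeny_range}"
            )
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        for drug in self.drugs:
            if drug not in self.schedule_h:
                raise ConfigurationError(f"no sampling schedule for drug {drug!r}")
            sched = self.schedule_h[drug]
            if sched[0] != 0:
                raise ConfigurationError("sampling schedule must start at 0 h")
            if any(b <= a for a, b in zip(sched, sched[1:])):
                raise ConfigurationError("sampling hours must be strictly increasing")
            if drug not in self.dose_mg_per_kg or self.dose_mg_per_kg[drug] <= 0:
                raise ConfigurationError(f"positive dose required for drug {drug!r}")
        self.resolved_batch_sizes()
        self.resolved_batch_weights()


@dataclass
class DispositionCurve:
    """Population disposition of one drug: IV-bolus biexponential parent
    plus a formation-limited (rise-then-fall) metabolite.

    Parent concentration per unit dose: ``C(t)/Dose = A e^{-alpha t} + B e^{-beta t}``
    with ``alpha > beta > 0`` (distribution and elimination phases).
    Metabolite: ``C_m(t) = M (e^{-k_elim t} - e^{-k_form t})`` with
    ``k_form > k_elim > 0`` so the curve rises to a single peak at
    ``ln(k_form/k_elim) / (k_form - k_elim)`` hours and then decays.
    """

    A: float
    B: float
    alpha: float
    beta: float
    met_scale: float
    k_form: float
    k_elim: float

    def validate(self) -> None:
        for name in ("A", "B", "met_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not (self.alpha > self.beta > 0):
            raise ConfigurationError("need alpha > beta > 0")
        if not (self.k_form > self.k_elim > 0):
            raise ConfigurationError("need k_form > k_elim > 0")


def _default_curves() -> dict:
    # Calibrated so population-mean NCA parameters land near the observed
    # study means: FLU parent Cl ~ 0.12 L/h/kg, T1/2 ~ 6.6 h, MRT ~ 3.9 h;
    # FBZ parent T1/2 ~ 15 h; FBZ metabolite peak ~ 3.6 h, FLU metabolite
    # peak ~ 0.7 h.
    return {
        "FBZ": DispositionCurve(A=1.14, B=0.145, alpha=0.80, beta=0.046,
                                met_scale=0.84, k_form=0.60, k_elim=0.10),
        "FLU": DispositionCurve(A=4.05, B=0.26, alpha=0.693, beta=0.105,
                                met_scale=0.08, k_form=6.0, k_elim=0.12),
    }


@dataclass
class TruthParams:
    """Generating parameters of the forward simulation.

    Random effects act on two log-scale disposition parameters:

    * ``log_scale`` — multiplies curve amplitudes (A, B, met_scale); a
      deviation ``u`` shifts log AUC by ``+u`` and log clearance by ``-u``.
    * ``log_rate`` — multiplies all rate constants; shifts log half-life.

    Variance maps give the per-parameter variance of sire, batch and
    animal-level deviations. Defaults put a sire variance of 0.01 on
    ``log_scale`` against batch 0.02 and a permanent animal deviation of
    0.05, with 28% lognormal measurement noise — a moderate heritability
    regime (scalar-model h2 around 0.2-0.3) matching what half-sib
    designs of this size report for drug disposition. The permanent
    animal deviation is deliberately modest because the longitudinal
    analysis model carries no permanent-environment term: what the
    generator puts there, the sire model partly absorbs (see
    docs/methods.md).
    """

    pop_curve: dict = field(default_factory=_default_curves)
    sigma2_sire: dict = field(default_factory=lambda: {"log_scale": 0.01})
    sigma2_batch: dict = field(default_factory=lambda: {"log_scale": 0.02})
    sigma2_e: dict = field(default_factory=lambda: {"log_scale": 0.05})
    fixed_sex: dict = field(default_factory=lambda: {"log_scale": 0.04})
    fixed_breed: dict = field(default_factory=dict)  # breed -> {param: shift}
    cv_measurement: float = 0.28
    ar1_rho: dict = field(default_factory=lambda: {"FBZ": 0.0, "FLU": 0.4})
    loq_ug_per_ml: float = 0.005

    PARAMS = ("log_scale", "log_rate")

    def validate(self) -> None:
        for curve in self.pop_curve.values():
            curve.validate()
        for name in ("sigma2_sire", "sigma2_batch", "sigma2_e"):
            for param, v in getattr(self, name).items():
                if param not in self.PARAMS:
                    raise ConfigurationError(f"unknown disposition parameter {param!r}")
                if v < 0:
                    raise ConfigurationError(f"{name}[{param!r}] must be >= 0")
        for drug, rho in self.ar1_rho.items():
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(f"ar1_rho[{drug!r}] must lie in (-1, 1)")
        if self.cv_measurement < 0:
            raise ConfigurationError("cv_measurement must be >= 0")

    def variance(self, which: str, param: str) -> float:
        return float(getattr(self, f"sigma2_{which}").get(param, 0.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pop_curve"] = {k: asdict(v) for k, v in self.pop_curve.items()}
        return d


def load_config(path: str | Path) -> tuple[PopulationConfig, TruthParams]:
    """Load a YAML/JSON study config with optional ``population`` and
    ``truth`` blocks; omitted fields keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pop_kwargs = dict(raw.get("population", {}))
    for key in ("progeny_range", "batch_sizes", "drugs"):
        if key in pop_kwargs and pop_kwargs[key] is not None:
            pop_kwargs[key] = tuple(pop_kwargs[key])
    pop = PopulationConfig(**pop_kwargs)
    truth_kwargs = dict(raw.get("truth", {}))
    if "pop_curve" in truth_kwargs:
        truth_kwargs["pop_curve"] = {
            k: DispositionCurve(**v) for k, v in truth_kwargs["pop_curve"].items()
        }
    truth = TruthParams(**truth_kwargs)
    pop.validate()
    truth.validate()
    return pop, truth
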