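"""Synthetic half-sib resource populations with drug concentration-time data.

The generator emulates a designed pharmacogenetic study in nursery pigs:
purebred sires of four breeds mated to common-line sows, progeny spread
across housing batches, each animal dosed IV with one drug and bled on a
fixed schedule over 48 h. Every dataset is produced from known ("truth")
variance components so that downstream variance-component estimation can
be tested for parameter recovery.

The generative model is multiplicative: sire, batch and animal deviations
act on log-scale disposition parameters (curve amplitude = log clearance,
rate constants = log half-life), guaranteeing positive concentrations.
Measurement error is lognormal with configurable CV, optionally serially
correlated (AR1 across an animal's sampling index); values below the
limit of quantification are recorded as missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BREEDS,
    SEXES,
    ConfigurationError,
    DispositionCurve,
    PopulationConfig,
    TruthParams,
)

__all__ = [
    "simulate_roster",
    "simulate_effects",
    "simulate_dataset",
    "simulate_study",
    "simulate_sire_trait",
    "parent_curve",
    "metabolite_curve",
    "write_dataset",
]

ROSTER_COLUMNS = [
    "animal_id", "sire_id", "breed", "sex", "batch",
    "body_weight_kg", "drug", "dose_mg_per_kg",
]


def parent_curve(curve: DispositionCurve, dose: float, times_h: np.ndarray,
                 scale_mult: float = 1.0, rate_mult: float = 1.0) -> np.ndarray:
    """IV-bolus biexponential parent concentration (ug/mL) at ``times_h``."""
    t = np.asarray(times_h, dtype=float)
    A = curve.A * scale_mult
    B = curve.B * scale_mult
    return dose * (A * np.exp(-curve.alpha * rate_mult * t)
                   + B * np.exp(-curve.beta * rate_mult * t))


def metabolite_curve(curve: DispositionCurve, dose: float, times_h: np.ndarray,
                     scale_mult: float = 1.0, rate_mult: float = 1.0) -> np.ndarray:
    """Formation-limited metabolite concentration: rises to a single peak
    then decays (difference of exponentials)."""
    t = np.asarray(times_h, dtype=float)
    kf = curve.k_form * rate_mult
    ke = curve.k_elim * rate_mult
    # dose enters through the amount of parent available for conversion
    return curve.met_scale * scale_mult * dose * (np.exp(-ke * t) - np.exp(-kf * t))


def simulate_roster(config: PopulationConfig) -> pd.DataFrame:
    """Generate the animal roster: sires nested in breed, progeny counts
    within the configured range, animals spread across batches (so sires
    span batches, reproducing the partial sire/batch confounding of the
    real design), drug assignment balanced over breed x sex within batch.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sires = []
    for breed in sorted(config.sires_per_breed):
        for i in range(config.sires_per_breed[breed]):
            sires.append((f"{breed[0]}{i + 1:02d}", breed))
    n_sires = len(sires)
    lo, hi = config.progeny_range

    # progeny counts: everyone starts at the minimum, remaining animals are
    # dealt one at a time to sires still below the maximum
    counts = np.full(n_sires, lo, dtype=int)
    remaining = config.n_animals - counts.sum()
    while remaining > 0:
        open_idx = np.flatnonzero(counts < hi)
        pick = rng.choice(open_idx)
        counts[pick] += 1
        remaining -= 1

    sire_of_animal = np.repeat(np.arange(n_sires), counts)
    rng.shuffle(sire_of_animal)  # spreads each sire's progeny across batches

    batch_sizes = config.resolved_batch_sizes()
    batch = np.repeat(np.arange(1, config.n_batches + 1), batch_sizes)

    n = config.n_animals
    n_female = int(round(config.sex_ratio * n))
    sex = np.array(["female"] * n_female + ["castrated male"] * (n - n_female))
    rng.shuffle(sex)

    rows = []
    for i in range(n):
        sid, breed = sires[sire_of_animal[i]]
        rows.append({
            "animal_id": f"A{i + 1:03d}",
            "sire_id": sid,
            "breed": breed,
            "sex": sex[i],
            "batch": int(batch[i]),
        })
    roster = pd.DataFrame(rows)

    # balanced drug assignment within batch, blocking on breed x sex
    drugs = list(config.drugs)
    drug_col = np.empty(n, dtype=object)
    for b in range(1, config.n_batches + 1):
        in_batch = np.flatnonzero(roster["batch"].to_numpy() == b)
        for _, grp in roster.iloc[in_batch].groupby(["breed", "sex"], sort=True):
            idx = grp.index.to_numpy()
            rng.shuffle(idx)
            start = rng.integers(len(drugs))
            for j, animal_idx in enumerate(idx):
                drug_col[animal_idx] = drugs[(start + j) % len(drugs)]
    roster["drug"] = drug_col
    roster["dose_mg_per_kg"] = roster["drug"].map(config.dose_mg_per_kg)

    weights = config.resolved_batch_weights()
    bw = np.empty(n)
    for b in range(1, config.n_batches + 1):
        mask = roster["batch"].to_numpy() == b
        mu, sd = weights[b - 1]
        bw[mask] = np.clip(rng.normal(mu, sd, mask.sum()), 5.0, None)
    roster["body_weight_kg"] = np.round(bw, 2)

    return roster[ROSTER_COLUMNS]


def simulate_effects(roster: pd.DataFrame, truth: TruthParams,
                     seed: int = 0) -> pd.DataFrame:
    """Per-animal latent log-scale disposition deviations.

    Each animal's deviation on parameter p is
    ``breed shift + sex shift + sire_dev + batch_dev + animal_dev`` with the
    sire and batch deviations drawn once per sire / batch and shared.
    Returns one row per animal with a column per disposition parameter.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    sire_ids = np.sort(roster["sire_id"].unique())
    batch_ids = np.sort(roster["batch"].unique())
    n = len(roster)

    out = pd.DataFrame({"animal_id": roster["animal_id"].to_numpy()})
    for param in TruthParams.PARAMS:
        s2s = truth.variance("sire", param)
        s2b = truth.variance("batch", param)
        s2e = truth.variance("e", param)
        sire_dev = dict(zip(sire_ids, rng.normal(0.0, np.sqrt(s2s), len(sire_ids))))
        batch_dev = dict(zip(batch_ids, rng.normal(0.0, np.sqrt(s2b), len(batch_ids))))
        animal_dev = rng.normal(0.0, np.sqrt(s2e), n)
        sex_shift = roster["sex"].map(
            lambda s: truth.fixed_sex.get(param, 0.0) if s == "female" else 0.0
        ).to_numpy(dtype=float)
        breed_shift = roster["breed"].map(
            lambda b: truth.fixed_breed.get(b, {}).get(param, 0.0)
        ).to_numpy(dtype=float)
        out[param] = (
            breed_shift + sex_shift
            + roster["sire_id"].map(sire_dev).to_numpy(dtype=float)
            + roster["batch"].map(batch_dev).to_numpy(dtype=float)
            + animal_dev
        )
    return out


def _ar1_noise(rng: np.random.Generator, m: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR1 log-noise across the sampling index."""
    z = np.empty(m)
    z[0] = rng.normal(0.0, sigma)
    for k in range(1, m):
        z[k] = rho * z[k - 1] + rng.normal(0.0, sigma * np.sqrt(1.0 - rho ** 2))
    return z


def simulate_dataset(roster: pd.DataFrame, truth: TruthParams,
                     config: PopulationConfig,
                     effects: pd.DataFrame | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Long-format concentration table: parent and metabolite per animal.

    The pre-dose (t = 0) draw records the back-extrapolated intercept for
    the parent and exactly zero for the metabolite; modelling stages drop
    t = 0. Concentrations below ``truth.loq_ug_per_ml`` are set missing.
    """
    truth.validate()
    if seed is None:
        seed = config.seed
    if effects is None:
        effects = simulate_effects(roster, truth, seed=seed)
    eff = effects.set_index("animal_id")
    rng = np.random.default_rng(seed + 1)
    sigma_log = np.sqrt(np.log1p(truth.cv_measurement ** 2))

    frames = []
    for row in roster.itertuples(index=False):
        drug = row.drug
        curve = truth.pop_curve[drug]
        times = np.asarray(config.schedule_h[drug], dtype=float)
        dose = float(row.dose_mg_per_kg)
        scale_mult = float(np.exp(eff.loc[row.animal_id, "log_scale"]))
        rate_mult = float(np.exp(eff.loc[row.animal_id].get("log_rate", 0.0)))
        rho = truth.ar1_rho.get(drug, 0.0)
        for compound, fn in (("parent", parent_curve), ("metabolite", metabolite_curve)):
            clean = fn(curve, dose, times, scale_mult, rate_mult)
            if sigma_log > 0:
                z = _ar1_noise(rng, len(times), sigma_log, rho)
            else:
                z = np.zeros(len(times))
            conc = clean * np.exp(z)
            if compound == "metabolite":
                conc[times == 0.0] = 0.0
            conc = np.where((conc < truth.loq_ug_per_ml) & (times > 0), np.nan, conc)
            frames.append(pd.DataFrame({
                "animal_id": row.animal_id,
                "sire_id": row.sire_id,
                "breed": row.breed,
                "sex": row.sex,
                "batch": row.batch,
                "drug": drug,
                "compound": compound,
                "dose_mg_per_kg": dose,
                "body_weight_kg": row.body_weight_kg,
                "time_h": times,
                "conc_ug_per_ml": conc,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_study(config: PopulationConfig | None = None,
                   truth: TruthParams | None = None,
                   seed: int | None = None):
    """Convenience wrapper: roster + effects + concentration table."""
    if config is None:
        config = PopulationConfig()
    if seed is not None:
        config.seed = seed
    if truth is None:
        truth = TruthParams()
    roster = simulate_roster(config)
    effects = simulate_effects(roster, truth, seed=config.seed)
    data = simulate_dataset(roster, truth, config, effects=effects)
    return roster, effects, data


def simulate_sire_trait(n_sires: int, n_progeny: int, sigma2_sire: float,
                        sigma2_batch: float = 0.0, sigma2_e: float = 1.0,
                        n_batches: int = 0, mu: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Balanced half-sib trait records drawn directly from the sire model
    ``y = mu + sire + batch + e`` — the minimal generator for variance
    component recovery and likelihood-ratio calibration experiments.

    With ``n_batches == 0`` no batch term is simulated. Weights are 1.
    """
    if min(sigma2_sire, sigma2_batch, sigma2_e) < 0:
        raise ConfigurationError("variances must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_sires * n_progeny
    sire_idx = np.repeat(np.arange(n_sires), n_progeny)
    sire_dev = rng.normal(0.0, np.sqrt(sigma2_sire), n_sires)
    y = mu + sire_dev[sire_idx] + rng.normal(0.0, np.sqrt(sigma2_e), n)
    df = pd.DataFrame({
        "animal_id": [f"A{i + 1:05d}" for i in range(n)],
        "sire_id": [f"S{s + 1:04d}" for s in sire_idx],
    })
    if n_batches > 0:
        batch = rng.integers(1, n_batches + 1, n)
        batch_dev = rng.normal(0.0, np.sqrt(sigma2_batch), n_batches)
        y = y + batch_dev[batch - 1]
        df["batch"] = batch
    df["y"] = y
    df["weight"] = 1.0
    return df


def write_dataset(data: pd.DataFrame, truth: TruthParams, out_dir: str | Path) -> None:
    """Write concentrations.csv and truth.json to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.to_csv(out / "concentrations.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
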