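"""Synthetic cohort, outcome, and growth-curve generator.

Generates data with the statistical structure the analysis pipeline
assumes, so every stage is testable end-to-end without external data:

* a cohort of ``n_patients`` x ``isolates_per_patient`` isolates whose
  per-patient Pf carriage pattern (all / two-thirds / one-third / none
  of the patient's isolates) is drawn from fixed probabilities, with
  carrier isolates of one patient sharing a single catalog phage (Pf
  phages cluster by patient and sequence type);
* latent interaction outcomes: the probability that an isolate resists
  a given lytic phage is inverse-logit(baseline + sum of the per-phage
  log-odds effects of the systems it carries);
* triplicate OD600 growth curves and spot grades consistent with the
  latent outcome: controls follow logistic growth, sensitive wells
  collapse to a lysis floor after an onset placed inside the control's
  exponential window (so productive infection is detectable by
  construction), resistant wells grow like controls.

Each stage consumes its own deterministic random stream derived from
``(seed, stage)``, so a fixed seed reproduces everything bit-for-bit
and stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .calling import GrowthCurve, SpotTriplicate, detect_exponential_window
from .cohort import Cohort, Isolate, PfPhage
from .errors import InputError
from . import io as pfio

_STAGE_COHORT = 0
_STAGE_OUTCOMES = 1
_STAGE_CURVES = 2

#: Background (non-Pf) defense-system name pool used to pad isolate
#: repertoires up to the drawn whole-genome count.
_BACKGROUND_POOL = tuple(f"BG-{i:02d}" for i in range(1, 61))


class CurveParams(BaseModel):
    """Logistic growth and lysis parameters for simulated OD600 wells."""

    K: float = Field(default=1.2, gt=0)  # carrying capacity (OD600)
    r: float = Field(default=0.8, gt=0)  # growth rate (1/h)
    od0: float = Field(default=0.05, gt=0)  # inoculum OD600
    lysis_floor: float = Field(default=0.08, gt=0)
    lysis_rate: float = Field(default=1.5, gt=0)  # decay rate after onset (1/h)
    noise_sd: float = Field(default=0.01, ge=0)
    sampling_interval_h: float = Field(default=0.5, gt=0)
    horizon_h: float = Field(default=24.0, gt=0)


def default_system_effects(
    catalog: Sequence[PfPhage], n_phages: int
) -> dict[str, tuple[float, ...]]:
    """Default per-phage log-odds effects for every catalog system.

    Superinfection-exclusion systems (PfsE-like) protect only against
    the first phage, standing in for receptor-specific defense; all
    other strategies protect broadly, abortive-infection systems more
    strongly than toxin-antitoxin or restriction systems.
    """
    effects: dict[str, tuple[float, ...]] = {}
    for phage in catalog:
        for s in phage.systems:
            if s.name in effects:
                continue
            if s.strategy == "sie":
                vec = [0.0] * n_phages
                vec[0] = 3.0
            elif s.strategy == "abi":
                vec = [2.0] * n_phages
            else:  # ta, restriction, unknown
                vec = [1.0] * n_phages
            effects[s.name] = tuple(vec)
    return effects


class SimulationConfig(BaseModel):
    """Knobs of the synthetic cohort; defaults mirror the study design."""

    n_patients: int = Field(default=25, ge=1)
    isolates_per_patient: int = Field(default=3, ge=1)
    carriage_pattern_probs: tuple[float, float, float, float] = (0.40, 0.12, 0.12, 0.36)
    n_phages: int = Field(default=4, ge=1)
    phage_ids: Optional[tuple[str, ...]] = None
    genome_systems_range: tuple[int, int] = (5, 19)
    catalog: Optional[tuple[PfPhage, ...]] = None
    baseline_resistance_logit: float = 0.8
    system_effects: Optional[dict[str, tuple[float, ...]]] = None
    curve_params: CurveParams = Field(default_factory=CurveParams)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        probs = self.carriage_pattern_probs
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("carriage_pattern_probs must be non-negative and sum to 1")
        if self.catalog is None:
            object.__setattr__(self, "catalog", pfio.load_table2_catalog())
        if self.phage_ids is None:
            ids = (
                ("DCL-PA6", "DCL-PA6a", "PAC2", "PAC8")
                if self.n_phages == 4
                else tuple(f"phage{i + 1:02d}" for i in range(self.n_phages))
            )
            object.__setattr__(self, "phage_ids", ids)
        if len(self.phage_ids) != self.n_phages:
            raise ValueError("phage_ids length must equal n_phages")
        lo, hi = self.genome_systems_range
        if lo > hi or lo < 0:
            raise ValueError("genome_systems_range must be an inclusive (lo, hi) pair")
        max_payload = max((len(p.system_names) for p in self.catalog), default=0)
        if lo < max_payload:
            raise ValueError(
                f"genome_systems_range lower bound {lo} < largest Pf payload "
                f"({max_payload} systems)"
            )
        known = {s.name for p in self.catalog for s in p.systems}
        known |= set(_BACKGROUND_POOL)
        if self.system_effects is None:
            object.__setattr__(
                self, "system_effects", default_system_effects(self.catalog, self.n_phages)
            )
        unknown = set(self.system_effects) - known
        if unknown:
            raise ValueError(f"system_effects references unknown systems {sorted(unknown)}")
        for name, vec in self.system_effects.items():
            if len(vec) != self.n_phages:
                raise ValueError(
                    f"effect vector for {name} has length {len(vec)}, expected {self.n_phages}"
                )
        return self

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class GroundTruth:
    """Latent record of what the generator actually drew."""

    pf_carriage: dict[str, tuple[str, ...]] = field(default_factory=dict)
    systems: dict[str, frozenset[str]] = field(default_factory=dict)
    phage_ids: tuple[str, ...] = ()
    probability: Optional[pd.DataFrame] = None  # isolate x phage P(resist)
    outcome: Optional[pd.DataFrame] = None  # isolate x phage {R, S}

    @property
    def complete(self) -> bool:
        return self.outcome is not None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pf_carriage": {k: list(v) for k, v in self.pf_carriage.items()},
            "systems": {k: sorted(v) for k, v in self.systems.items()},
            "phage_ids": list(self.phage_ids),
            "probability": None
            if self.probability is None
            else self.probability.round(10).to_dict(orient="index"),
            "outcome": None if self.outcome is None else self.outcome.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw the cohort: carriage patterns, shared phages, repertoires."""
    rng = config.rng(_STAGE_COHORT)
    ipp = config.isolates_per_patient
    lo, hi = config.genome_systems_range
    isolates: list[Isolate] = []
    truth = GroundTruth(phage_ids=config.phage_ids)
    for p in range(1, config.n_patients + 1):
        pattern = int(rng.choice(4, p=config.carriage_pattern_probs))
        n_carriers = int(round(ipp * (3 - pattern) / 3))
        carrier_slots = set(map(int, rng.choice(ipp, size=n_carriers, replace=False)))
        phage = config.catalog[int(rng.integers(len(config.catalog)))]
        patient_st = str(int(rng.integers(100, 3000)))
        patient_id = f"P{p:02d}"
        for i in range(ipp):
            carrier = i in carrier_slots
            # Non-carrier isolates of mixed-carriage patients tend to be
            # a different lineage; give them their own sequence type.
            st = patient_st if carrier or n_carriers == 0 else str(int(rng.integers(100, 3000)))
            payload = frozenset(s.name for s in phage.systems) if carrier else frozenset()
            n_total = int(rng.integers(lo, hi + 1))
            n_background = max(0, n_total - len(payload))
            background = rng.choice(
                len(_BACKGROUND_POOL), size=n_background, replace=False
            )
            names = payload | {_BACKGROUND_POOL[int(b)] for b in background}
            iso_id = f"{patient_id}-{i + 1}"
            isolates.append(
                Isolate(
                    id=iso_id,
                    patient_id=patient_id,
                    st=st,
                    pf_ids=(phage.id,) if carrier else (),
                    pf_isolate_names=(f"Pf{iso_id}",) if carrier else (),
                    n_genome_systems=len(names),
                    genome_system_names=frozenset(names),
                )
            )
            truth.pf_carriage[iso_id] = (phage.id,) if carrier else ()
            truth.systems[iso_id] = frozenset(names)
    cohort = Cohort(isolates=tuple(isolates), catalog=tuple(config.catalog))
    return cohort, truth


def simulate_interaction_outcomes(
    cohort: Cohort, truth: GroundTruth, config: SimulationConfig
) -> GroundTruth:
    """Fill per-interaction resistance probabilities and latent R/S outcomes."""
    if set(truth.systems) != {iso.id for iso in cohort.isolates}:
        raise InputError("ground truth does not cover the cohort's isolates")
    rng = config.rng(_STAGE_OUTCOMES)
    iso_ids = [iso.id for iso in cohort.isolates]
    prob = np.empty((len(iso_ids), config.n_phages))
    for row, iso in enumerate(cohort.isolates):
        for j in range(config.n_phages):
            logit = config.baseline_resistance_logit + sum(
                config.system_effects.get(name, (0.0,) * config.n_phages)[j]
                for name in iso.genome_system_names
            )
            prob[row, j] = expit(logit)
    draws = rng.random(prob.shape)
    outcome = np.where(draws < prob, "R", "S")
    truth.probability = pd.DataFrame(
        prob, index=pd.Index(iso_ids, name="isolate_id"), columns=list(config.phage_ids)
    )
    truth.outcome = pd.DataFrame(
        outcome, index=pd.Index(iso_ids, name="isolate_id"), columns=list(config.phage_ids)
    )
    return truth


def _logistic(t: np.ndarray, cp: CurveParams) -> np.ndarray:
    return cp.K / (1.0 + ((cp.K - cp.od0) / cp.od0) * np.exp(-cp.r * t))


def lysis_onset_time(cp: CurveParams) -> float:
    """Lysis onset: a quarter of the way into the noise-free control's
    exponential window, so suppression is visible inside the window.

    The window is detected on a long reference grid (independent of the
    configured horizon) so that slow growth regimes whose exponential
    phase lies beyond the horizon are rejected rather than truncated.
    """
    ref_horizon = max(cp.horizon_h, 48.0)
    times = np.arange(0.0, ref_horizon + cp.sampling_interval_h / 2, cp.sampling_interval_h)
    control = GrowthCurve(times=times, od=_logistic(times, cp), condition="control")
    t0, t1 = detect_exponential_window([control])
    return t0 + 0.25 * (t1 - t0)


def simulate_growth_curves(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[
    dict[tuple[str, str], list[GrowthCurve]], dict[tuple[str, str], SpotTriplicate]
]:
    """Generate triplicate infected/control wells and spot grades per interaction."""
    if not truth.complete:
        raise InputError("simulate interaction outcomes before growth curves")
    cp = config.curve_params
    times = np.arange(0.0, cp.horizon_h + cp.sampling_interval_h / 2, cp.sampling_interval_h)
    t_on = lysis_onset_time(cp)
    if cp.horizon_h <= t_on:
        raise InputError(
            f"horizon {cp.horizon_h} h ends before lysis onset at {t_on:.2f} h"
        )
    base = _logistic(times, cp)
    lysed = base.copy()
    after = times > t_on
    od_on = float(_logistic(np.array([t_on]), cp)[0])
    lysed[after] = cp.lysis_floor + (od_on - cp.lysis_floor) * np.exp(
        -cp.lysis_rate * (times[after] - t_on)
    )
    rng = config.rng(_STAGE_CURVES)
    curves: dict[tuple[str, str], list[GrowthCurve]] = {}
    spots: dict[tuple[str, str], SpotTriplicate] = {}

    def noisy(profile: np.ndarray) -> np.ndarray:
        if cp.noise_sd == 0:
            return profile.copy()
        return np.maximum(profile + rng.normal(0.0, cp.noise_sd, len(profile)), 1e-4)

    for iso_id in truth.outcome.index:
        for phage_id in truth.outcome.columns:
            sensitive = truth.outcome.at[iso_id, phage_id] == "S"
            well: list[GrowthCurve] = []
            for rep in range(3):
                well.append(
                    GrowthCurve(
                        times=times,
                        od=noisy(lysed if sensitive else base),
                        replicate_id=f"rep{rep + 1}",
                        condition="infected",
                    )
                )
            for rep in range(3):
                well.append(
                    GrowthCurve(
                        times=times,
                        od=noisy(base),
                        replicate_id=f"rep{rep + 1}",
                        condition="control",
                    )
                )
            curves[(iso_id, phage_id)] = well
            if sensitive:
                grades = ("clear", "clear", "clear")
            elif rng.random() < 0.7:
                grades = ("none", "none", "none")
            else:  # partial spotting still calls negative (needs all three)
                grades = tuple(
                    rng.permutation(["clear", "none", "none"]).tolist()
                )
            spots[(iso_id, phage_id)] = SpotTriplicate(grades=grades)
    return curves, spots


@dataclass
class SimulationResult:
    config: SimulationConfig
    cohort: Cohort
    truth: GroundTruth
    curves: dict[tuple[str, str], list[GrowthCurve]]
    spots: dict[tuple[str, str], SpotTriplicate]


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Run the three stages in order under one seed."""
    cohort, truth = simulate_cohort(config)
    truth = simulate_interaction_outcomes(cohort, truth, config)
    curves, spots = simulate_growth_curves(truth, config)
    return SimulationResult(config, cohort, truth, curves, spots)


def curves_to_frame(
    curves: dict[tuple[str, str], list[GrowthCurve]]
) -> pd.DataFrame:
    """Flatten curve objects into the long-format CSV dialect."""
    records = []
    for (iso_id, phage_id), well in curves.items():
        for curve in well:
            for t, od in zip(curve.times, curve.od):
                records.append(
                    (iso_id, phage_id, curve.condition, curve.replicate_id, float(t), float(od))
                )
    return pd.DataFrame(records, columns=pfio.CURVE_COLUMNS)


def frame_to_curves(df: pd.DataFrame) -> dict[tuple[str, str], list[GrowthCurve]]:
    """Rebuild curve objects from the long-format table."""
    curves: dict[tuple[str, str], list[GrowthCurve]] = {}
    keys = ["isolate_id", "phage_id", "condition", "replicate_id"]
    for (iso_id, phage_id, condition, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        curves.setdefault((iso_id, phage_id), []).append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(),
                od=grp["od600"].to_numpy(),
                replicate_id=rep,
                condition=condition,
            )
        )
    return curves


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write cohort/catalog/spots/curves/truth in the pipeline's dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.tsv",
        "catalog": outdir / "catalog.tsv",
        "spots": outdir / "spots.tsv",
        "curves": outdir / "curves.csv",
        "truth": outdir / "truth.json",
    }
    pfio.write_cohort_table(result.cohort, paths["cohort"])
    pfio.write_catalog_table(result.cohort.catalog, paths["catalog"])
    pfio.write_spot_table(
        {k: v.grades for k, v in result.spots.items()}, paths["spots"]
    )
    pfio.write_curve_table(curves_to_frame(result.curves), paths["curves"])
    result.truth.to_json(paths["truth"])
    return paths
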