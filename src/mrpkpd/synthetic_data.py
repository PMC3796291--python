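"""Synthetic chronic and acute study generator.

No animal-level data are deposited with the source studies, so this module
generates complete event/observation datasets with the statistical structure
the analysis assumes:

* two chronic 27-day studies (eplerenone: 15/50/450 mg/kg BID; the
  non-steroidal antagonist PF-03882845: 5/15/50 mg/kg BID), each with a
  sham-operated vehicle group and an aldosterone-infused vehicle group,
  n = 11 per group, BID oral dosing at 6 am / 4 pm (alternating 10 h / 14 h
  intervals), sparse PK sampling on Days 1/14/26/27, UACR on Days 0/14/25
  and serum K+ on Days 0/14/27 (terminal sample ~16 h after the final dose);
* two acute urinary Na+/K+ studies (single oral dose, urine collected over
  0-2/2-4/4-7 h and timestamped at the interval midpoints 1/3/5.5 h, plasma
  at 0/1/2/4/7 h).

Aldosterone infusion is not modeled mechanistically: it is encoded as the
disease condition — a below-steady-state UACR baseline (uacr0 < Kin/Kout)
so the untreated trajectory rises toward Kin/Kout — switched on for infused
groups; sham animals sit at their own healthy steady state.  Between-animal
variability is log-normal on absorption, clearance and volume; residual
error is proportional for concentrations and UACR and additive for the
delta-type endpoints.  Turnover/potency truths default to the model
estimates of the source analysis; variability magnitudes are artifact
choices documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .estimation import PkStructure
from .pd_models import _linear_turnover
from .pk_models import (
    ClDoseModel,
    DoseEvent,
    DrugProperties,
    PkParameters,
    conc_on_grid,
    dose_dependent_clearance,
)

__all__ = [
    "StudyDesign",
    "PkPopulation",
    "SimulationTruth",
    "default_truth",
    "generate_chronic_study",
    "generate_acute_study",
    "generate_study_pair",
    "DATASET_COLUMNS",
]

PF, EPL = "PF-03882845", "eplerenone"

DATASET_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "CMT", "DOSE", "GROUP", "DRUG",
]

#: observation compartment codes
CMT_DEPOT, CMT_CONC, CMT_UACR, CMT_SERUM_K, CMT_NA_K = 1, 2, 3, 4, 5

# chronic sampling schedule (hours since first dose)
CHRONIC_CONC_TIMES = (1.0, 2.0, 4.0, 7.0, 319.0, 601.0, 602.0, 604.0, 607.0, 650.0)
CHRONIC_UACR_TIMES = (0.0, 336.0, 600.0)   # Days 0 / 14 / 25
CHRONIC_K_TIMES = (0.0, 319.0, 650.0)      # Days 0 / 14 / 27 (16 h post final dose)
ACUTE_CONC_TIMES = (1.0, 2.0, 4.0, 7.0)
ACUTE_NAK_TIMES = (1.0, 3.0, 5.5)          # midpoints of 0-2 / 2-4 / 4-7 h


@dataclass(frozen=True)
class StudyDesign:
    """One study's arms and sampling schedules."""

    kind: str                    # "chronic" | "acute"
    label: str                   # study tag used in GROUP / subject ids
    drug: str
    dose_levels: tuple[float, ...]
    n_per_group: int = 11
    aldosterone: bool = True
    include_sham: bool = True
    duration_days: float = 27.0
    id_start: int = 101
    conc_times: tuple[float, ...] = CHRONIC_CONC_TIMES
    uacr_times: tuple[float, ...] = CHRONIC_UACR_TIMES
    k_times: tuple[float, ...] = CHRONIC_K_TIMES
    nak_times: tuple[float, ...] = ACUTE_NAK_TIMES

    def __post_init__(self) -> None:
        if self.kind not in ("chronic", "acute"):
            raise ValidationError(f"unknown study kind {self.kind!r}")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")
        if not all(d > 0 for d in self.dose_levels):
            raise ValidationError("dose levels must be > 0")
        horizon = (self.duration_days + 1.0) * 24.0
        times = self.conc_times + self.uacr_times + self.k_times
        if self.kind == "acute":
            times = times + self.nak_times
        if times and max(times) > horizon:
            raise ValidationError("sampling schedule lies outside the study length")

    @property
    def dose_times(self) -> np.ndarray:
        """6 am / 4 pm BID schedule: alternating 10 h / 14 h intervals."""
        if self.kind == "acute":
            return np.array([0.0])
        days = np.arange(int(self.duration_days))
        return np.sort(np.concatenate([days * 24.0, days * 24.0 + 10.0]))

    @property
    def group_names(self) -> list[str]:
        names = []
        if self.kind == "chronic" and self.include_sham:
            names.append("veh-sham")
        names.append("veh-aldo" if self.kind == "chronic" else "veh")
        names += [f"{self.drug}-{d:g}" for d in self.dose_levels]
        return names

    @staticmethod
    def chronic_study_a() -> "StudyDesign":
        return StudyDesign("chronic", "A", EPL, (15.0, 50.0, 450.0), id_start=101)

    @staticmethod
    def chronic_study_b() -> "StudyDesign":
        return StudyDesign("chronic", "B", PF, (5.0, 15.0, 50.0), id_start=201)

    @staticmethod
    def acute_pf() -> "StudyDesign":
        return StudyDesign(
            "acute", "AP", PF, (3.0, 10.0, 30.0),
            n_per_group=10, aldosterone=False, include_sham=False,
            duration_days=1.0, id_start=301,
            conc_times=ACUTE_CONC_TIMES, uacr_times=(), k_times=(),
        )

    @staticmethod
    def acute_epl() -> "StudyDesign":
        return StudyDesign(
            "acute", "AE", EPL, (5.0, 30.0, 300.0),
            n_per_group=10, aldosterone=False, include_sham=False,
            duration_days=1.0, id_start=401,
            conc_times=ACUTE_CONC_TIMES, uacr_times=(), k_times=(),
        )


@dataclass(frozen=True)
class PkPopulation:
    """Population PK truth: typical parameters, structure and variability."""

    typical: PkParameters
    structure: PkStructure
    bsv_cv: dict[str, float] = field(default_factory=dict)  # ka / cl / v1
    cl_dose: ClDoseModel | None = None
    zero_order_duration: float = 0.0


@dataclass(frozen=True)
class TurnoverTruth:
    """Shared turnover constants plus per-drug potency (time unit as noted)."""

    kin: float
    kout: float
    potency: dict[str, float]
    imax: float = 1.0


@dataclass(frozen=True)
class NoiseModel:
    conc_cv: float = 0.15
    uacr_cv: float = 0.20
    k_sd: float = 0.15     # mmol/L
    nak_sd: float = 0.25   # ratio units


@dataclass(frozen=True)
class BaselineTruth:
    uacr0_mean: float = 30.0
    uacr0_cv: float = 0.30
    k_base_mean: float = 4.3       # mmol/L
    k_base_sd: float = 0.25
    k_drift_per_day: float = -0.012  # aldosterone-induced serum K+ decline
    nak_base_mean: float = 3.5
    nak_base_sd: float = 0.5


@dataclass(frozen=True)
class SimulationTruth:
    """Everything the generators need; reproducible given a seed."""

    chronic_pk: dict[str, PkPopulation]
    acute_pk: dict[str, PkPopulation]
    uacr: TurnoverTruth            # rates per day, potency in total nM
    serum_k: TurnoverTruth         # rates per day, potency in total nM
    na_k: TurnoverTruth            # rates per hour, potency on the free/in-vitro scale
    baselines: BaselineTruth = BaselineTruth()
    noise: NoiseModel = NoiseModel()
    drug_props: dict[str, DrugProperties] = field(default_factory=dict)
    seed: int = 0

    def without_variability(self) -> "SimulationTruth":
        """Copy with all residual noise and between-animal variability off."""
        chronic = {
            k: replace(v, bsv_cv={}, cl_dose=v.cl_dose and replace(v.cl_dose, eta=0.0))
            for k, v in self.chronic_pk.items()
        }
        acute = {
            k: replace(v, bsv_cv={}, cl_dose=v.cl_dose and replace(v.cl_dose, eta=0.0))
            for k, v in self.acute_pk.items()
        }
        return replace(
            self,
            chronic_pk=chronic,
            acute_pk=acute,
            noise=NoiseModel(0.0, 0.0, 0.0, 0.0),
            baselines=replace(
                self.baselines, uacr0_cv=0.0, k_base_sd=0.0, nak_base_sd=0.0
            ),
        )


def default_truth() -> SimulationTruth:
    """Study conditions used throughout the package.

    Potency truths are the model estimates of the source analysis (UACR
    IC50: 10.4 nM PF-03882845, 671 nM eplerenone; serum-K+ EC50: 874 and
    988 nM total; acute normalized EC50: 3.10 and 5.92).  Turnover rates,
    PK typical values and variability magnitudes are artifact choices (see
    the methods note): the untreated aldosterone trajectory roughly triples
    UACR by Day 26.
    """
    chronic_pk = {
        PF: PkPopulation(
            typical=PkParameters(
                ka=1.2, cl_initial=1.6, v1=3.0, cl_induced=3.2, q=0.8, v2=3.0
            ),
            structure=PkStructure(
                n_compartments=2, induction=True, fixed={"q": 0.8, "v2": 3.0}
            ),
            bsv_cv={"ka": 0.25, "cl": 0.25, "v1": 0.20},
        ),
        EPL: PkPopulation(
            typical=PkParameters(ka=0.8, cl_initial=2.5, v1=4.0, cl_induced=4.0),
            structure=PkStructure(n_compartments=1, induction=True),
            bsv_cv={"ka": 0.25, "cl": 0.25, "v1": 0.20},
        ),
    }
    acute_pk = {
        PF: PkPopulation(
            typical=PkParameters(ka=1.5, cl_initial=2.0, v1=4.0),
            structure=PkStructure(n_compartments=1),
            bsv_cv={"ka": 0.25, "cl": 0.25, "v1": 0.20},
        ),
        EPL: PkPopulation(
            typical=PkParameters(ka=1.0, cl_initial=3.0, v1=1.5, q=1.0, v2=3.0),
            structure=PkStructure(
                n_compartments=2, absorption="zero_order",
                fixed={"q": 1.0, "v2": 3.0},
            ),
            bsv_cv={"cl": 0.25, "v1": 0.20},
            cl_dose=ClDoseModel(theta1=3.0, pwr=0.25),
            zero_order_duration=1.0,
        ),
    }
    return SimulationTruth(
        chronic_pk=chronic_pk,
        acute_pk=acute_pk,
        uacr=TurnoverTruth(kin=7.9, kout=0.08, imax=0.95,
                           potency={PF: 10.4, EPL: 671.0}),
        serum_k=TurnoverTruth(kin=0.22, kout=0.35, potency={PF: 874.0, EPL: 988.0}),
        na_k=TurnoverTruth(kin=0.9, kout=0.30, potency={PF: 3.10, EPL: 5.92}),
        drug_props={
            PF: DrugProperties(fu=0.0038, ic50_invitro=0.75, nmol_per_mg=2286.0),
            EPL: DrugProperties(fu=0.68, ic50_invitro=109.0, nmol_per_mg=2413.0),
        },
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _sample_subject_pk(
    rng: np.random.Generator, pop: PkPopulation, dose_level: float
) -> PkParameters:
    fka = _lognormal_factor(rng, pop.bsv_cv.get("ka", 0.0))
    fcl = _lognormal_factor(rng, pop.bsv_cv.get("cl", 0.0))
    fv = _lognormal_factor(rng, pop.bsv_cv.get("v1", 0.0))
    t = pop.typical
    if pop.cl_dose is not None and dose_level > 0:
        eta = float(np.log(fcl))
        cl = dose_dependent_clearance(replace(pop.cl_dose, eta=eta), dose_level)
        cl_ind = None
    else:
        cl = t.cl_initial * fcl
        cl_ind = None if t.cl_induced is None else t.cl_induced * fcl
    return replace(t, ka=t.ka * fka, cl_initial=cl, cl_induced=cl_ind, v1=t.v1 * fv)


def _prop_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return values.copy()
    noisy = values * (1.0 + rng.normal(0.0, cv, size=values.shape))
    return np.maximum(noisy, 0.01 * values)


def _add_noise(rng: np.random.Generator, values: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return values.copy()
    return values + rng.normal(0.0, sd, size=values.shape)


def _row(i, t, amt, rate, dv, evid, mdv, cmt, dose, group, drug):
    return {
        "ID": i, "TIME": t, "AMT": amt, "RATE": rate, "DV": dv, "EVID": evid,
        "MDV": mdv, "CMT": cmt, "DOSE": dose, "GROUP": group, "DRUG": drug,
    }


def _finish(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def generate_chronic_study(
    design: StudyDesign, truth: SimulationTruth, seed
) -> pd.DataFrame:
    """Event/observation dataset for one chronic 27-day study."""
    if design.kind != "chronic":
        raise ValidationError("generate_chronic_study needs a chronic design")
    rng = np.random.default_rng(seed)
    pop = truth.chronic_pk[design.drug]
    props = truth.drug_props[design.drug]
    base, noise = truth.baselines, truth.noise
    uacr_t, k_t = truth.uacr, truth.serum_k
    kin_h, kout_h = uacr_t.kin / 24.0, uacr_t.kout / 24.0
    kink_h, koutk_h = k_t.kin / 24.0, k_t.kout / 24.0
    ic50 = uacr_t.potency[design.drug]
    ec50 = k_t.potency[design.drug]

    grid = np.round(np.arange(0.0, 650.0 + 1e-9, 0.1), 10)
    conc_idx = np.searchsorted(grid, design.conc_times)
    uacr_idx = np.searchsorted(grid, design.uacr_times)
    k_idx = np.searchsorted(grid, design.k_times)
    dose_times = design.dose_times

    rows: list[dict] = []
    sid = design.id_start
    for gi, gname in enumerate(design.group_names):
        sham = gname == "veh-sham"
        dose = 0.0 if gname.startswith("veh") else design.dose_levels[gi - 1 - int(design.include_sham)]
        treated = dose > 0
        group = f"{design.label}/{gname}"
        for _ in range(design.n_per_group):
            pk = _sample_subject_pk(rng, pop, dose)
            u0 = base.uacr0_mean * _lognormal_factor(rng, base.uacr0_cv)
            k0 = base.k_base_mean + (rng.normal(0.0, base.k_base_sd) if base.k_base_sd > 0 else 0.0)
            drug = design.drug if treated else None

            if treated:
                doses = [DoseEvent(t, dose, drug=drug, subject=sid) for t in dose_times]
                conc = conc_on_grid(pk, doses, grid, nmol_per_mg=props.nmol_per_mg)
            else:
                conc = np.zeros_like(grid)

            # UACR trajectory (opaque units)
            if sham:
                uacr = np.full_like(grid, u0)
            else:
                inh = 1.0 - uacr_t.imax * conc / (conc + ic50)
                uacr = u0 * np.exp(-kout_h * grid) + kin_h * _linear_turnover(
                    inh, grid, kout_h
                )
            # serum K+ (mmol/L): baseline + disease drift + drug effect
            drift = 0.0 if sham else base.k_drift_per_day / 24.0
            delta_k = kink_h * _linear_turnover(conc / (conc + ec50), grid, koutk_h)
            serum_k = k0 + drift * grid + delta_k

            if treated:
                for t in dose_times:
                    rows.append(_row(sid, t, dose, 0.0, np.nan, 1, 1, CMT_DEPOT,
                                     dose, group, drug))
                dv = _prop_noise(rng, conc[conc_idx], noise.conc_cv)
                for t, v in zip(design.conc_times, dv):
                    rows.append(_row(sid, t, np.nan, np.nan, v, 0, 0, CMT_CONC,
                                     dose, group, drug))
            dv = _prop_noise(rng, uacr[uacr_idx], noise.uacr_cv)
            for t, v in zip(design.uacr_times, dv):
                rows.append(_row(sid, t, np.nan, np.nan, v, 0, 0, CMT_UACR,
                                 dose, group, drug))
            dv = _add_noise(rng, serum_k[k_idx], noise.k_sd)
            for t, v in zip(design.k_times, dv):
                rows.append(_row(sid, t, np.nan, np.nan, v, 0, 0, CMT_SERUM_K,
                                 dose, group, drug))
            sid += 1
    return _finish(rows)


def generate_acute_study(
    design: StudyDesign, truth: SimulationTruth, seed
) -> pd.DataFrame:
    """Single-dose urinary Na+/K+ study with plasma sampling."""
    if design.kind != "acute":
        raise ValidationError("generate_acute_study needs an acute design")
    rng = np.random.default_rng(seed)
    pop = truth.acute_pk[design.drug]
    props = truth.drug_props[design.drug]
    base, noise = truth.baselines, truth.noise
    nak = truth.na_k
    ec50 = nak.potency[design.drug]

    grid = np.round(np.arange(0.0, 7.0 + 1e-9, 0.01), 10)
    conc_idx = np.searchsorted(grid, design.conc_times)
    nak_idx = np.searchsorted(grid, design.nak_times)

    rows: list[dict] = []
    sid = design.id_start
    for gi, gname in enumerate(design.group_names):
        dose = 0.0 if gname.startswith("veh") else design.dose_levels[gi - 1]
        treated = dose > 0
        group = f"{design.label}/{gname}"
        for _ in range(design.n_per_group):
            pk = _sample_subject_pk(rng, pop, dose)
            nak0 = base.nak_base_mean + (
                rng.normal(0.0, base.nak_base_sd) if base.nak_base_sd > 0 else 0.0
            )
            drug = design.drug if treated else None
            if treated:
                dur = pop.zero_order_duration
                doses = [DoseEvent(0.0, dose, duration=dur, drug=drug, subject=sid)]
                conc = conc_on_grid(pk, doses, grid, nmol_per_mg=props.nmol_per_mg)
            else:
                conc = np.zeros_like(grid)

            drive = props.fu * conc / props.ic50_invitro
            delta = nak.kin * _linear_turnover(drive / (drive + ec50), grid, nak.kout)
            ratio = nak0 + delta

            if treated:
                dur = pop.zero_order_duration
                rate = dose / dur if dur > 0 else 0.0
                cmt = CMT_CONC if dur > 0 else CMT_DEPOT
                rows.append(_row(sid, 0.0, dose, rate, np.nan, 1, 1, cmt,
                                 dose, group, drug))
                # pre-dose plasma sample: below quantification, not fitted
                rows.append(_row(sid, 0.0, np.nan, np.nan, np.nan, 0, 1, CMT_CONC,
                                 dose, group, drug))
                dv = _prop_noise(rng, conc[conc_idx], noise.conc_cv)
                for t, v in zip(design.conc_times, dv):
                    rows.append(_row(sid, t, np.nan, np.nan, v, 0, 0, CMT_CONC,
                                     dose, group, drug))
            obs_t = (0.0,) + tuple(design.nak_times)
            vals = np.concatenate([[nak0], ratio[nak_idx]])
            dv = _add_noise(rng, vals, noise.nak_sd)
            for t, v in zip(obs_t, dv):
                rows.append(_row(sid, t, np.nan, np.nan, v, 0, 0, CMT_NA_K,
                                 dose, group, drug))
            sid += 1
    return _finish(rows)


def generate_study_pair(kind: str, truth: SimulationTruth, seed) -> pd.DataFrame:
    """Both drugs' studies of one kind, combined (as the pooled fits need)."""
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    if kind == "chronic":
        a = generate_chronic_study(StudyDesign.chronic_study_a(), truth, child_a)
        b = generate_chronic_study(StudyDesign.chronic_study_b(), truth, child_b)
    elif kind == "acute":
        a = generate_acute_study(StudyDesign.acute_epl(), truth, child_a)
        b = generate_acute_study(StudyDesign.acute_pf(), truth, child_b)
    else:
        raise ValidationError(f"unknown study kind {kind!r}")
    return pd.concat([a, b], ignore_index=True)
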