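"""Two-stage (piece-wise) population estimation.

Stage 1 fits each animal's pharmacokinetic parameters from its own
dose/concentration records (maximum likelihood under a proportional residual
error model, implemented as observation-weighted least squares on
log-transformed parameters).  Stage 2 fixes those individual PK parameters
and fits the pharmacodynamic systems to BOTH drugs' data simultaneously:
the system constants (Kin or Kin_max, Kout, Imax) are shared across drugs
and only the potency (IC50/EC50) is drug-specific.  Per-animal UACR
baselines are profiled out in closed form (the turnover ODE is linear, so
the prediction is affine in the baseline).

Confidence intervals are asymptotic (curvature-based) by default;
``bootstrap_ci`` provides case-resampling percentile intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import EstimationError, ValidationError
from .pd_models import _linear_turnover, double_delta, vehicle_reference
from .pk_models import (
    ClDoseModel,
    DoseEvent,
    DrugProperties,
    PkParameters,
    _run_skeleton,
    _segment_clearances,
    _Skeleton,
)

__all__ = [
    "ResidualErrorModel",
    "FitResult",
    "PkStructure",
    "SubjectPk",
    "BootstrapResult",
    "fit_pk_individual",
    "fit_pd_pooled",
    "bootstrap_ci",
]

#: CMT codes of the observation records (see io module docs)
CMT_CONC, CMT_UACR, CMT_SERUM_K, CMT_NA_K = 2, 3, 4, 5

_ENDPOINT_CMT = {"uacr": CMT_UACR, "delta_serum_k": CMT_SERUM_K, "delta_na_k": CMT_NA_K}
_HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ResidualErrorModel:
    """Residual error specification for one endpoint."""

    kind: str = "proportional"  # "proportional" | "additive"
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive"):
            raise ValidationError(f"unknown residual error kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass
class FitResult:
    """Estimates, objective, CIs and diagnostics of one fit."""

    params: dict[str, float]
    objective: float
    ci: dict[str, tuple[float, float]]
    converged: bool
    seed: int | None
    n_subjects: int
    n_obs: int
    message: str = ""
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PkStructure:
    """Choice of PK model structure for a stage-1 fit.

    ``fixed`` holds parameters held constant (e.g. ``q``/``v2`` fixed at
    population values when per-animal data are too sparse — mirroring the
    parameter fixing used in the unified acute-study shell).
    """

    n_compartments: int = 1
    absorption: str = "first_order"  # "first_order" | "zero_order"
    induction: bool = False
    induction_window: tuple[float, float] = (24.0, 168.0)  # h
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValidationError("n_compartments must be 1 or 2")
        if self.absorption not in ("first_order", "zero_order"):
            raise ValidationError(f"unknown absorption {self.absorption!r}")

    @property
    def free_names(self) -> list[str]:
        names = []
        if self.absorption == "first_order":
            names.append("ka")
        names += ["cl", "v1"]
        if self.induction:
            names.append("cl_fold")
        if self.n_compartments == 2:
            names += ["q", "v2"]
        return [n for n in names if n not in self.fixed]


@dataclass(frozen=True)
class SubjectPk:
    """Fixed individual PK carried from stage 1 into stage 2."""

    params: PkParameters
    nmol_per_mg: float = 1.0
    cl_dose: ClDoseModel | None = None


@dataclass
class BootstrapResult:
    ci: dict[str, tuple[float, float]]
    replicates: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def doses_from_records(rows: pd.DataFrame) -> list[DoseEvent]:
    """Dose events (amounts in mg/kg) from EVID == 1 rows of one subject."""
    out = []
    for r in rows.itertuples():
        dur = r.AMT / r.RATE if r.RATE and r.RATE > 0 else 0.0
        out.append(DoseEvent(time=r.TIME, amount=r.AMT, duration=dur))
    return out


def _params_from_theta(theta: dict[str, float], structure: PkStructure) -> PkParameters:
    get = lambda k, d=None: theta.get(k, structure.fixed.get(k, d))
    cl = get("cl")
    fold = get("cl_fold", 1.0) if structure.induction else None
    return PkParameters(
        ka=get("ka", 1.0),
        cl_initial=cl,
        v1=get("v1"),
        cl_induced=None if fold is None else cl * fold,
        induction_start=structure.induction_window[0],
        induction_end=structure.induction_window[1],
        q=get("q", 0.0) if structure.n_compartments == 2 else 0.0,
        v2=get("v2", 0.0) if structure.n_compartments == 2 else 0.0,
    )


def _safe_exp(x: float) -> float:
    return float(np.exp(np.clip(x, -745.0, 709.0)))


def _asymptotic_ci(res, names: list[str], n_obs: int) -> dict[str, tuple[float, float]]:
    """95% CI on the natural scale from the log-scale Jacobian."""
    p = len(names)
    dof = max(n_obs - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        jtj = res.jac.T @ res.jac
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    ci = {}
    for i, name in enumerate(names):
        lo, hi = res.x[i] - 1.96 * se[i], res.x[i] + 1.96 * se[i]
        ci[name] = (lo, hi)
    return ci


def _multistart(
    objective: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    restarts: int,
    seed: int | None,
    jitter_sd: float = 0.25,
):
    rng = np.random.default_rng(0 if seed is None else seed)
    best = None
    for k in range(max(restarts, 1)):
        xk = x0 if k == 0 else x0 + rng.normal(0.0, jitter_sd, size=x0.size)
        try:
            res = least_squares(objective, xk, method="lm", max_nfev=400 * x0.size)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise EstimationError("all optimization starts failed")
    return best


# ---------------------------------------------------------------------------
# stage 1: individual PK
# ---------------------------------------------------------------------------


def fit_pk_individual(
    data: pd.DataFrame,
    structure: PkStructure,
    error: ResidualErrorModel,
    init: Mapping[str, float],
    *,
    nmol_per_mg: float = 1.0,
    restarts: int = 1,
    seed: int | None = None,
) -> FitResult:
    """Fit one animal's PK parameters from its dose + concentration records.

    ``data`` holds the io-schema rows of a single subject.  Proportional
    residual error is realized as observation-weighted least squares,
    ``r = (obs - pred) / obs``, on log-transformed parameters.
    """
    if error.kind != "proportional":
        raise ValidationError("PK fits use a proportional residual error model")
    ids = data["ID"].unique()
    if len(ids) != 1:
        raise EstimationError(f"expected records of one subject, got {len(ids)}")
    doses = doses_from_records(data[data["EVID"] == 1])
    obs_rows = data[(data["EVID"] == 0) & (data["CMT"] == CMT_CONC) & (data["MDV"] == 0)]
    t_obs = obs_rows["TIME"].to_numpy(float)
    y_obs = obs_rows["DV"].to_numpy(float)
    if np.any(y_obs <= 0):
        raise ValidationError("non-positive concentration observations")
    order = np.argsort(t_obs)
    t_obs, y_obs = t_obs[order], y_obs[order]

    names = structure.free_names
    if t_obs.size < len(names):
        raise EstimationError(
            f"under-determined fit: {t_obs.size} observations for "
            f"{len(names)} free parameters {names}"
        )
    if not doses:
        raise EstimationError("no dose events for this subject")
    missing = [n for n in names if n not in init]
    if missing:
        raise ValidationError(f"missing initial values for {missing}")

    window = structure.induction_window if structure.induction else None
    skel = _Skeleton(doses, t_obs, window, ramp_substep=0.5, nmol_per_mg=nmol_per_mg)

    def predict(theta: dict[str, float]) -> np.ndarray:
        params = _params_from_theta(theta, structure)
        cl_seg = _segment_clearances(skel, params, None, None)
        return _run_skeleton(skel, params, cl_seg)

    def objective(x: np.ndarray) -> np.ndarray:
        theta = dict(zip(names, np.exp(x)))
        pred = predict(theta)
        return (pred - y_obs) / y_obs

    x0 = np.log([init[n] for n in names])
    res = _multistart(objective, x0, restarts, seed)

    theta = dict(zip(names, np.exp(res.x)))
    params = dict(theta)
    for k, v in structure.fixed.items():
        params[k] = v
    if structure.induction:
        params["cl_induced"] = params["cl"] * params["cl_fold"]
    ci_log = _asymptotic_ci(res, names, t_obs.size)
    ci = {n: (_safe_exp(lo), _safe_exp(hi)) for n, (lo, hi) in ci_log.items()}
    return FitResult(
        params=params,
        objective=2.0 * res.cost,
        ci=ci,
        converged=bool(res.status > 0 and np.isfinite(res.cost)),
        seed=seed,
        n_subjects=1,
        n_obs=int(t_obs.size),
        message=res.message,
        extra={"subject": int(ids[0]), "free_names": names},
    )


def subject_pk_from_fit(
    fit: FitResult, structure: PkStructure, nmol_per_mg: float
) -> SubjectPk:
    """Package a stage-1 fit into the fixed-PK carrier for stage 2."""
    theta = {k: v for k, v in fit.params.items() if k != "cl_induced"}
    return SubjectPk(
        params=_params_from_theta(theta, structure), nmol_per_mg=nmol_per_mg
    )


# ---------------------------------------------------------------------------
# stage 2: pooled PD
# ---------------------------------------------------------------------------


def _is_sham(group: str) -> bool:
    return isinstance(group, str) and "sham" in group.lower()


def _snap_to_grid(t: np.ndarray, h: float) -> np.ndarray:
    idx = np.round(t / h).astype(int)
    if np.any(np.abs(idx * h - t) > 1e-6 * np.maximum(1.0, np.abs(t))):
        raise ValidationError(
            "observation times do not lie on the PD evaluation grid; "
            "choose a grid_step that divides the sampling times"
        )
    return idx


def _conc_matrix(
    subjects: list[int],
    data: pd.DataFrame,
    pk: Mapping[int, SubjectPk],
    t_grid: np.ndarray,
) -> np.ndarray:
    conc = np.zeros((len(subjects), t_grid.size))
    for i, sid in enumerate(subjects):
        rows = data[data["ID"] == sid]
        doses = doses_from_records(rows[rows["EVID"] == 1])
        if not doses:
            continue  # vehicle animal: zero drive
        spk = pk.get(sid)
        if spk is None:
            raise ValidationError(f"no PK parameters supplied for subject {sid}")
        window = (
            (spk.params.induction_start, spk.params.induction_end)
            if spk.params.has_induction and spk.cl_dose is None
            else None
        )
        skel = _Skeleton(doses, t_grid, window, 0.5, spk.nmol_per_mg * spk.params.f)
        level = doses[0].amount if spk.cl_dose is not None else None
        cl_seg = _segment_clearances(skel, spk.params, spk.cl_dose, level)
        conc[i] = _run_skeleton(skel, spk.params, cl_seg)
    return np.maximum(conc, 0.0)


def fit_pd_pooled(
    data: pd.DataFrame,
    pk: Mapping[int, SubjectPk],
    endpoint: str,
    init: Mapping[str, float],
    *,
    drug_props: Mapping[str, DrugProperties] | None = None,
    seed: int | None = 0,
    restarts: int = 5,
    grid_step: float = 0.1,
    rate_unit: str | None = None,
) -> FitResult:
    """Pooled two-drug fit of one PD endpoint with fixed individual PK.

    Parameters
    ----------
    data : DataFrame
        io-schema records of one or more studies (both drugs required).
    pk : mapping of subject id -> SubjectPk
        Stage-1 individual PK, held fixed.
    endpoint : {"uacr", "delta_serum_k", "delta_na_k"}
        ``uacr`` fits the inhibited-input turnover to raw UACR with
        per-animal profiled baselines and proportional error (vehicle
        aldosterone animals enter with zero drive; sham animals are
        excluded).  The delta endpoints apply the double-delta transform
        against the pooled vehicle reference and fit the stimulated-input
        turnover with additive error.  ``delta_na_k`` drives the model with
        free concentration normalized to in vitro potency (requires
        ``drug_props``); the others use total plasma concentration.
    rate_unit : {"day", "hour"}, optional
        Unit of the reported turnover rates; defaults to days for the
        chronic endpoints and hours for the acute urinary endpoint.
    """
    if endpoint not in _ENDPOINT_CMT:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    cmt = _ENDPOINT_CMT[endpoint]
    if rate_unit is None:
        rate_unit = "hour" if endpoint == "delta_na_k" else "day"
    if rate_unit not in ("day", "hour"):
        raise ValidationError("rate_unit must be 'day' or 'hour'")
    unit = _HOURS_PER_DAY if rate_unit == "day" else 1.0

    keep = data[~data["GROUP"].map(_is_sham)]
    obs = keep[(keep["EVID"] == 0) & (keep["CMT"] == cmt) & (keep["MDV"] == 0)]
    if obs.empty:
        raise EstimationError(f"no observations for endpoint {endpoint!r}")
    subj_drug = (
        keep[keep["EVID"] == 1].groupby("ID")["DRUG"].first().to_dict()
    )  # dosed subjects only
    drugs = sorted({d for d in subj_drug.values() if isinstance(d, str)})
    if len(drugs) < 2:
        raise EstimationError(
            "the shared-parameter fit needs both drugs' data; got " + repr(drugs)
        )
    if endpoint == "delta_na_k" and drug_props is None:
        raise ValidationError("delta_na_k requires drug_props for the free drive")

    # assemble per-subject observation series
    if endpoint == "uacr":
        subjects = sorted(obs["ID"].unique())  # treated + vehicle-aldo
        series = {
            sid: g.sort_values("TIME")[["TIME", "DV"]].to_numpy(float)
            for sid, g in obs.groupby("ID")
        }
    else:
        veh_ids = [sid for sid in obs["ID"].unique() if sid not in subj_drug]
        trt_ids = [sid for sid in obs["ID"].unique() if sid in subj_drug]
        if not veh_ids:
            raise EstimationError("no vehicle animals for the double-delta reference")
        ref = vehicle_reference(obs[obs["ID"].isin(veh_ids)])
        series = {}
        for sid in sorted(trt_ids):
            g = obs[obs["ID"] == sid].sort_values("TIME")[["TIME", "DV"]]
            dd = double_delta(g.to_numpy(float), ref, subject=sid, endpoint=endpoint)
            m = dd.times > 0  # the time-0 delta is identically zero
            series[sid] = np.column_stack([dd.times[m], dd.values[m]])
        subjects = sorted(series)

    t_max = max(float(s[:, 0].max()) for s in series.values())
    n_steps = int(round(t_max / grid_step))
    t_grid = np.linspace(0.0, n_steps * grid_step, n_steps + 1)
    conc = _conc_matrix(subjects, keep, pk, t_grid)

    # drive transform and per-subject drug index
    drug_of = np.array(
        [drugs.index(subj_drug[sid]) if sid in subj_drug else -1 for sid in subjects]
    )
    if endpoint == "delta_na_k":
        scale = np.ones(len(subjects))
        for i, sid in enumerate(subjects):
            if drug_of[i] >= 0:
                props = drug_props[drugs[drug_of[i]]]
                scale[i] = props.fu / props.ic50_invitro
        conc = conc * scale[:, None]

    # flatten observations
    sub_idx, time_idx, y_obs = [], [], []
    for i, sid in enumerate(subjects):
        s = series[sid]
        sub_idx.append(np.full(s.shape[0], i))
        time_idx.append(_snap_to_grid(s[:, 0], grid_step))
        y_obs.append(s[:, 1])
    sub_idx = np.concatenate(sub_idx)
    time_idx = np.concatenate(time_idx)
    y_obs = np.concatenate(y_obs)
    n_subj = len(subjects)

    pot_key = "ic50" if endpoint == "uacr" else "ec50"
    if endpoint == "uacr":
        shared = ["kin", "kout", "imax"]
    else:
        shared = ["kin_max", "kout"]
    names = shared + [f"{pot_key}_{d}" for d in drugs]
    missing = [n for n in names if n not in init and n.split("_")[0] != pot_key]
    missing += [
        f"{pot_key}_{d}" for d in drugs
        if f"{pot_key}_{d}" not in init and pot_key not in init
    ]
    if missing:
        raise ValidationError(f"missing initial values for {missing}")

    def transform(x: np.ndarray) -> dict[str, float]:
        theta = {}
        for name, xi in zip(names, x):
            if name == "imax":
                theta[name] = 1.0 / (1.0 + math.exp(-xi))
            else:
                theta[name] = math.exp(xi)
        return theta

    def x_init() -> np.ndarray:
        x = []
        for name in names:
            v = init.get(name, init.get(pot_key))
            if name == "imax":
                v = min(max(v, 1e-6), 1 - 1e-6)
                x.append(math.log(v / (1 - v)))
            else:
                x.append(math.log(v))
        return np.asarray(x)

    uacr0_store: dict[str, np.ndarray] = {}

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = transform(x)
        kout_h = theta["kout"] / unit
        pot = np.array([theta[f"{pot_key}_{d}"] for d in drugs])
        pot_sub = np.where(drug_of >= 0, pot[np.maximum(drug_of, 0)], 1.0)[:, None]
        if endpoint == "uacr":
            kin_h = theta["kin"] / unit
            drive = 1.0 - theta["imax"] * conc / (conc + pot_sub)
            b = kin_h * _linear_turnover(drive, t_grid, kout_h)
            a = np.exp(-kout_h * t_grid)
            a_t = a[time_idx]
            b_t = b[sub_idx, time_idx]
            w2 = y_obs**2
            num = np.bincount(sub_idx, a_t * (y_obs - b_t) / w2, minlength=n_subj)
            den = np.bincount(sub_idx, a_t**2 / w2, minlength=n_subj)
            u0 = np.maximum(num / np.maximum(den, 1e-300), 1e-9)
            uacr0_store["u0"] = u0
            pred = u0[sub_idx] * a_t + b_t
            return (pred - y_obs) / y_obs
        kin_h = theta["kin_max"] / unit
        drive = conc / (conc + pot_sub)
        y = kin_h * _linear_turnover(drive, t_grid, kout_h)
        pred = y[sub_idx, time_idx]
        return pred - y_obs

    res = _multistart(residuals, x_init(), restarts, seed)
    theta = transform(res.x)
    ci_x = _asymptotic_ci(res, names, y_obs.size)
    ci = {}
    for name, (lo, hi) in ci_x.items():
        if name == "imax":
            ci[name] = (1 / (1 + _safe_exp(-lo)), 1 / (1 + _safe_exp(-hi)))
        else:
            ci[name] = (_safe_exp(lo), _safe_exp(hi))
    extra: dict = {"drugs": drugs, "endpoint": endpoint, "rate_unit": rate_unit}
    if endpoint == "uacr":
        residuals(res.x)  # refresh profiled baselines at the optimum
        extra["uacr0"] = dict(zip(subjects, uacr0_store["u0"]))
    return FitResult(
        params=theta,
        objective=2.0 * res.cost,
        ci=ci,
        converged=bool(res.status > 0 and np.isfinite(res.cost)),
        seed=seed,
        n_subjects=n_subj,
        n_obs=int(y_obs.size),
        message=res.message,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    fit: Callable[[pd.DataFrame], FitResult],
    data: pd.DataFrame,
    n_boot: int,
    seed: int,
    *,
    id_col: str = "ID",
    group_col: str = "GROUP",
    level: float = 0.95,
) -> BootstrapResult:
    """Case-resampling percentile CIs: subjects resampled within group.

    ``fit`` maps a resampled dataset to a FitResult; resampled subjects are
    assigned fresh unique ids so a subject drawn twice contributes twice.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    groups = {
        g: sorted(d[id_col].unique()) for g, d in data.groupby(group_col, dropna=False)
    }
    by_id = {sid: d for sid, d in data.groupby(id_col)}
    rows = []
    for _ in range(n_boot):
        parts = []
        new_id = 1
        for g in sorted(groups, key=str):
            ids = groups[g]
            draw = rng.choice(ids, size=len(ids), replace=True)
            for sid in draw:
                part = by_id[sid].copy()
                part[id_col] = new_id
                new_id += 1
                parts.append(part)
        result = fit(pd.concat(parts, ignore_index=True))
        rows.append(result.params)
    reps = pd.DataFrame(rows)
    alpha = (1.0 - level) / 2.0
    ci = {
        c: (
            float(np.quantile(reps[c], alpha)),
            float(np.quantile(reps[c], 1 - alpha)),
        )
        for c in reps.columns
    }
    return BootstrapResult(ci=ci, replicates=reps, seed=seed)
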