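"""Dataset reading/writing and run configuration.

Datasets use a NONMEM-style rectangular layout as comma-delimited text with
a fixed header::

    ID,TIME,AMT,RATE,DV,EVID,MDV,CMT,DOSE,GROUP,DRUG

* ``EVID`` 1 = dose event (no DV), 0 = observation;
* ``RATE`` > 0 marks zero-order input (duration = AMT/RATE), 0/missing a
  first-order depot dose;
* ``MDV`` 1 = DV missing/not fitted;
* ``CMT`` codes: 1 depot dose, 2 plasma concentration (nM), 3 UACR
  (opaque units), 4 serum K+ (mmol/L), 5 urinary Na+/K+ ratio;
* ``DOSE`` group dose level (mg/kg, 0 for vehicle), ``GROUP`` study/arm
  label, ``DRUG`` drug id or missing for vehicle animals.

Missing values are ".".  Times are hours; the decimal dialect is fixed
(comma delimiter, point decimal — no sniffing).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .errors import DatasetError
from .synthetic_data import DATASET_COLUMNS

__all__ = ["read_dataset", "write_dataset", "RunConfig", "DATASET_COLUMNS"]

_NUMERIC = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "CMT", "DOSE"]


def read_dataset(path) -> pd.DataFrame:
    """Read and validate an event/observation table.

    Raises :class:`DatasetError` naming the offending column/subject on
    schema violations: unknown or missing columns, non-monotone times
    within a subject, or a dose row carrying a DV.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["."], keep_default_na=False, dtype=str)
    unknown = [c for c in df.columns if c not in DATASET_COLUMNS]
    if unknown:
        raise DatasetError(f"unknown column(s) {unknown} in {path.name}")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing column(s) {missing} in {path.name}")
    if len(df) == 0:
        raise DatasetError(f"{path.name} contains a header but no records")
    out = pd.DataFrame()
    for c in _NUMERIC:
        try:
            out[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"non-numeric value in column {c}: {exc}") from None
    out["GROUP"] = df["GROUP"]
    out["DRUG"] = df["DRUG"].where(df["DRUG"].notna(), None)
    out = out[DATASET_COLUMNS]
    for c in ("ID", "EVID", "MDV", "CMT"):
        out[c] = out[c].astype(int)
    _validate_semantics(out)
    return out


def _validate_semantics(df: pd.DataFrame) -> None:
    for sid, g in df.groupby("ID"):
        t = g["TIME"].to_numpy(float)
        if not (t[1:] >= t[:-1] - 1e-12).all():
            raise DatasetError(f"non-monotone times within subject {sid}")
    bad = df[(df["EVID"] == 1) & df["DV"].notna()]
    if len(bad):
        raise DatasetError(
            f"dose rows carrying a DV for subject(s) {sorted(bad['ID'].unique())}"
        )


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, (int,)) and not isinstance(v, bool):
        return str(v)
    if isinstance(v, float) or hasattr(v, "dtype"):
        v = float(v)
        if math.isnan(v):
            return "."
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)
    return str(v)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset in the fixed dialect ('.' for missing, lossless
    shortest-round-trip float formatting)."""
    path = Path(path)
    lines = [",".join(DATASET_COLUMNS)]
    for row in df[DATASET_COLUMNS].itertuples(index=False):
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


class EstimationSettings(BaseModel):
    restarts_pk: int = 1
    restarts_pd: int = 5
    grid_step_chronic: float = Field(0.1, gt=0)   # h
    grid_step_acute: float = Field(0.01, gt=0)     # h
    n_boot: int = 0          # 0 disables bootstrap TI CIs (>= 100 to report)


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (times in config may be days;
    converted to hours at parse time by the consuming code)."""

    seed: int = 0
    kind: str = "chronic"
    outdir: str = "results"
    dataset: str | None = None   # fit an existing dataset instead of simulating
    noise_off: bool = False
    estimation: EstimationSettings = EstimationSettings()

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return RunConfig(**payload)
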