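"""Therapeutic-index calculus and potency normalization.

The chain of corrections applied to a model-estimated potency (total plasma
concentration scale) is:

* ``fEC50 = EC50 * fu`` — correct for plasma protein binding;
* ``fEC50 / in-vitro IC50`` — normalize to receptor potency, making values
  comparable across drugs;
* ``TI = (normalized serum-K+ potency) / (normalized UACR potency)`` — the
  safety margin between the adverse (hyperkalemia) and desired (UACR
  lowering) effects.

Within one drug the unbound fraction and the in vitro potency cancel in the
TI ratio, so the TI algebraically equals the ratio of the raw total-plasma
EC50s; the implementation asserts this identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pk_models import DrugProperties

__all__ = [
    "TiResult",
    "free_ec50",
    "potency_normalized",
    "therapeutic_index",
    "fold_difference",
    "ti_confidence_interval",
    "sig_figs",
    "build_ti_table",
]


def sig_figs(x: float, n: int = 3) -> float:
    """Round to ``n`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, n - 1 - int(math.floor(math.log10(abs(x)))))


def free_ec50(ec50_total: float, fu: float) -> float:
    """Protein-binding corrected potency: EC50 (total, nM) times fu."""
    if ec50_total <= 0:
        raise ValidationError("ec50_total must be > 0")
    if not 0 < fu <= 1:
        raise ValidationError(f"fu must be in (0, 1], got {fu}")
    return ec50_total * fu


def potency_normalized(fec50: float, invitro_ic50: float) -> float:
    """Free potency divided by in vitro receptor potency (dimensionless)."""
    if fec50 <= 0:
        raise ValidationError("fec50 must be > 0")
    if invitro_ic50 <= 0:
        raise ValidationError("in vitro IC50 must be > 0")
    return fec50 / invitro_ic50


def fold_difference(a: float, b: float) -> float:
    """Ratio a/b; report text shows the integer fold."""
    if b <= 0:
        raise ValidationError("denominator must be > 0")
    if a <= 0:
        raise ValidationError("numerator must be > 0")
    return a / b


@dataclass
class TiResult:
    """Derived potency table for one drug."""

    drug: str
    ec50_k: float
    ec50_uacr: float
    fec50_k: float
    fec50_uacr: float
    norm_k: float
    norm_uacr: float
    ti: float
    ti_ci: tuple[float, float] | None = None
    provenance: dict[str, str] = field(default_factory=dict)


def therapeutic_index(
    ec50_k: float, ec50_uacr: float, props: DrugProperties, drug: str = ""
) -> TiResult:
    """TI from total-concentration potencies and drug properties.

    Computed as the ratio of potency-normalized values; the cancellation
    identity (TI == ec50_k / ec50_uacr) is asserted.
    """
    if ec50_k <= 0 or ec50_uacr <= 0:
        raise ValidationError("EC50 values must be > 0")
    fec_k = free_ec50(ec50_k, props.fu)
    fec_u = free_ec50(ec50_uacr, props.fu)
    norm_k = potency_normalized(fec_k, props.ic50_invitro)
    norm_u = potency_normalized(fec_u, props.ic50_invitro)
    ti = norm_k / norm_u
    assert abs(ti - ec50_k / ec50_uacr) <= 1e-9 * ti, "fu/in-vitro cancellation violated"
    return TiResult(
        drug=drug,
        ec50_k=ec50_k,
        ec50_uacr=ec50_uacr,
        fec50_k=fec_k,
        fec50_uacr=fec_u,
        norm_k=norm_k,
        norm_uacr=norm_u,
        ti=ti,
    )


def ti_confidence_interval(
    ec50_k_reps, ec50_uacr_reps, level: float = 0.95
) -> tuple[float, float]:
    """Percentile interval of the per-replicate potency ratio.

    Replicates must be paired (same bootstrap resamples).
    """
    k = np.asarray(ec50_k_reps, dtype=float)
    u = np.asarray(ec50_uacr_reps, dtype=float)
    if k.shape != u.shape or k.ndim != 1 or k.size == 0:
        raise ValidationError("replicate vectors must be paired and 1-D")
    ratio = k / u
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(ratio, alpha)), float(np.quantile(ratio, 1 - alpha))


def build_ti_table(
    results: list[TiResult], provenance: dict[str, str] | None = None
) -> pd.DataFrame:
    """Assemble the per-drug/per-endpoint report table (3 significant figures
    for display columns, full precision kept in the raw columns)."""
    rows = []
    for r in results:
        for endpoint, ec50, fec, norm in (
            ("serum_K", r.ec50_k, r.fec50_k, r.norm_k),
            ("UACR", r.ec50_uacr, r.fec50_uacr, r.norm_uacr),
        ):
            rows.append(
                {
                    "drug": r.drug,
                    "endpoint": endpoint,
                    "ec50_total_nM": ec50,
                    "fec50_nM": sig_figs(fec),
                    "fec50_over_invitro": sig_figs(norm),
                    "ti": sig_figs(r.ti),
                    "ti_ci_lower": r.ti_ci[0] if r.ti_ci else np.nan,
                    "ti_ci_upper": r.ti_ci[1] if r.ti_ci else np.nan,
                    "provenance": (provenance or {}).get(r.drug, "fitted"),
                }
            )
    return pd.DataFrame(rows)
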