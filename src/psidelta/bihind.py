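"""Site-specific Ψ stoichiometry from BIHIND-qPCR Ct quartets.

Bisulfite adducts at a Ψ block ligation of the probe spanning the site,
delaying amplification of the Ψ-probe relative to the U-probe in the
BS-treated sample. With perfect 2-fold amplification per cycle the
modified fraction is

    f = 1 - 0.5 ** ddCt,
    ddCt = (Ct_bs_psi - Ct_bs_u) - (Ct_unt_psi - Ct_unt_u)

where the untreated pair corrects for probe-efficiency differences.
Noise can push the raw estimate outside [0, 1]; by default it is clamped
with a flag, and the raw value is kept for diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .psi_calling import pooled_t_test

logger = logging.getLogger("psidelta")

CT_TABLE_COLUMNS = [
    "sample_label", "replicate_id", "ct_bs_psi", "ct_bs_u", "ct_unt_psi", "ct_unt_u",
]
_CT_SOFT_RANGE = (5.0, 45.0)


@dataclass(frozen=True)
class CtQuartet:
    """The four Ct values feeding the ddCt estimator for one replicate."""

    ct_bs_psi: float
    ct_bs_u: float
    ct_unt_psi: float
    ct_unt_u: float
    replicate_id: str = ""
    sample_label: str = ""

    def __post_init__(self) -> None:
        for name in ("ct_bs_psi", "ct_bs_u", "ct_unt_psi", "ct_unt_u"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
            if not (_CT_SOFT_RANGE[0] <= v <= _CT_SOFT_RANGE[1]):
                logger.warning(
                    "Ct value %s=%.2f outside typical qPCR range %s", name, v, _CT_SOFT_RANGE
                )

    @property
    def ddct(self) -> float:
        return (self.ct_bs_psi - self.ct_bs_u) - (self.ct_unt_psi - self.ct_unt_u)


@dataclass(frozen=True)
class PsiEstimate:
    per_replicate_fraction: tuple[float, ...]
    mean: float
    sem: float          # nan when n == 1
    clamped_flags: tuple[bool, ...] = ()

    @property
    def n(self) -> int:
        return len(self.per_replicate_fraction)


def estimate_psi_fraction(q: CtQuartet, clamp: bool = True) -> float:
    """Ψ fraction 1 - 2**(-ddCt) for one quartet.

    ``clamp`` truncates to [0, 1]; use :func:`estimate_raw` for the
    untruncated value.
    """
    raw = estimate_raw(q)
    if clamp:
        return min(max(raw, 0.0), 1.0)
    return raw


def estimate_raw(q: CtQuartet) -> float:
    return 1.0 - 2.0 ** (-q.ddct)


def aggregate_replicates(estimates: Sequence[float], clamped: Sequence[bool] | None = None) -> PsiEstimate:
    """Mean +/- SEM over replicate fraction estimates.

    SEM is sample SD / sqrt(n); undefined (nan) for n = 1.
    """
    vals = np.asarray(list(estimates), float)
    if vals.size == 0:
        raise ValueError("no replicate estimates")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else math.nan
    flags = tuple(clamped) if clamped is not None else tuple(False for _ in vals)
    return PsiEstimate(tuple(float(v) for v in vals), mean, sem, flags)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Student's t (pooled variance) between two replicate sets."""
    t, p, _ = pooled_t_test(a, b)
    return t, p


def read_ct_table(path) -> list[CtQuartet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        CtQuartet(
            float(r.ct_bs_psi), float(r.ct_bs_u), float(r.ct_unt_psi), float(r.ct_unt_u),
            replicate_id=str(r.replicate_id), sample_label=str(r.sample_label),
        )
        for r in df.itertuples(index=False)
    ]


def estimate_table(quartets: Sequence[CtQuartet], clamp: bool = True) -> pd.DataFrame:
    """Per-replicate estimates plus per-sample aggregation, tidy form."""
    rows = []
    for q in quartets:
        raw = estimate_raw(q)
        clamped_val = min(max(raw, 0.0), 1.0)
        rows.append(
            {
                "sample_label": q.sample_label,
                "replicate_id": q.replicate_id,
                "ddct": q.ddct,
                "fraction_raw": raw,
                "fraction": clamped_val if clamp else raw,
                "clamped": clamped_val != raw,
            }
        )
    return pd.DataFrame(rows)


def aggregate_table(per_rep: pd.DataFrame) -> pd.DataFrame:
    out = (
        per_rep.groupby("sample_label", sort=True)
        .agg(
            n=("fraction", "size"),
            mean_fraction=("fraction", "mean"),
            sd=("fraction", lambda v: v.std(ddof=1)),
            n_clamped=("clamped", "sum"),
        )
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns=["sd"])
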