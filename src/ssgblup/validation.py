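"""Validation of (genomic) breeding values.

Three schemes, matching standard aquaculture practice:

* **mid-parent** — family-mean progeny phenotypes (raw or adjusted) against
  the parent average ``PA = (u_sire + u_dam) / 2`` of the training-run
  (G)EBVs, after removing half-sib families.
* **adjusted** — forward validation of partial-run (G)EBVs against
  whole-run adjusted phenotypes ``y*``; predictive ability scaled by
  ``1/sqrt(h2)`` to an accuracy.
* **LR** — the linear-regression method of comparing whole- and
  partial-data evaluations of the same animals: accuracy
  ``sqrt(cov(u_w, u_p) / ((1 - Fbar) sigma2_u))``, bias ``mean(u_p) -
  mean(u_w)``, dispersion slope ``cov(u_w, u_p)/var(u_p)`` and consistency
  ``cor(u_w, u_p)``.

All covariances and variances use the n-1 denominator, consistent with the
regression-based slope.  The mid-parent regression is of the family-mean
phenotype on PA, so a slope below 1 reads as over-dispersion of the
breeding values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree


class ValidationError(ValueError):
    pass


@dataclass
class ValidationReport:
    method: str
    accuracy: float
    b0: float
    b1: float
    n: int
    bias: float | None = None          # LR only
    consistency: float | None = None   # LR only
    accuracy_defined: bool = True

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("accuracy", self.accuracy),
            ("b0", self.b0),
            ("b1", self.b1),
        ]
        if self.bias is not None:
            rows.append(("bias", self.bias))
        if self.consistency is not None:
            rows.append(("consistency", self.consistency))
        return pd.DataFrame(
            {"method": self.method, "statistic": [r[0] for r in rows],
             "value": [r[1] for r in rows], "n": self.n}
        )


def _regress(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares of y on x -> (intercept, slope)."""
    vx = np.var(x, ddof=1)
    if vx <= 0:
        raise ValidationError("zero variance in the predictor; regression undefined")
    b1 = float(np.cov(y, x, ddof=1)[0, 1] / vx)
    b0 = float(np.mean(y) - b1 * np.mean(x))
    return b0, b1


def midparent_validation(
    gebv: Mapping[str, float] | pd.Series,
    ped: Pedigree,
    progeny_records: pd.DataFrame,
    mode: str = "raw",
) -> ValidationReport:
    """Family-mean progeny phenotypes against mid-parent (G)EBV.

    ``progeny_records`` needs columns ``animal`` and ``phenotype`` (already
    adjusted when ``mode='adjusted'``; the mode only labels the report).
    Families are full-sib groups keyed by the pedigree's (sire, dam) of each
    progeny; families sharing a sire or a dam with an already-kept family
    are dropped (first occurrence kept), mirroring half-sib removal.
    """
    if mode not in ("raw", "adjusted"):
        raise ValidationError(f"unknown mode: {mode}")
    gebv = pd.Series(gebv)
    df = progeny_records.copy()
    df["animal"] = df["animal"].astype(str)
    idx = ped.index_of(df["animal"])
    sire_i, dam_i = ped.sire[idx], ped.dam[idx]
    if np.any(sire_i == UNKNOWN) or np.any(dam_i == UNKNOWN):
        raise ValidationError("validation progeny must have both parents known")
    df["_sire"] = [ped.ids[i] for i in sire_i]
    df["_dam"] = [ped.ids[i] for i in dam_i]

    fam = (
        df.groupby(["_sire", "_dam"], sort=False)["phenotype"].mean().reset_index()
    )
    # drop half-sib families: keep first family per sire and per dam
    seen_s: set = set()
    seen_d: set = set()
    keep = []
    for _, row in fam.iterrows():
        if row["_sire"] in seen_s or row["_dam"] in seen_d:
            keep.append(False)
            continue
        seen_s.add(row["_sire"])
        seen_d.add(row["_dam"])
        keep.append(True)
    fam = fam[np.array(keep)]
    if len(fam) < 3:
        raise ValidationError(f"too few full-sib families for validation: {len(fam)}")
    missing = [p for p in pd.concat([fam["_sire"], fam["_dam"]]) if p not in gebv.index]
    if missing:
        raise ValidationError(f"parents without (G)EBV: {sorted(set(missing))[:5]}")
    pa = (gebv[fam["_sire"]].to_numpy() + gebv[fam["_dam"]].to_numpy()) / 2.0
    ph = fam["phenotype"].to_numpy(dtype=float)
    if np.var(pa, ddof=1) <= 0:
        raise ValidationError("parent averages are constant; correlation undefined")
    cor = float(np.corrcoef(ph, pa)[0, 1])
    b0, b1 = _regress(ph, pa)
    return ValidationReport(
        method=f"midparent-{mode}", accuracy=cor, b0=b0, b1=b1, n=len(fam)
    )


def forward_validation_adjusted(
    y_star: np.ndarray, u_hat_partial: np.ndarray, h2: float
) -> ValidationReport:
    """Adjusted phenotypes from the whole data vs partial-run (G)EBV.

    ``accuracy = cor(y*, u_hat) / sqrt(h2)``; b0 and b1 come from the
    regression of ``y*`` on ``u_hat``.
    """
    y_star = np.asarray(y_star, dtype=float)
    u = np.asarray(u_hat_partial, dtype=float)
    if y_star.shape != u.shape:
        raise ValidationError("y* and u_hat must be the same length")
    if not (0 < h2 <= 1):
        raise ValidationError(f"h2 must be in (0, 1], got {h2}")
    if np.var(u, ddof=1) <= 0:
        raise ValidationError("zero variance in u_hat")
    cor = float(np.corrcoef(y_star, u)[0, 1])
    b0, b1 = _regress(y_star, u)
    return ValidationReport(
        method="adjusted", accuracy=cor / np.sqrt(h2), b0=b0, b1=b1, n=len(u)
    )


def lr_validation(
    u_hat_whole: np.ndarray,
    u_hat_partial: np.ndarray,
    F_bar: float,
    sigma2_u: float,
) -> ValidationReport:
    """The four LR-method statistics from whole vs partial evaluations.

    A negative ``cov(u_w, u_p)`` makes the accuracy undefined; it is then
    reported as NaN with ``accuracy_defined=False`` while the other three
    statistics are still returned.
    """
    uw = np.asarray(u_hat_whole, dtype=float)
    up = np.asarray(u_hat_partial, dtype=float)
    if uw.shape != up.shape:
        raise ValidationError("whole and partial (G)EBV vectors differ in length")
    if sigma2_u <= 0:
        raise ValidationError("sigma2_u must be positive")
    c = float(np.cov(uw, up, ddof=1)[0, 1])
    vp = float(np.var(up, ddof=1))
    if vp <= 0:
        raise ValidationError("zero variance in partial (G)EBV")
    bias = float(np.mean(up) - np.mean(uw))
    slope = c / vp
    consistency = float(np.corrcoef(uw, up)[0, 1])
    denom = (1.0 - F_bar) * sigma2_u
    if c >= 0 and denom > 0:
        accuracy, defined = float(np.sqrt(c / denom)), True
    else:
        accuracy, defined = float("nan"), False
    return ValidationReport(
        method="LR", accuracy=accuracy, b0=bias, b1=slope, n=len(uw),
        bias=bias, consistency=consistency, accuracy_defined=defined,
    )
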