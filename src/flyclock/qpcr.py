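"""qPCR standard-curve fitting, primer efficiency and relative quantification.

A dilution series of template gives a straight line of Ct against
log10(relative template amount); the slope carries the primer's amplification
efficiency, ``E = 10^(-1/slope) - 1`` (slope -3.3219 corresponds to perfect
doubling, E = 100%).  Unknowns are quantified by inverting the fitted line,
``quantity = 10^((Ct - intercept) / slope)``, and normalized to a reference
gene (Actin5C in the standard fly design) by simple ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StandardCurve:
    log10_dilutions: np.ndarray
    ct_values: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 = 100%)."""
        return 10 ** (-1.0 / self.slope) - 1.0

    @property
    def amplification_factor(self) -> float:
        """Per-cycle amplification, ``10^(-1/slope)`` (2.0 = perfect doubling)."""
        return 10 ** (-1.0 / self.slope)


def fit_standard_curve(
    dilutions: Sequence[float],
    cts: Sequence[float],
    average_replicates: bool = True,
) -> StandardCurve:
    """OLS fit of Ct on log10(relative template amount).

    ``dilutions`` are relative template amounts (e.g. 1, 0.5, 0.25 ... for a
    2-fold series).  Replicate Cts at the same dilution are averaged before
    the regression unless ``average_replicates`` is False.
    """
    d = np.asarray(dilutions, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if d.shape != ct.shape:
        raise ValueError("dilutions and cts must align")
    if not np.all(np.isfinite(ct)) or not np.all(d > 0):
        raise ValueError("cts must be finite and dilutions positive")
    logd = np.log10(d)
    if average_replicates:
        uniq = np.unique(logd)
        ct = np.array([ct[logd == u].mean() for u in uniq])
        logd = uniq
    if np.unique(logd).size < 3:
        raise ValueError("need at least 3 distinct dilutions")
    res = sps.linregress(logd, ct)
    if res.slope >= 0:
        raise ValueError("non-amplifying curve: slope must be negative")
    return StandardCurve(
        log10_dilutions=logd,
        ct_values=ct,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def relative_quantity(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Invert the standard curve: ``10^((ct - intercept) / slope)``."""
    if not isinstance(curve, StandardCurve):
        raise TypeError("curve must be a fitted StandardCurve")
    q = 10 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)
    return float(q) if np.isscalar(ct) else q


def normalize_to_reference(
    target_qty: float | np.ndarray, reference_qty: float | np.ndarray
) -> float | np.ndarray:
    """Relative expression level: target quantity over reference-gene quantity."""
    ref = np.asarray(reference_qty, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference quantity must be positive")
    out = np.asarray(target_qty, dtype=float) / ref
    return float(out) if out.ndim == 0 else out


def quantify_table(
    ct_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference_gene: str,
) -> pd.DataFrame:
    """Relative quantification of a tidy Ct table with reference normalization.

    ``ct_table`` needs columns gene, sample, ct (one row per well); every gene
    must have a fitted curve.  Returns one row per (gene, sample) with the
    mean quantity and the level normalized to ``reference_gene``.
    """
    needed = {"gene", "sample", "ct"}
    if not needed <= set(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(needed)}")
    rows = []
    for (gene, sample), sub in ct_table.groupby(["gene", "sample"], sort=False):
        q = relative_quantity(sub["ct"].to_numpy(float), curves[gene])
        rows.append({"gene": gene, "sample": sample, "quantity": float(np.mean(q))})
    out = pd.DataFrame(rows)
    ref = out[out["gene"] == reference_gene].set_index("sample")["quantity"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} missing from table")
    out["relative_level"] = [
        normalize_to_reference(row.quantity, ref[row.sample]) for row in out.itertuples()
    ]
    return out
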