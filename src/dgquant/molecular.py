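"""Standard-curve qPCR quantification and Prox1-normalized expression.

Absolute quantification: a serial dilution of a purified standard gives
quantification cycles that are linear in log starting quantity,

    Cq = a + b * log10(q),    b < 0,
    efficiency = 10^(-1/b) - 1   (1.0 = perfect doubling per cycle),

and unknown samples are inverted through the fitted line,
``q = 10^((Cq - a) / b)``.  Quantities are arbitrary units; the biological
readout is the ratio of Dcx (or Bdnf) to Prox1, the transcription factor
expressed by every dentate granule cell, which normalizes for the amount of
granule-cell tissue in the sample.  Immunoassay (protein) quantities skip
the curve step and are normalized the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StandardCurve", "InvalidCurveError", "fit_standard_curve",
           "quantify", "normalize_expression"]


@dataclass
class StandardCurve:
    intercept_a: float
    slope_b: float
    efficiency: float
    r2: float


class InvalidCurveError(ValueError):
    """Dilution series with non-negative slope cannot be a qPCR curve."""


def fit_standard_curve(quantities, cqs) -> StandardCurve:
    """Least-squares Cq ~ log10(quantity) fit of a dilution series."""
    q = np.asarray(quantities, dtype=float)
    cq = np.asarray(cqs, dtype=float)
    if q.shape != cq.shape:
        raise ValueError("quantities and Cq values must align")
    if np.any(q <= 0):
        raise ValueError("standard quantities must be positive")
    if np.unique(q).size < 3:
        raise ValueError("need at least 3 distinct standard quantities")
    x = np.log10(q)
    b, a = np.polyfit(x, cq, 1)
    if b >= 0:
        raise InvalidCurveError(f"fitted slope {b:.4f} is not negative")
    resid = cq - (a + b * x)
    ss_tot = float(((cq - cq.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(float(a), float(b),
                         float(10.0 ** (-1.0 / b) - 1.0), r2)


def quantify(cq, curve: StandardCurve):
    """Starting quantity from a Cq value via the inverted standard curve."""
    cq = np.asarray(cq, dtype=float)
    q = 10.0 ** ((cq - curve.intercept_a) / curve.slope_b)
    return float(q) if q.ndim == 0 else q


def normalize_expression(samples: pd.DataFrame) -> pd.DataFrame:
    """Populate Prox1-normalized ratio columns of a quantity table.

    ``samples`` needs columns ``animal_id, region, modality, dcx_qty,
    prox1_qty`` and optionally ``bdnf_qty``; returns a copy with
    ``normalized_dcx`` (and ``normalized_bdnf`` where Bdnf was measured).
    Hemispheres are pooled upstream at dissection, so each row is one
    animal-region sample.
    """
    out = samples.copy()
    prox1 = out["prox1_qty"].to_numpy(dtype=float)
    if np.any(~np.isfinite(prox1)) or np.any(prox1 <= 0):
        bad = out.loc[~(prox1 > 0), "animal_id"].tolist()
        raise ZeroDivisionError(
            f"non-positive Prox1 quantity for animal(s) {bad}")
    out["normalized_dcx"] = out["dcx_qty"] / out["prox1_qty"]
    if "bdnf_qty" in out.columns:
        out["normalized_bdnf"] = out["bdnf_qty"] / out["prox1_qty"]
    return out
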