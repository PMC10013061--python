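"""Parenclitic deviation: orthogonal residuals from the reference lines.

For a patient with observed pair values (x0, y0) and reference line
y = a + b x, the vertical residual is v = |y0 - (a + b x0)| and the
horizontal residual is h = |x0 - (y0 - a) / b|.  The parenclitic deviation is
the altitude of the right triangle formed by the two residual legs,

    delta = v * h / sqrt(v^2 + h^2),

which is algebraically identical to the perpendicular (orthogonal) distance
from the point to the line, v / sqrt(1 + b^2).  The closed form is used for
computation because it has no 0/0 case at v = h = 0 and no singularity at
b = 0 (where the triangle formula degenerates and the deviation is simply v).

Deviations are unsigned edge weights in the patient's network.  They are kept
in raw units, so values are comparable across patients within an axis but not
across axes.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParencliticError
from .reference import ReferenceModelSet, RegressionLine


def residual_legs(x0: float, y0: float, line: RegressionLine) -> tuple[float, float]:
    """Absolute vertical and horizontal residuals (v, h) from the line.

    For slope b != 0 the legs satisfy h = v / |b| exactly.  For b = 0 the
    horizontal leg is undefined (reported as inf when v > 0, 0 on the line).
    """
    v = abs(y0 - line.predict(x0))
    if line.slope == 0:
        h = 0.0 if v == 0 else math.inf
    else:
        h = abs(x0 - (y0 - line.intercept) / line.slope)
    return v, h


def orthogonal_delta(x0: float, y0: float, line: RegressionLine) -> float:
    """Parenclitic deviation of point (x0, y0) from the reference line.

    Computed as the perpendicular distance v / sqrt(1 + b^2); equals the
    residual-triangle altitude v h / sqrt(v^2 + h^2) for b != 0 and its
    b -> 0 limit v otherwise.
    """
    if not (np.isfinite(x0) and np.isfinite(y0)):
        raise ParencliticError(f"non-finite input point ({x0}, {y0})")
    v = abs(y0 - line.predict(x0))
    return v / math.sqrt(1.0 + line.slope**2)


def compute_profile(
    row: Mapping[str, float], refset: ReferenceModelSet
) -> dict[str, float]:
    """Per-patient deviation profile: one delta per reference pair.

    Pairs with a missing member variable are absent from the profile (the
    corresponding network edge is absent); missingness never fails.
    """
    profile: dict[str, float] = {}
    for pair in refset.pairs:
        x0 = row.get(pair.corr.x_var, np.nan)
        y0 = row.get(pair.corr.y_var, np.nan)
        if pd.isna(x0) or pd.isna(y0):
            continue
        profile[pair.key] = orthogonal_delta(float(x0), float(y0), pair.line)
    return profile


def compute_cohort_profiles(
    cohort: pd.DataFrame, refset: ReferenceModelSet
) -> pd.DataFrame:
    """Deviation profiles for every patient, reference class included.

    Returns a frame indexed by ``patient_id`` (sorted) with one column per
    reference pair; absent deltas are NaN.  Vectorized per pair.
    """
    index = cohort["patient_id"].to_numpy()
    out = pd.DataFrame(index=pd.Index(index, name="patient_id"))
    for pair in refset.pairs:
        x = cohort[pair.corr.x_var].to_numpy(dtype=float)
        y = cohort[pair.corr.y_var].to_numpy(dtype=float)
        v = np.abs(y - (pair.line.intercept + pair.line.slope * x))
        out[pair.key] = v / math.sqrt(1.0 + pair.line.slope**2)
    return out.sort_index()
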