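"""Synthetic cirrhosis-cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage can be exercised and validated without patient
data:

* a "clean" class whose variable pairs follow injected linear models
  ``y = slope * x + intercept + N(0, noise_sd)``;
* a "disrupted" class identical except that the residual noise on a subset of
  axes is inflated by a constant factor, mimicking the loss of physiological
  coupling seen in non-survivors;
* exponential event times whose log-hazard increases linearly with the true
  orthogonal deviation on each hazard-linked axis (a proportional-hazards
  data-generating process, so the downstream Cox stage is correctly
  specified), with administrative censoring at the follow-up horizon;
* MELD and Child-Pugh scores as monotone noisy functions of bilirubin,
  prothrombin time, albumin (and HE grade for Child-Pugh), so measured
  severity correlates with outcome;
* completely-at-random missingness on the clinical columns.

Variables are generated following the pair-spec list as a directed chain:
a spec whose response is not yet realized draws it from its predictor; a spec
whose predictor is not yet realized draws the predictor by inverting the line
(used for the ammonia-HE axis, where HE severity already exists); a spec with
both members realized is *induced* -- its correlation arises through the
shared parent and no sampling step is performed.  Hepatic encephalopathy is
generated as a latent continuous severity and discretized into grades 0/1/2
only at the end, preserving an approximately linear latent relation with its
partners.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .io import COHORT_COLUMNS
from .variables import CLINICAL_VARIABLES

#: Latent HE severity thresholds for grades 0 / 1 / 2.
HE_CUTPOINTS: tuple[float, float] = (0.25, 0.85)

#: Lower physical bounds applied to generated marginals.
_FLOORS = {"bil": 0.5, "pt": 5.0, "nh4": 1.0, "cr": 20.0}

# Fallback marginals for variables not generated by any pair spec.
_MARGINAL_MEAN_SD = {
    "bil": (60.0, 30.0),
    "pt": (15.0, 2.5),
    "nh4": (80.0, 30.0),
    "cr": (80.0, 25.0),
    "na": (137.0, 4.0),
}


def _floor(name: str, values: np.ndarray) -> np.ndarray:
    lo = _FLOORS.get(name)
    return values if lo is None else np.maximum(values, lo)


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Parameters
    ----------
    config
        Generator settings; see :class:`~parenclitic.config.SyntheticConfig`.
    seed
        Overrides ``config.seed`` when given.  The same (config, seed)
        always yields an identical table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_clean = config.n_survivors
    n = n_clean + config.n_nonsurvivors
    inflated = np.zeros(n, dtype=bool)
    inflated[n_clean:] = True

    values: dict[str, np.ndarray] = {}
    # Exogenous marginals, drawn in fixed order for reproducibility.
    values["alb"] = rng.uniform(20.0, 45.0, size=n)
    values["cr"] = _floor("cr", rng.normal(80.0, 25.0, size=n))
    values["na"] = rng.normal(137.0, 4.0, size=n)

    # True orthogonal deviation per generated axis (response-axis residual
    # projected perpendicular to the injected line); drives the hazard.
    true_dev: dict[str, np.ndarray] = {}

    for spec in config.pair_specs:
        sd_scale = np.ones(n)
        if spec.key in config.disrupted_axes:
            sd_scale[inflated] = config.deviation_inflation
        if spec.y_var not in values and spec.x_var in values:
            # direct: response from predictor
            eps = rng.normal(0.0, spec.noise_sd, size=n) * sd_scale
            y = spec.intercept + spec.slope * values[spec.x_var] + eps
            values[spec.y_var] = _floor(spec.y_var, y)
            true_dev[spec.key] = np.abs(eps) / math.sqrt(1.0 + spec.slope**2)
        elif spec.x_var not in values and spec.y_var in values:
            # inverse: predictor from response (e.g. ammonia from HE severity)
            if spec.slope == 0:
                raise ValueError(f"cannot invert zero-slope spec {spec.key}")
            nu = rng.normal(0.0, spec.noise_sd / abs(spec.slope), size=n) * sd_scale
            x = (values[spec.y_var] - spec.intercept) / spec.slope + nu
            values[spec.x_var] = _floor(spec.x_var, x)
            resid = spec.slope * nu  # response-scale residual of y on x
            true_dev[spec.key] = np.abs(resid) / math.sqrt(1.0 + spec.slope**2)
        # both realized: induced axis, correlation via the shared parent

    # Fallback marginals for anything not reached by the spec chain.
    for name in CLINICAL_VARIABLES:
        if name in values:
            continue
        if name == "he":
            values["he"] = rng.choice(
                np.array([0.0, 1.0, 2.0]), size=n, p=[0.45, 0.30, 0.25]
            )
        else:
            mean, sd = _MARGINAL_MEAN_SD[name]
            values[name] = _floor(name, rng.normal(mean, sd, size=n))

    he_latent = values["he"]
    he_grade = np.digitize(he_latent, HE_CUTPOINTS).astype(float)

    # Severity scores: monotone noisy functions of Bil, PT, ALB (+ HE grade).
    meld_noise = rng.normal(0.0, 1.5, size=n)
    cp_noise = rng.normal(0.0, 0.8, size=n)
    meld = np.clip(
        np.round(
            6.0
            + 0.06 * values["bil"]
            + 0.7 * (values["pt"] - 12.0)
            + 0.15 * (45.0 - values["alb"])
            + meld_noise
        ),
        6,
        40,
    ).astype(int)
    child_pugh = np.clip(
        np.round(
            5.0
            + 0.02 * values["bil"]
            + 0.25 * (values["pt"] - 12.0)
            + 0.10 * (45.0 - values["alb"])
            + he_grade
            + cp_noise
        ),
        5,
        15,
    ).astype(int)

    # Event times: exponential, rate = baseline * exp(sum coeff * |deviation|),
    # common uniform draws so the event process is monotone in the
    # coefficients patient by patient.
    log_rate = np.full(n, math.log(config.baseline_hazard))
    for axis, coeff in config.hazard_coeffs.items():
        if axis in true_dev:
            log_rate = log_rate + coeff * true_dev[axis]
    rate = np.exp(log_rate)
    u = 1.0 - rng.random(n)  # in (0, 1]
    t = np.maximum(-np.log(u) / rate, 0.01)
    event = (t <= config.censor_day).astype(int)
    time = np.where(event == 1, t, float(config.censor_day))

    clinical = {k: np.asarray(values[k], dtype=float) for k in CLINICAL_VARIABLES}
    clinical["he"] = he_grade

    # Completely-at-random missingness on the clinical columns only.
    if config.missing_rate > 0:
        for name in CLINICAL_VARIABLES:
            mask = rng.random(n) < config.missing_rate
            col = clinical[name].copy()
            col[mask] = np.nan
            clinical[name] = col

    width = max(4, len(str(n)))
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            **{k: clinical[k] for k in CLINICAL_VARIABLES},
            "event": event,
            "time": time,
            "meld": meld,
            "child_pugh": child_pugh,
        }
    )
    return df.loc[:, list(COHORT_COLUMNS)]
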