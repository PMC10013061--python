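"""Analysis and simulation configuration.

``AnalysisConfig`` holds the knobs of the analysis pipeline; ``SyntheticConfig``
those of the synthetic cohort generator.  Both can be loaded from a single YAML
file with top-level keys ``analysis:`` and ``synthetic:`` (all fields
defaulted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import ConfigError
from .variables import CLINICAL_VARIABLES


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline configuration.

    Parameters
    ----------
    alpha
        Family-wise significance level for the Bonferroni-corrected pair
        screening (default 0.05).
    horizon_days
        Follow-up horizon in days; events after the horizon are
        administratively censored at the horizon (default 365).
    min_pair_n
        Minimum number of complete observation pairs for a correlation to be
        computed at all (default 10).  Pairs below this stay in the Bonferroni
        denominator but are excluded from screening.
    seed
        Seed for any stochastic step of the analysis layer.
    """

    alpha: float = 0.05
    horizon_days: float = 365.0
    min_pair_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.horizon_days <= 0:
            raise ConfigError(f"horizon_days must be positive, got {self.horizon_days}")
        if self.min_pair_n < 3:
            raise ConfigError(f"min_pair_n must be >= 3, got {self.min_pair_n}")


@dataclass(frozen=True)
class PairSpec:
    """One injected linear axis: y = slope * x + intercept + N(0, noise_sd)."""

    x_var: str
    y_var: str
    slope: float
    intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        for v in (self.x_var, self.y_var):
            if v not in CLINICAL_VARIABLES:
                raise ConfigError(f"unknown variable in pair spec: {v!r}")
        if self.x_var == self.y_var:
            raise ConfigError("pair spec must join two distinct variables")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be positive, got {self.noise_sd}")

    @property
    def key(self) -> str:
        return f"{self.x_var}_{self.y_var}"


# The six survivor-correlated axes emulated by default.  Scales are chosen to
# be clinically plausible for a decompensated-cirrhosis cohort: albumin in
# g/L, bilirubin in umol/L, prothrombin time in seconds, ammonia in umol/L,
# HE as a latent continuous severity later cut into grades 0/1/2.
# The bil->pt and pt->he axes are *induced* through the shared albumin parent
# (both members are already generated when they are reached), so their slope /
# noise entries describe the implied marginal relation, not a sampling step.
DEFAULT_PAIR_SPECS: tuple[PairSpec, ...] = (
    PairSpec("alb", "bil", -3.0, 160.0, 14.0),
    PairSpec("alb", "pt", -0.45, 30.0, 1.8),
    PairSpec("alb", "he", -0.09, 3.2, 0.30),
    PairSpec("nh4", "he", 0.02, -1.0, 0.30),
    PairSpec("bil", "pt", 0.106, 8.8, 2.5),
    PairSpec("pt", "he", 0.153, -1.5, 0.45),
)

#: Axes whose noise is inflated in the non-survivor class by default.
DEFAULT_DISRUPTED_AXES: tuple[str, ...] = ("alb_bil", "alb_pt", "alb_he", "nh4_he")

#: Per-axis log-hazard slope applied to |true orthogonal deviation|.  Scaled
#: to each axis's deviation units so the four axes contribute comparably.
DEFAULT_HAZARD_COEFFS: dict[str, float] = {
    "alb_bil": 0.18,
    "alb_pt": 0.6,
    "alb_he": 2.25,
    "nh4_he": 2.25,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Synthetic cohort generator configuration.

    The generator draws a "clean" class (``n_survivors``) that follows the
    injected pairwise linear models, and a "disrupted" class
    (``n_nonsurvivors``) identical except that the residual noise on the
    ``disrupted_axes`` is inflated by ``deviation_inflation``.  Event times
    are exponential with per-patient rate
    ``baseline_hazard * exp(sum_axis hazard_coeffs[axis] * |true deviation|)``
    and administrative censoring at ``censor_day``, so survival status is an
    outcome of the hazard model, not a label copied from the class.
    """

    n_survivors: int = 400
    n_nonsurvivors: int = 100
    pair_specs: tuple[PairSpec, ...] = DEFAULT_PAIR_SPECS
    deviation_inflation: float = 3.0
    disrupted_axes: tuple[str, ...] = DEFAULT_DISRUPTED_AXES
    hazard_coeffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_COEFFS)
    )
    baseline_hazard: float = 6e-6
    censor_day: float = 365.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survivors < 0 or self.n_nonsurvivors < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.deviation_inflation < 1:
            raise ConfigError(
                f"deviation_inflation must be >= 1, got {self.deviation_inflation}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.censor_day <= 0:
            raise ConfigError("censor_day must be positive")
        spec_keys = {s.key for s in self.pair_specs}
        for axis in self.disrupted_axes:
            if axis not in spec_keys:
                raise ConfigError(f"disrupted axis {axis!r} has no pair spec")
        for axis in self.hazard_coeffs:
            if axis not in spec_keys:
                raise ConfigError(f"hazard coefficient for unknown axis {axis!r}")


def _pair_specs_from_yaml(entries: list) -> tuple[PairSpec, ...]:
    specs = []
    for e in entries:
        if isinstance(e, dict):
            specs.append(PairSpec(**e))
        else:  # sequence form [x, y, slope, intercept, noise_sd]
            specs.append(PairSpec(*e))
    return tuple(specs)


def load_config(path: str) -> tuple[AnalysisConfig, SyntheticConfig]:
    """Load ``analysis`` and ``synthetic`` sections from a YAML file.

    Missing sections or fields fall back to defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    analysis = AnalysisConfig(**(raw.get("analysis") or {}))
    syn_raw = dict(raw.get("synthetic") or {})
    if "pair_specs" in syn_raw:
        syn_raw["pair_specs"] = _pair_specs_from_yaml(syn_raw["pair_specs"])
    if "disrupted_axes" in syn_raw:
        syn_raw["disrupted_axes"] = tuple(syn_raw["disrupted_axes"])
    synthetic = SyntheticConfig(**syn_raw)
    return analysis, synthetic


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
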