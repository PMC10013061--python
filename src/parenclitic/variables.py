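"""Clinical variable registry and hepatic-encephalopathy grade encoding.

The analysis operates on seven routine clinical/laboratory variables.  Their
order is fixed and meaningful: for any variable pair, the variable that comes
earlier in :data:`CLINICAL_VARIABLES` is the predictor (x) of the pair's
reference regression and the later one is the response (y).  Orthogonal
distance to a least-squares line depends on which variable is regressed, so a
fixed orientation keeps results reproducible.
"""

from __future__ import annotations

from .errors import CohortValidationError

#: Fixed variable order; defines pair orientation (earlier = predictor).
CLINICAL_VARIABLES: tuple[str, ...] = ("alb", "bil", "pt", "cr", "nh4", "na", "he")

VARIABLE_LABELS: dict[str, str] = {
    "alb": "Albumin",
    "bil": "Bilirubin",
    "pt": "Prothrombin Time",
    "cr": "Creatinine",
    "nh4": "Ammonia",
    "na": "Sodium",
    "he": "Hepatic Encephalopathy",
}

VARIABLE_UNITS: dict[str, str] = {
    "alb": "g/L",
    "bil": "umol/L",
    "pt": "s",
    "cr": "umol/L",
    "nh4": "umol/L",
    "na": "mmol/L",
    "he": "grade (0/1/2)",
}

#: Hepatic encephalopathy is graded as an ordinal three-level variable.
HE_GRADES: dict[str, int] = {"unimpaired": 0, "minimal": 1, "overt": 2}


def encode_he(label: object) -> int:
    """Encode a hepatic-encephalopathy grade as an ordinal integer.

    Accepts the text grades ``unimpaired`` / ``minimal`` / ``overt``
    (case-insensitive, surrounding whitespace ignored) or the integers
    0 / 1 / 2 directly.

    Raises
    ------
    CohortValidationError
        If the label is not a recognized grade.
    """
    if isinstance(label, str):
        key = label.strip().lower()
        if key in HE_GRADES:
            return HE_GRADES[key]
        # allow numeric strings such as "2" or "2.0"
        try:
            value = float(key)
        except ValueError:
            raise CohortValidationError(f"unrecognized HE grade: {label!r}") from None
    elif isinstance(label, (int, float)):
        value = float(label)
    else:
        raise CohortValidationError(f"unrecognized HE grade: {label!r}")
    if value in (0.0, 1.0, 2.0):
        return int(value)
    raise CohortValidationError(f"unrecognized HE grade: {label!r}")


def ordered_pairs(variables: tuple[str, ...] = CLINICAL_VARIABLES) -> list[tuple[str, str]]:
    """All unordered variable pairs, oriented by the fixed variable order."""
    return [
        (variables[i], variables[j])
        for i in range(len(variables))
        for j in range(i + 1, len(variables))
    ]


def pair_key(x_var: str, y_var: str) -> str:
    """Column-safe identifier for a pair, e.g. ``alb_bil``."""
    return f"{x_var}_{y_var}"


def pair_label(x_var: str, y_var: str) -> str:
    """Human-readable pair name, e.g. ``Albumin-Bilirubin``."""
    return f"{VARIABLE_LABELS[x_var]}-{VARIABLE_LABELS[y_var]}"
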