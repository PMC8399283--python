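"""Model parameters, validation, presets, and plain-text config I/O.

The model tracks four compartments inside a single host:

``x``  susceptible target cells,
``y``  free virus / infected cells,
``z``  cytotoxic T lymphocytes (CTLs),
``w``  an exponentially weighted memory of ``y`` carrying the distributed
       delay of the immune response (linear chain trick, mean delay 1/sigma).

Eleven rates define the dynamics; three white-noise intensities perturb the
x, y and z channels multiplicatively.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "ModelParams",
    "validate_params",
    "example1",
    "example2",
    "PRESETS",
    "params_from_dict",
    "params_to_dict",
]

# Canonical config-file keys, in serialization order.  "h" is an accepted
# alias for "d" (some sources use h for the susceptible death rate).
_CONFIG_TO_FIELD = {
    "lambda": "lambda_",
    "d": "d",
    "h": "d",
    "e": "e",
    "a": "a",
    "p": "p",
    "c": "c",
    "b": "b",
    "sigma": "sigma_delay",
    "sigma1": "sigma1",
    "sigma2": "sigma2",
    "sigma3": "sigma3",
}
_FIELD_TO_CONFIG = {
    "lambda_": "lambda",
    "d": "d",
    "e": "e",
    "a": "a",
    "p": "p",
    "c": "c",
    "b": "b",
    "sigma_delay": "sigma",
    "sigma1": "sigma1",
    "sigma2": "sigma2",
    "sigma3": "sigma3",
}

_STRICTLY_POSITIVE = ("lambda_", "d", "a", "p", "c", "b", "sigma_delay")
_NON_NEGATIVE = ("sigma1", "sigma2", "sigma3")


@dataclass(frozen=True)
class ModelParams:
    """Rate and noise parameters of the stochastic infection model.

    Parameters
    ----------
    lambda_ : float
        Recruitment rate of susceptible cells (cells / time).
    d : float
        Susceptible-cell death rate (1 / time).
    e : float
        Infection rate (1 / (cell * time)).  ``e = 0`` decouples the virus
        from the susceptible pool and is accepted with a warning (used as a
        closed-form test limit).
    a : float
        Virus / infected-cell death rate (1 / time).
    p : float
        CTL killing rate (1 / (CTL * time)).
    c : float
        CTL activation rate (1 / time).
    b : float
        CTL death rate (1 / time).
    sigma_delay : float
        Rate of the exponential delay kernel (1 / time); the immune response
        reacts to past viral load with mean lag ``1 / sigma_delay``.
    sigma1, sigma2, sigma3 : float
        White-noise intensities on x, y, z (1 / sqrt(time)).
    """

    lambda_: float
    d: float
    e: float
    a: float
    p: float
    c: float
    b: float
    sigma_delay: float
    sigma1: float = 0.0
    sigma2: float = 0.0
    sigma3: float = 0.0


def validate_params(params: ModelParams) -> ModelParams:
    """Validate a parameter set, returning it unchanged on success.

    Raises ``ValueError`` naming the offending field when a rate is not
    strictly positive or a noise intensity is negative.  ``e = 0`` is
    accepted with a ``UserWarning`` because it disables infection entirely
    (the decoupled limit has a known closed-form stationary law and is used
    as an oracle).
    """
    for name in _STRICTLY_POSITIVE:
        value = getattr(params, name)
        if not (value > 0):
            raise ValueError(
                f"parameter {_FIELD_TO_CONFIG[name]!r} must be strictly "
                f"positive, got {value!r}"
            )
    if params.e < 0:
        raise ValueError(f"parameter 'e' must be non-negative, got {params.e!r}")
    if params.e == 0:
        warnings.warn(
            "infection rate e = 0: the virus channel is decoupled from the "
            "susceptible pool (degenerate test limit)",
            UserWarning,
            stacklevel=2,
        )
    for name in _NON_NEGATIVE:
        value = getattr(params, name)
        if value < 0:
            raise ValueError(
                f"noise intensity {name!r} must be non-negative, got {value!r}"
            )
    return params


def params_from_dict(mapping: Mapping[str, float]) -> ModelParams:
    """Build a validated ``ModelParams`` from config-style keys.

    Accepts exactly the keys lambda, d (or the alias h), e, a, p, c, b,
    sigma, sigma1, sigma2, sigma3.  Unknown keys are rejected by name;
    missing keys are rejected by name (there are no parameter defaults
    except the noise intensities, which default to 0).
    """
    unknown = sorted(k for k in mapping if k not in _CONFIG_TO_FIELD)
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
    if "d" in mapping and "h" in mapping:
        raise ValueError("give either 'd' or its alias 'h', not both")
    fields: dict[str, float] = {}
    for key, value in mapping.items():
        fields[_CONFIG_TO_FIELD[key]] = float(value)
    required = [
        f for f in _FIELD_TO_CONFIG
        if f not in fields and f not in _NON_NEGATIVE
    ]
    if required:
        missing = sorted(_FIELD_TO_CONFIG[f] for f in required)
        raise ValueError(
            "missing parameter keys: "
            + ", ".join(missing)
            + " (no defaults; noise intensities sigma1..sigma3 default to 0)"
        )
    return validate_params(ModelParams(**fields))


def params_to_dict(params: ModelParams) -> dict[str, float]:
    """Serialize to the canonical config keys (d, never the h alias)."""
    return {
        key: getattr(params, field)
        for field, key in _FIELD_TO_CONFIG.items()
    }


def example1() -> ModelParams:
    """Persistence-regime preset: high recruitment, R0* > 1.

    lambda=1000, d=0.1, e=0.002, a=5, p=0.2, c=0.2, b=0.3, sigma=0.2,
    sigma1=sigma2=sigma3=0.1.
    """
    return ModelParams(
        lambda_=1000.0, d=0.1, e=0.002, a=5.0, p=0.2, c=0.2, b=0.3,
        sigma_delay=0.2, sigma1=0.1, sigma2=0.1, sigma3=0.1,
    )


def example2() -> ModelParams:
    """Extinction-regime preset: identical to :func:`example1` except
    lambda=250, which pushes R0* below 1."""
    return dataclasses.replace(example1(), lambda_=250.0)


PRESETS = {"example1": example1, "example2": example2}


def get_preset(name: str) -> ModelParams:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return factory()


def config_keys() -> Iterable[str]:
    """The canonical parameter keys, in file order."""
    return tuple(_FIELD_TO_CONFIG.values())
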