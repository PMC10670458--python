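"""Response-convention handling.

Plate readers report drug response either as remaining viability or as
inhibition, on a 0-1 ratio scale or as a percentage.  Every response is
stored internally as *percent inhibition*; the functions here convert
between that canonical unit and any of the four input conventions.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Quantity",
    "Scale",
    "ResponseConvention",
    "PERCENT_INHIBITION",
    "to_percent_inhibition",
    "from_percent_inhibition",
]


class Quantity(str, Enum):
    VIABILITY = "viability"
    INHIBITION = "inhibition"


class Scale(str, Enum):
    RATIO = "ratio"
    PERCENT = "percent"


@dataclass(frozen=True)
class ResponseConvention:
    """How raw responses are expressed: what is measured and on what scale."""

    quantity: Quantity = Quantity.INHIBITION
    scale: Scale = Scale.PERCENT

    def __post_init__(self) -> None:
        # accept plain strings for convenience
        object.__setattr__(self, "quantity", Quantity(self.quantity))
        object.__setattr__(self, "scale", Scale(self.scale))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.quantity.value} ({self.scale.value})"


PERCENT_INHIBITION = ResponseConvention(Quantity.INHIBITION, Scale.PERCENT)


def _convert_array(values: np.ndarray, convention: ResponseConvention) -> np.ndarray:
    """Vectorised conversion to percent inhibition; NaN passes through (missing well)."""
    out = np.asarray(values, dtype=float)
    if np.any(np.isinf(out)):
        raise ValueError("non-finite response value")
    if convention.scale is Scale.RATIO:
        out = out * 100.0
    if convention.quantity is Quantity.VIABILITY:
        out = 100.0 - out
    return out


def _invert_array(values: np.ndarray, convention: ResponseConvention) -> np.ndarray:
    out = np.asarray(values, dtype=float)
    if convention.quantity is Quantity.VIABILITY:
        out = 100.0 - out
    if convention.scale is Scale.RATIO:
        out = out / 100.0
    return out


def to_percent_inhibition(value, convention: ResponseConvention):
    """Convert a response from *convention* to percent inhibition.

    viability ratio v  -> (1 - v) * 100
    viability percent p -> 100 - p
    inhibition ratio r -> r * 100
    inhibition percent -> identity

    Raises ``ValueError`` on non-finite input.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite response value")
    out = _convert_array(arr, convention)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def from_percent_inhibition(value, convention: ResponseConvention):
    """Inverse of :func:`to_percent_inhibition` (exact round-trip)."""
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite response value")
    out = _invert_array(arr, convention)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out
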