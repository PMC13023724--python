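"""Probability densities over chemical shifts.

Two families of densities are used to score how well an experimental shift
matches a predicted one:

* **single Gaussians** — used when shifts are predicted discretely for a known
  crystal structure ("XS" mode): the density for site *i* is a normal
  distribution centred at the predicted shift with a width equal to the
  uncertainty of the prediction method.
* **uniform-weight Gaussian mixtures** — used when shifts are predicted from a
  database of fragment-matched environments ("DB" mode): one component per
  matched database entry, centred at that entry's predicted shift with that
  entry's predicted uncertainty, all with weight 1/K.

2D densities score a correlated ¹³C–¹H cross-peak.  For a single-Gaussian
pair the joint density is the product of the two marginals.  For a mixture the
components are *paired*: component k contributes p_k(y1)·p_k(y2), i.e. the
carbon and proton Gaussians of the same database fragment stay together — the
mixture is an average of K products, not a product of two averages.

All evaluation is available in log space; the assignment engine never leaves
the log domain until marginal probabilities are exponentiated for output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from .errors import ValidationError

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ShiftGaussian:
    """A normal distribution over one chemical shift, in ppm.

    Parameters
    ----------
    mean : float
        Predicted chemical shift (ppm).
    sigma : float
        Standard deviation (ppm); the uncertainty of the prediction.
    """

    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean)):
            raise ValidationError(f"ShiftGaussian mean must be finite, got {self.mean}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValidationError(f"ShiftGaussian sigma must be > 0, got {self.sigma}")

    def logpdf(self, y: float) -> float:
        z = (y - self.mean) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - _LOG_SQRT_2PI

    def pdf(self, y: float) -> float:
        return math.exp(self.logpdf(y))


@dataclass(frozen=True)
class ShiftMixture:
    """Uniform-weight mixture of :class:`ShiftGaussian` components (1D)."""

    components: tuple[ShiftGaussian, ...]

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValidationError("ShiftMixture needs at least one component")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def logpdf(self, y: float) -> float:
        logs = [c.logpdf(y) for c in self.components]
        m = max(logs)
        if m == -math.inf:
            return -math.inf
        s = sum(math.exp(v - m) for v in logs)
        return m + math.log(s) - math.log(len(logs))

    def pdf(self, y: float) -> float:
        return math.exp(self.logpdf(y))


@dataclass(frozen=True)
class ShiftGaussian2D:
    """Separable 2D Gaussian for a bonded ¹³C–¹H pair: p(y1, y2) = p_C(y1)·p_H(y2)."""

    carbon: ShiftGaussian
    proton: ShiftGaussian

    def logpdf(self, y1: float, y2: float) -> float:
        return self.carbon.logpdf(y1) + self.proton.logpdf(y2)

    def pdf(self, y1: float, y2: float) -> float:
        return math.exp(self.logpdf(y1, y2))


@dataclass(frozen=True)
class ShiftMixture2D:
    """Uniform-weight mixture of paired (carbon, proton) Gaussian products.

    Component k contributes p_k(y1)·p_k(y2); carbon/proton components from
    the same source fragment are kept together.
    """

    components: tuple[tuple[ShiftGaussian, ShiftGaussian], ...]

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValidationError("ShiftMixture2D needs at least one component")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def logpdf(self, y1: float, y2: float) -> float:
        logs = [c.logpdf(y1) + h.logpdf(y2) for c, h in self.components]
        m = max(logs)
        if m == -math.inf:
            return -math.inf
        s = sum(math.exp(v - m) for v in logs)
        return m + math.log(s) - math.log(len(logs))

    def pdf(self, y1: float, y2: float) -> float:
        return math.exp(self.logpdf(y1, y2))


Density1D = Union[ShiftGaussian, ShiftMixture]
Density2D = Union[ShiftGaussian2D, ShiftMixture2D]
Density = Union[Density1D, Density2D]


def is_2d(density: Density) -> bool:
    return isinstance(density, (ShiftGaussian2D, ShiftMixture2D))
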