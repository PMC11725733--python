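"""Linear freshness equations and their evaluation.

A :class:`LinearEquation` maps named metabolite concentrations (mg/dL) to a
freshness indicator.  The two reference equations relate total bacterial
count (TBC, log CFU/g) to lysine and malate, and volatile basic nitrogen
(VBN, mg/100 g) to methionine and niacinamide; they double as the ground
truth of the synthetic-data generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError

__all__ = [
    "LinearEquation",
    "TBC_EQUATION",
    "VBN_EQUATION",
    "evaluate_equation",
    "coefficient_ratio_report",
]


@dataclass(frozen=True)
class LinearEquation:
    """Intercept plus named linear terms, ``y = b0 + sum_j b_j x_j``."""

    name: str
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, inputs: Mapping[str, float]) -> float:
        return evaluate_equation(self, inputs)

    def to_text(self) -> str:
        terms = "".join(
            f" {c:+.6g}*({v})" for v, c in self.coefficients.items()
        )
        return f"{self.name} = {self.intercept:.6g}{terms}"


#: Reference TBC model: log CFU/g from lysine and malate (mg/dL).
TBC_EQUATION = LinearEquation("TBC", 2.316, {"lysine": 0.120, "malate": 0.288})

#: Reference VBN model: mg/100 g from methionine and niacinamide (mg/dL).
VBN_EQUATION = LinearEquation(
    "VBN", 9.727, {"methionine": 0.614, "niacinamide": -0.923}
)


def evaluate_equation(
    equation: LinearEquation, inputs: Mapping[str, float]
) -> float:
    """Evaluate ``equation`` at the named ``inputs``.

    Raises :class:`DomainError` naming the first missing variable.
    """
    total = equation.intercept
    for var, coef in equation.coefficients.items():
        if var not in inputs:
            raise DomainError(
                f"equation {equation.name!r} needs variable {var!r}, "
                f"absent from inputs"
            )
        total += coef * inputs[var]
    return total


def coefficient_ratio_report(equation: LinearEquation) -> dict[str, float]:
    """Pairwise |coefficient| ratios between the equation's terms.

    Returns a mapping ``"num/den" -> |b_num| / |b_den|`` for every ordered
    pair, plus ``"dominant"`` entries are implied by the largest magnitude
    term appearing as numerator.  Zero denominators yield ``inf``.
    """
    terms = list(equation.coefficients.items())
    if len(terms) < 2:
        raise DomainError(
            f"equation {equation.name!r} has fewer than two non-intercept terms"
        )
    ratios: dict[str, float] = {}
    for num, bn in terms:
        for den, bd in terms:
            if num == den:
                continue
            ratios[f"{num}/{den}"] = (
                math.inf if bd == 0 else abs(bn) / abs(bd)
            )
    return ratios
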