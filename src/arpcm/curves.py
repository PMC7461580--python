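"""Dose-response curves and their conversion to phenotype classes.

A curve records luciferase-reporter activity of one AR mutant treated with one
drug over an increasing concentration series, expressed as percent of
wild-type activity (100 = wild-type).  Four phenotypes are distinguished:

* ``non-responsive`` (0) — negligible activity at every dose,
* ``antagonist`` (1) — activity falls with dose and is suppressed at the top dose,
* ``agonist`` (2) — activity rises with dose and never drops below half of WT,
* ``mixed-response`` (3) — activity falls but recovers (u-shaped), the
  resistance-associated phenotype.

Classification is rule-based on three curve summaries: the mean activation
over all doses (vehicle control included), the activation at the first (0 μM)
and last grid point, and the minimum activation.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    DuplicateRecordError,
    EmptyInputError,
    MalformedCurveError,
    UnclassifiableCurveError,
)

logger = logging.getLogger(__name__)

#: Concentration grid of the reporter assay: vehicle control (0 μM) followed by
#: a ten-step serial dilution up to 50 μM.
DEFAULT_GRID: tuple[float, ...] = (
    0.0,
    0.0025,
    0.0076,
    0.023,
    0.069,
    0.206,
    0.617,
    1.852,
    5.556,
    16.667,
    50.0,
)


class PhenotypeLabel(IntEnum):
    """Phenotype class with its fixed integer code."""

    NON_RESPONSIVE = 0
    ANTAGONIST = 1
    AGONIST = 2
    MIXED_RESPONSE = 3

    @property
    def label(self) -> str:
        return _LABEL_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "PhenotypeLabel":
        for code, nm in _LABEL_NAMES.items():
            if nm == name:
                return code
        raise ValueError(f"unknown phenotype name {name!r}")


_LABEL_NAMES = {
    PhenotypeLabel.NON_RESPONSIVE: "non-responsive",
    PhenotypeLabel.ANTAGONIST: "antagonist",
    PhenotypeLabel.AGONIST: "agonist",
    PhenotypeLabel.MIXED_RESPONSE: "mixed-response",
}


@dataclass(frozen=True)
class DoseResponseCurve:
    """One mutant-drug dose-response curve.

    Parameters
    ----------
    mutant_id, drug_id
        Identifiers of the pair.
    concentrations
        Strictly increasing molar-scale doses in μM; the first entry must be 0
        (vehicle control).
    activations
        Percent-of-wild-type activation at each dose, same length.
    """

    mutant_id: str
    drug_id: str
    concentrations: tuple[float, ...]
    activations: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        act = tuple(float(a) for a in self.activations)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "activations", act)
        if len(conc) < 2:
            raise MalformedCurveError(
                f"curve ({self.mutant_id}, {self.drug_id}): needs at least 2 "
                f"grid points, got {len(conc)}"
            )
        if len(conc) != len(act):
            raise MalformedCurveError(
                f"curve ({self.mutant_id}, {self.drug_id}): {len(conc)} "
                f"concentrations but {len(act)} activations"
            )
        if conc[0] != 0.0:
            raise MalformedCurveError(
                f"curve ({self.mutant_id}, {self.drug_id}): first concentration "
                f"must be the 0 μM vehicle control, got {conc[0]}"
            )
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise MalformedCurveError(
                f"curve ({self.mutant_id}, {self.drug_id}): concentrations must "
                "be strictly increasing"
            )
        if not all(math.isfinite(a) for a in act):
            raise MalformedCurveError(
                f"curve ({self.mutant_id}, {self.drug_id}): non-finite activation"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.mutant_id, self.drug_id)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class CurveSummary:
    """Summary statistics a curve is classified on."""

    mean_activation: float
    a_zero: float
    a_max_conc: float
    min_activation: float


@dataclass(frozen=True)
class RuleThresholds:
    """Thresholds of the curve-to-class rules, in percent of WT activity.

    ``nonresponsive_mean_max``: mean activation below this is non-responsive.
    ``antagonist_top_max``: a decreasing curve ending below this is antagonist,
    otherwise (u-shaped recovery) mixed-response.
    ``agonist_min_floor``: an increasing curve is agonist only if its minimum
    stays above this.
    """

    nonresponsive_mean_max: float = 5.0
    antagonist_top_max: float = 10.0
    agonist_min_floor: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.nonresponsive_mean_max < self.antagonist_top_max < self.agonist_min_floor):
            raise ValueError(
                "thresholds must satisfy 0 < nonresponsive_mean_max < "
                "antagonist_top_max < agonist_min_floor, got "
                f"{self.nonresponsive_mean_max}, {self.antagonist_top_max}, "
                f"{self.agonist_min_floor}"
            )


def summarize_curve(curve: DoseResponseCurve) -> CurveSummary:
    """Compute the quantities the classification rules test.

    The mean runs over all grid points including the 0 μM control; the
    endpoint activations are read from the first and last grid point (50 μM on
    the default grid).
    """
    act = np.asarray(curve.activations, dtype=float)
    return CurveSummary(
        mean_activation=float(act.mean()),
        a_zero=float(act[0]),
        a_max_conc=float(act[-1]),
        min_activation=float(act.min()),
    )


def classify_curve(
    curve: DoseResponseCurve,
    thresholds: RuleThresholds | None = None,
    *,
    strict: bool = False,
) -> PhenotypeLabel:
    """Assign one of the four phenotype classes to a curve.

    Rule precedence (all comparisons strict):

    1. mean activation < ``nonresponsive_mean_max`` → non-responsive;
    2. top-dose activation below the 0 μM activation (decreasing trend) and
       below ``antagonist_top_max`` → antagonist;
    3. decreasing trend but top-dose activation at or above
       ``antagonist_top_max`` (u-shaped recovery) → mixed-response;
    4. non-decreasing trend with minimum activation above
       ``agonist_min_floor`` → agonist;
    5. residual (non-decreasing but minimum ≤ floor): the rules do not cover
       this case; it is assigned mixed-response with a warning, or raises
       :class:`UnclassifiableCurveError` when ``strict`` is true.

    A tie between the endpoint activations counts as non-decreasing, since a
    decreasing trend is defined strictly.
    """
    th = thresholds or RuleThresholds()
    s = summarize_curve(curve)
    if s.mean_activation < th.nonresponsive_mean_max:
        return PhenotypeLabel.NON_RESPONSIVE
    decreasing = s.a_max_conc < s.a_zero
    if decreasing:
        if s.a_max_conc < th.antagonist_top_max:
            return PhenotypeLabel.ANTAGONIST
        return PhenotypeLabel.MIXED_RESPONSE
    if s.min_activation > th.agonist_min_floor:
        return PhenotypeLabel.AGONIST
    msg = (
        f"curve ({curve.mutant_id}, {curve.drug_id}) falls in the residual "
        "case (non-decreasing trend, partial activation): assigning "
        "mixed-response"
    )
    if strict:
        raise UnclassifiableCurveError(msg)
    warnings.warn(msg, stacklevel=2)
    return PhenotypeLabel.MIXED_RESPONSE


@dataclass(frozen=True)
class LabelledCurve:
    mutant_id: str
    drug_id: str
    label: PhenotypeLabel


def label_dataset(
    curves: Iterable[DoseResponseCurve],
    thresholds: RuleThresholds | None = None,
    *,
    strict: bool = False,
) -> list[LabelledCurve]:
    """Classify every curve of a dataset; keys must be unique.

    Logs the resulting class frequency table.
    """
    curves = list(curves)
    if not curves:
        raise EmptyInputError("no curves to label")
    seen: set[tuple[str, str]] = set()
    out: list[LabelledCurve] = []
    for c in curves:
        if c.key in seen:
            raise DuplicateRecordError(f"duplicate curve key {c.key}")
        seen.add(c.key)
        out.append(LabelledCurve(c.mutant_id, c.drug_id, classify_curve(c, thresholds, strict=strict)))
    freq = Counter(rec.label for rec in out)
    logger.info(
        "labelled %d curves: %s",
        len(out),
        {lab.label: freq.get(lab, 0) for lab in PhenotypeLabel},
    )
    return out
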