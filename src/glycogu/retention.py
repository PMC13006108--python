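"""Additive HILIC retention model in glucose units, with modification
coefficients.

The base model is composition-additive: a peptide's GU retention is the sum
of per-residue GU increments plus optional terminus/intercept terms, as in
published additive HILIC models for unmodified tryptic peptides. A
modification (here, glycation) contributes a single GU coefficient per
event on top of the base value — derived empirically as the mean GU shift
between glycated peptides and their unmodified counterparts.

Two glycation coefficient presets ship with the package: +0.35 GU derived
from standard peptides and in vitro glycated proteins, and +0.52 GU derived
from IgG tryptic test cases (used for the Glu-C workflow, where the base
model does not cover the peptides and the observed unmodified GU is used
instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve, gu_to_min
from .digestion import Glycoform, Peptide
from .masses import CANONICAL_RESIDUES, ModificationSpec

#: Glycation GU coefficient from standard peptides/proteins.
GLYCATION_GU_STANDARDS = 0.35
#: Glycation GU coefficient pooled from IgG tryptic test cases.
GLYCATION_GU_IGG = 0.52


@dataclass(frozen=True)
class CoefficientTable:
    """Per-residue, terminus and per-modification GU increments."""

    residue_gu: dict[str, float]
    term_gu: dict[str, float] = field(default_factory=dict)
    modification_gu: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = sorted(CANONICAL_RESIDUES - set(self.residue_gu))
        if missing:
            raise ValueError(
                "missing coefficient for " + ", ".join(missing)
            )
        for name, value in {**self.residue_gu, **self.term_gu,
                            **self.modification_gu}.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite coefficient for {name!r}")


@dataclass(frozen=True)
class CoefficientEstimate:
    """Results of deriving a modification GU coefficient from paired
    glycated/unmodified observations."""

    modification: str
    mean_shift_gu: float
    sd_gu: float
    n: int
    per_pair_shifts: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.n != len(self.per_pair_shifts):
            raise ValueError("n must equal the number of per-pair shifts")

    def summary(self) -> str:
        lines = [
            f"GU retention coefficient for {self.modification}",
            f"  mean shift: {self.mean_shift_gu:+.4f} GU",
            f"  sd (n-1):   {self.sd_gu:.4f} GU",
            f"  n pairs:    {self.n}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class RetentionPrediction:
    """A predicted GU retention with its additive breakdown.

    ``components`` maps contribution labels (residues aggregated as
    ``base``, terminus terms, modification names) to GU increments;
    ``predicted_gu`` is exactly their sum.
    """

    predicted_gu: float
    components: tuple[tuple[str, float], ...]
    peptide: Peptide | None = None
    glycoform: Glycoform | None = None
    predicted_min: float | None = None

    def with_minutes(self, curve: CalibrationCurve) -> "RetentionPrediction":
        return RetentionPrediction(
            predicted_gu=self.predicted_gu,
            components=self.components,
            peptide=self.peptide,
            glycoform=self.glycoform,
            predicted_min=gu_to_min(self.predicted_gu, curve),
        )


def predict_gu(peptide: Peptide | str, table: CoefficientTable) -> RetentionPrediction:
    """Base GU retention of an unmodified peptide from the additive model.

    Accepts a ``Peptide`` or a bare sequence string. The base value is the
    sum of residue coefficients plus any ``nterm``/``cterm``/``intercept``
    terms present in the table.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    bad = sorted(set(seq) - set(table.residue_gu))
    if bad:
        raise ValueError(f"residue(s) {bad} absent from coefficient table")
    base = sum(table.residue_gu[r] for r in seq)
    components = [("base", base)]
    for term in ("intercept", "nterm", "cterm"):
        if term in table.term_gu:
            components.append((term, table.term_gu[term]))
    total = math.fsum(v for _, v in components)
    return RetentionPrediction(
        predicted_gu=total,
        components=tuple(components),
        peptide=peptide if isinstance(peptide, Peptide) else None,
    )


def predict_modified_gu(
    base: RetentionPrediction,
    mods: list[ModificationSpec],
    table: CoefficientTable,
    glycoform: Glycoform | None = None,
) -> RetentionPrediction:
    """Add per-event modification GU coefficients to a base prediction.

    Exact arithmetic, no refit: each applied modification event adds its
    coefficient once, so a doubly glycated candidate adds the glycation
    coefficient twice (an extrapolation beyond single-event observations;
    reports flag it).
    """
    components = list(base.components)
    for mod in mods:
        if mod.name not in table.modification_gu:
            raise ValueError(f"no GU coefficient for modification {mod.name!r}")
        components.append((mod.name, table.modification_gu[mod.name]))
    return RetentionPrediction(
        predicted_gu=math.fsum(v for _, v in components),
        components=tuple(components),
        peptide=base.peptide,
        glycoform=glycoform if glycoform is not None else base.glycoform,
    )


def base_gu_from_observation(
    observed_unmodified_gu: float, label: str = "observed"
) -> RetentionPrediction:
    """Wrap an experimentally observed base GU as a prediction.

    Used when the additive model does not cover an enzyme's peptides (e.g.
    Glu-C digests): the modification coefficient is added to the observed
    GU of the unmodified variant instead of a modelled base value.
    """
    if not math.isfinite(observed_unmodified_gu):
        raise ValueError("observed GU must be finite")
    return RetentionPrediction(
        predicted_gu=observed_unmodified_gu,
        components=((label, observed_unmodified_gu),),
    )


def derive_coefficient(
    pairs: list[tuple[float, float, str]], modification: str = "glycation"
) -> CoefficientEstimate:
    """Derive a modification GU coefficient from paired observations.

    ``pairs`` holds ``(unmodified_gu, modified_gu, label)`` tuples; each
    pair contributes one shift ``modified - unmodified``. The estimate is
    the arithmetic mean with the sample (n-1) standard deviation. Duplicate
    labels are treated as independent measurements.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to derive a coefficient")
    shifts = tuple((label, mod - unmod) for unmod, mod, label in pairs)
    values = np.array([d for _, d in shifts], dtype=float)
    return CoefficientEstimate(
        modification=modification,
        mean_shift_gu=float(values.mean()),
        sd_gu=float(values.std(ddof=1)),
        n=len(values),
        per_pair_shifts=shifts,
    )
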