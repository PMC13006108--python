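"""MS1 feature matching and end-to-end glycation screening.

Identification rests on two orthogonal measurements, exactly as the
workflow defines them: accurate mass (theoretical m/z within a ppm
tolerance of an observed feature) and HILIC retention (predicted GU within
a window of the observed GU, obtained through the dextran calibration).
MS/MS evidence is deliberately not modelled — glycated ions are typically
too low-abundance for data-dependent MS2 selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .calibration import CalibrationCurve, ExtrapolationWarning, min_to_gu
from .digestion import (
    CleavageRule,
    Glycoform,
    SiteAssignment,
    assign_site,
    digest,
    enumerate_glycoforms,
)
from .masses import (
    CARBAMIDOMETHYL,
    GLYCATION,
    ModificationSpec,
    apply_fixed_modifications,
    mz as compute_mz,
    peptide_mass,
    ppm_error,
)
from .retention import (
    CoefficientTable,
    RetentionPrediction,
    predict_gu,
    predict_modified_gu,
)

UNMODIFIED_ASSIGNMENT = SiteAssignment("unmodified", "no variable modification")


@dataclass(frozen=True)
class FeatureObservation:
    """An MS1 feature: apex m/z, retention time and intensity."""

    mz: float
    rt_min: float
    intensity: float
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.rt_min < 0:
            raise ValueError("rt_min must be non-negative")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be a positive integer when present")


@dataclass(frozen=True)
class Candidate:
    """A theoretical species: prediction plus monoisotopic mass."""

    sequence: str
    monoisotopic_mass: float
    prediction: RetentionPrediction
    modifications: tuple[str, ...] = ()
    glycoform: Glycoform | None = None
    site_assignment: SiteAssignment = UNMODIFIED_ASSIGNMENT

    @property
    def predicted_gu(self) -> float:
        return self.prediction.predicted_gu

    @property
    def is_glycated(self) -> bool:
        return "glycation" in self.modifications


@dataclass(frozen=True)
class MatchResult:
    candidate: Candidate
    charge: int
    theoretical_mz: float
    observed: FeatureObservation
    ppm_error: float
    predicted_gu: float
    observed_gu: float
    delta_gu: float
    note: str = ""

    @property
    def peptide_sequence(self) -> str:
        return self.candidate.sequence

    @property
    def modifications_label(self) -> str:
        if not self.candidate.modifications:
            return "-"
        if self.candidate.glycoform is not None:
            sites = ";".join(str(s) for s in self.candidate.glycoform.sites)
            return f"glycation[{sites}]"
        return ";".join(self.candidate.modifications)

    @property
    def site_assignment(self) -> SiteAssignment:
        return self.candidate.site_assignment


def match(
    candidates: Sequence[Candidate],
    features: Sequence[FeatureObservation],
    curve: CalibrationCurve,
    ppm_tol: float = 100.0,
    gu_window: float = 0.5,
    charges: Iterable[int] = (1, 2, 3, 4),
    all_matches: bool = False,
) -> list[MatchResult]:
    """Match theoretical candidates to MS1 features.

    A (candidate, charge, feature) triple is in-window when the signed mass
    error is within ``ppm_tol`` ppm and |observed GU - predicted GU| is
    within ``gu_window``. A feature annotated with a charge is only tried
    at that charge. By default every feature keeps only its best candidate,
    ranked by |ppm error|, then |delta GU|, then shorter peptide, then
    lexicographic sequence; ``all_matches`` emits every in-window pair.
    Output order is deterministic: by sequence, charge, then feature m/z.
    """
    if ppm_tol <= 0 or gu_window <= 0:
        raise ValueError("ppm_tol and gu_window must be positive")
    if not candidates or not features:
        return []
    charges = sorted(set(charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive integers")

    feat_mz = np.array([f.mz for f in features])
    order = np.argsort(feat_mz, kind="stable")
    sorted_mz = feat_mz[order]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        feat_gu = np.array([min_to_gu(f.rt_min, curve) for f in features])

    per_feature: dict[int, list[tuple]] = {}
    for ci, cand in enumerate(candidates):
        for z in charges:
            theo = compute_mz(cand.monoisotopic_mass, z)
            half = theo * ppm_tol / 1e6
            lo = np.searchsorted(sorted_mz, theo - half, side="left")
            hi = np.searchsorted(sorted_mz, theo + half, side="right")
            for fi in order[lo:hi]:
                feature = features[fi]
                if feature.charge is not None and feature.charge != z:
                    continue
                err = ppm_error(feature.mz, theo)
                if abs(err) > ppm_tol:
                    continue
                delta = feat_gu[fi] - cand.predicted_gu
                if abs(delta) > gu_window:
                    continue
                key = (abs(err), abs(delta), len(cand.sequence), cand.sequence, z)
                per_feature.setdefault(int(fi), []).append(
                    (key, ci, z, theo, err, float(delta), float(feat_gu[fi]))
                )

    results = []
    for fi, entries in per_feature.items():
        entries.sort(key=lambda e: e[0])
        chosen = entries if all_matches else entries[:1]
        for _, ci, z, theo, err, delta, obs_gu in chosen:
            cand = candidates[ci]
            results.append(
                MatchResult(
                    candidate=cand,
                    charge=z,
                    theoretical_mz=theo,
                    observed=features[fi],
                    ppm_error=err,
                    predicted_gu=cand.predicted_gu,
                    observed_gu=obs_gu,
                    delta_gu=delta,
                )
            )
    results.sort(
        key=lambda m: (m.peptide_sequence, m.modifications_label, m.charge,
                       m.observed.mz, m.observed.rt_min)
    )
    return results


def build_candidates(
    protein,
    rule: CleavageRule,
    table: CoefficientTable,
    max_missed: int = 1,
    max_glycations: int = 1,
    fixed_mods: Sequence[ModificationSpec] = (CARBAMIDOMETHYL,),
) -> list[Candidate]:
    """Digest a protein and build unmodified + glycated candidates.

    Glycated candidates only exist for peptides with admissible sites; for
    trypsin that means missed-cleavage lysines or the protein N-terminus.
    Each glycation event adds the +162.05282 Da Amadori mass and one GU
    coefficient from the table.
    """
    candidates = []
    for peptide in digest(protein, rule, max_missed):
        fixed = apply_fixed_modifications(peptide.sequence, list(fixed_mods))
        base_mass = peptide_mass(peptide.sequence, fixed)
        base_pred = predict_gu(peptide, table)
        candidates.append(
            Candidate(
                sequence=peptide.sequence,
                monoisotopic_mass=base_mass.monoisotopic_mass,
                prediction=base_pred,
                modifications=tuple(m.name for m in fixed),
            )
        )
        for form in enumerate_glycoforms(peptide, rule, max_glycations):
            mods = fixed + [GLYCATION] * form.n_glycations
            mass = peptide_mass(peptide.sequence, mods)
            pred = predict_modified_gu(
                base_pred, [GLYCATION] * form.n_glycations, table, glycoform=form
            )
            candidates.append(
                Candidate(
                    sequence=peptide.sequence,
                    monoisotopic_mass=mass.monoisotopic_mass,
                    prediction=pred,
                    modifications=tuple(m.name for m in mods),
                    glycoform=form,
                    site_assignment=assign_site(form, rule),
                )
            )
    return candidates


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of an end-to-end glycation screen of one protein."""

    matches: tuple[MatchResult, ...]
    unmatched_glycated: tuple[Candidate, ...]
    n_candidates: int

    @property
    def glycated_matches(self) -> tuple[MatchResult, ...]:
        return tuple(m for m in self.matches if m.candidate.is_glycated)

    @property
    def unmodified_matches(self) -> tuple[MatchResult, ...]:
        return tuple(m for m in self.matches if not m.candidate.is_glycated)

    def summary(self) -> str:
        return (
            f"screened {self.n_candidates} candidates: "
            f"{len(self.glycated_matches)} glycated and "
            f"{len(self.unmodified_matches)} unmodified matches; "
            f"{len(self.unmatched_glycated)} glycated candidates unmatched"
        )


def screen_glycated(
    protein,
    rule: CleavageRule,
    table: CoefficientTable,
    features: Sequence[FeatureObservation],
    curve: CalibrationCurve,
    max_missed: int = 1,
    max_glycations: int = 1,
    ppm_tol: float = 100.0,
    gu_window: float = 0.5,
    charges: Iterable[int] = (1, 2, 3, 4),
    fixed_mods: Sequence[ModificationSpec] = (CARBAMIDOMETHYL,),
) -> ScreenReport:
    """Full pipeline: digest, enumerate glycoforms, predict, match, assign.

    Glycated matches whose unmodified missed-cleavage partner was not
    detected are annotated ``unmodified partner undetected`` — a common
    situation, since trypsin cleaves unmodified K/R efficiently and the
    unmodified missed-cleavage peptide may fall below detection.
    """
    candidates = build_candidates(
        protein, rule, table, max_missed, max_glycations, fixed_mods
    )
    results = match(candidates, features, curve, ppm_tol, gu_window, charges)
    matched_unmod_seqs = {
        m.peptide_sequence for m in results if not m.candidate.is_glycated
    }
    annotated = []
    for m in results:
        if m.candidate.is_glycated and m.peptide_sequence not in matched_unmod_seqs:
            m = replace(m, note="unmodified partner undetected")
        annotated.append(m)
    matched_glyco_ids = {
        id(m.candidate) for m in results if m.candidate.is_glycated
    }
    unmatched = tuple(
        c for c in candidates if c.is_glycated and id(c) not in matched_glyco_ids
    )
    return ScreenReport(
        matches=tuple(annotated),
        unmatched_glycated=unmatched,
        n_candidates=len(candidates),
    )
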