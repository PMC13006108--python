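"""On-disk formats: FASTA proteins and TSV tables.

All tabular artifacts are tab-separated UTF-8 with a header row. Numeric
columns are written with fixed precision (4 decimals for GU, minutes and
m/z; 1 decimal for ppm error) and validation is strict: every error names
the offending record or row, and nothing is silently coerced or skipped.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .calibration import CalibrationCurve, LadderTable
from .masses import CANONICAL_RESIDUES
from .retention import CoefficientTable

_MOD_TERM_KEYS = {"nterm", "cterm", "intercept"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its FASTA identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: non-canonical residue {ch!r} at position {pos}"
                )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; non-canonical residues raise with the record
    id and 1-based position. Duplicate ids are rejected.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                header = f">{rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        return list(reader)


def read_ladder(path: str | Path, run_label: str | None = None) -> LadderTable:
    """Read a dextran-ladder TSV with columns gu_index, rt_min.

    Rows are sorted by gu_index before validation; monotonicity of rt_min
    and the >= 3 rung minimum are enforced by ``LadderTable``.
    """
    rows = _read_tsv(path, ["gu_index", "rt_min"])
    rungs = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        try:
            rungs.append((int(row["gu_index"]), float(row["rt_min"])))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    rungs.sort(key=lambda r: r[0])
    return LadderTable(run_label=run_label or Path(path).stem, rungs=tuple(rungs))


def write_ladder(ladder: LadderTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gu_index", "rt_min"])
        for gu, rt in ladder.rungs:
            writer.writerow([gu, f"{rt:.4f}"])


def read_coefficient_table(path: str | Path) -> CoefficientTable:
    """Read a GU coefficient TSV with columns key, gu_coefficient.

    Keys are the 20 residue letters (all required), the optional terminus
    terms ``nterm``/``cterm``/``intercept``, and modification names
    (e.g. ``glycation``). Duplicate keys are an error.
    """
    rows = _read_tsv(path, ["key", "gu_coefficient"])
    residue_gu: dict[str, float] = {}
    term_gu: dict[str, float] = {}
    modification_gu: dict[str, float] = {}
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        key = row["key"].strip()
        if key in seen:
            raise ValueError(f"{path}: line {i}: duplicate key {key!r}")
        seen.add(key)
        try:
            value = float(row["gu_coefficient"])
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        if key in CANONICAL_RESIDUES:
            residue_gu[key] = value
        elif key in _MOD_TERM_KEYS:
            term_gu[key] = value
        else:
            modification_gu[key] = value
    return CoefficientTable(residue_gu, term_gu, modification_gu)


def write_coefficient_table(table: CoefficientTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["key", "gu_coefficient"])
        for key in sorted(table.residue_gu):
            writer.writerow([key, f"{table.residue_gu[key]:.6f}"])
        for key in sorted(table.term_gu):
            writer.writerow([key, f"{table.term_gu[key]:.6f}"])
        for key in sorted(table.modification_gu):
            writer.writerow([key, f"{table.modification_gu[key]:.6f}"])


def read_feature_table(path: str | Path):
    """Read an MS1 feature TSV: columns mz, rt_min, intensity[, charge]."""
    from .matching import FeatureObservation  # deferred: matching imports types only

    rows = _read_tsv(path, ["mz", "rt_min", "intensity"])
    features = []
    for i, row in enumerate(rows, start=2):
        try:
            charge = None
            raw = row.get("charge", "")
            if raw not in ("", None, "NA", "."):
                charge = int(raw)
            features.append(
                FeatureObservation(
                    mz=float(row["mz"]),
                    rt_min=float(row["rt_min"]),
                    intensity=float(row["intensity"]),
                    charge=charge,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return features


def write_feature_table(features, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["mz", "rt_min", "intensity", "charge"])
        for f in features:
            writer.writerow(
                [f"{f.mz:.4f}", f"{f.rt_min:.4f}", f"{f.intensity:.1f}",
                 "" if f.charge is None else f.charge]
            )


def read_pairs(path: str | Path) -> list[tuple[float, float, str]]:
    """Read paired glycated/unmodified GU observations for coefficient
    derivation: columns label, unmodified_gu, modified_gu."""
    rows = _read_tsv(path, ["label", "unmodified_gu", "modified_gu"])
    pairs = []
    for i, row in enumerate(rows, start=2):
        try:
            pairs.append(
                (float(row["unmodified_gu"]), float(row["modified_gu"]),
                 row["label"].strip())
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return pairs


REPORT_COLUMNS = [
    "peptide", "modifications", "site_assignment", "charge",
    "theoretical_mz", "observed_mz", "ppm_error",
    "predicted_gu", "observed_gu", "delta_gu",
]


def write_report(matches, path: str | Path) -> None:
    """Write match results as a TSV report, ordered by peptide then charge."""
    ordered = sorted(matches, key=lambda m: (m.peptide_sequence, m.charge))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(REPORT_COLUMNS)
        for m in ordered:
            writer.writerow(
                [
                    m.peptide_sequence,
                    m.modifications_label,
                    m.site_assignment.verdict,
                    m.charge,
                    f"{m.theoretical_mz:.4f}",
                    f"{m.observed.mz:.4f}",
                    f"{m.ppm_error:.1f}",
                    f"{m.predicted_gu:.4f}",
                    f"{m.observed_gu:.4f}",
                    f"{m.delta_gu:.4f}",
                ]
            )


def read_report(path: str | Path) -> list[dict[str, str]]:
    """Re-read a match report as raw string rows (round-trip checks)."""
    return _read_tsv(path, REPORT_COLUMNS)


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    """Serialize a calibration curve as JSON."""
    payload = {
        "a": curve.intercept_a,
        "b": curve.slope_b,
        "rmse": curve.fit_rmse,
        "n_rungs": curve.n_rungs,
        "source_runs": list(curve.source_runs),
        "rt_range": list(curve.rt_range),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_curve(path: str | Path) -> CalibrationCurve:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CalibrationCurve(
        intercept_a=payload["a"],
        slope_b=payload["b"],
        fit_rmse=payload["rmse"],
        n_rungs=payload["n_rungs"],
        source_runs=tuple(payload["source_runs"]),
        rt_range=tuple(payload.get("rt_range", (0.0, float("inf")))),
    )
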