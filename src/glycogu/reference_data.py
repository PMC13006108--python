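"""Bundled reference measurements of HILIC glycation retention shifts.

Three published measurement sets ship with the package as TSV data:

* ``standards_glycation_shifts`` — per-peptide retention shifts upon
  glycation (minutes and GU) for standard peptides and in vitro glycated
  bovine proteins; the source of the +0.35 GU standards-derived
  coefficient.
* ``igg1_tryptic_glycation`` / ``igg4_tryptic_glycation`` — paired
  predicted/observed retention for tryptic peptides of glycated IgG1
  (adalimumab) and IgG4 (natalizumab); their shifts pool to the +0.52 GU
  IgG-derived coefficient.
* ``igg1_gluc_glycation`` — Glu-C peptides of glycated IgG1, where the
  glycated GU is predicted from the observed unmodified GU plus 0.52.

Site markers use ``K<pos>`` (1-based position within the peptide) or
``protein-N-term``. Duplicate sequences are independent measurements.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA_PACKAGE = "glycogu.data"


def _load(name: str) -> pd.DataFrame:
    ref = resources.files(_DATA_PACKAGE).joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def standards_shift_table() -> pd.DataFrame:
    """Glycation retention shifts of standard peptides and proteins.

    Columns: analyte, sequence, site, shift_min, shift_gu. One row per
    measured glycated/unmodified pair (17 pairs).
    """
    return _load("standards_glycation_shifts.tsv")


def igg_tryptic_shifts(mab: str = "adalimumab") -> pd.DataFrame:
    """Paired predicted/observed retention for glycated IgG tryptic peptides.

    ``mab`` is ``"adalimumab"`` (IgG1) or ``"natalizumab"`` (IgG4). Rows
    alternate unmodified/glycated variants per peptide; GU shifts are on
    the glycated rows.
    """
    files = {
        "adalimumab": "igg1_tryptic_glycation.tsv",
        "natalizumab": "igg4_tryptic_glycation.tsv",
    }
    if mab not in files:
        raise ValueError(f"unknown mAb {mab!r}; expected one of {sorted(files)}")
    return _load(files[mab])


def gluc_gu_observations() -> pd.DataFrame:
    """Glu-C peptides of glycated IgG1 with observed and predicted GU."""
    return _load("igg1_gluc_glycation.tsv")


def shifts_as_pairs(frame: pd.DataFrame, shift_column: str = "shift_gu",
                    label_column: str = "sequence") -> list[tuple[float, float, str]]:
    """Express printed shifts as (unmodified, modified, label) GU pairs.

    When only shifts are published, anchoring each pair at 0 GU preserves
    the per-pair delta that coefficient derivation consumes.
    """
    rows = frame.dropna(subset=[shift_column])
    return [
        (0.0, float(r[shift_column]), str(r[label_column]))
        for _, r in rows.iterrows()
    ]
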