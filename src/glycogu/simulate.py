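"""Seeded synthetic data with the statistical structure the workflow
assumes.

The generator emulates a HILIC-MS glycation experiment end to end:
proteins with tryptic sites, a dextran ladder obeying the logarithmic
rt = a + b*ln(GU) law with small retention noise, a composition-additive
"true" GU coefficient table, and MS1 feature tables in which every tryptic
peptide appears unmodified and a seeded subset of admissible glycation
sites carries a +162.05282 Da partner whose GU shift is drawn from a
normal distribution centred on the glycation retention coefficient
(default N(0.35, 0.12^2), the empirical shift statistics from standards).

Everything is a pure function of (config, seed): the same configuration
reproduces the same tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import LadderTable
from .digestion import TRYPSIN, digest, enumerate_glycoforms
from .io import ProteinRecord
from .masses import (
    GLYCATION,
    apply_fixed_modifications,
    mz as compute_mz,
    peptide_mass,
)
from .matching import FeatureObservation
from .retention import CoefficientTable, predict_gu

# residue draw weights: roughly vertebrate proteome composition with K/R
# upweighted so that tryptic sites are plentiful
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_WEIGHTS = np.array(
    [7.4, 1.5, 5.3, 6.5, 4.0, 6.8, 2.3, 5.5, 7.0, 9.1,
     2.2, 4.3, 5.0, 4.0, 6.5, 7.5, 5.7, 6.5, 1.3, 3.2]
)
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    ``gu_shift_mean``/``gu_shift_sd`` are the glycation GU shift statistics
    (+0.35 GU, SD 0.12 GU from the standards-derived coefficient).
    ``ladder_a``/``ladder_b`` place dextran rungs on a 40-minute HILIC
    gradient (GU 2 near 6 min, GU 15 near 28 min). Noise defaults are
    modest, in line with bracketed-calibrant reproducibility.
    """

    seed: int = 0
    n_proteins: int = 3
    protein_length_range: tuple[int, int] = (80, 160)
    glycation_fraction: float = 0.5
    gu_shift_mean: float = 0.35
    gu_shift_sd: float = 0.12
    ladder_a: float = -1.4
    ladder_b: float = 10.7
    ladder_gu_range: tuple[int, int] = (2, 15)
    ladder_noise_sd_min: float = 0.05
    mz_jitter_ppm_sd: float = 10.0
    rt_noise_gu_sd: float = 0.05
    max_missed: int = 1
    charges: tuple[int, ...] = (1, 2, 3, 4)
    annotate_charge: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.glycation_fraction <= 1.0:
            raise ValueError("glycation_fraction must be a probability")
        for name in ("gu_shift_sd", "ladder_noise_sd_min",
                     "mz_jitter_ppm_sd", "rt_noise_gu_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ladder_b <= 0:
            raise ValueError("ladder_b must be positive")


@dataclass(frozen=True)
class PlantedGlycoform:
    """Ground-truth record for one planted feature."""

    protein_id: str
    sequence: str
    start: int
    end: int
    site: str  # "K<pos>" | "protein-N-term" | "-" for unmodified
    charge: int
    mz: float
    gu: float
    shift_gu: float


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_proteins(config: SimulationConfig) -> list[ProteinRecord]:
    """Random canonical-alphabet proteins with at least one tryptic site."""
    rng = _rng(config, 1)
    lo, hi = config.protein_length_range
    proteins = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(_ALPHABET), size=length, p=_WEIGHTS))
        if not TRYPSIN.cut_sites("".join(seq)):
            seq[length // 2] = "K"
            if length // 2 + 1 < length and seq[length // 2 + 1] == "P":
                seq[length // 2 + 1] = "A"
        proteins.append(ProteinRecord(id=f"sim{i + 1}", sequence="".join(seq)))
    return proteins


def simulate_coefficient_table(config: SimulationConfig) -> CoefficientTable:
    """A composition-additive 'true' coefficient table.

    Residue GU increments are uniform in [0.0, 0.6]; an intercept of 2 GU
    keeps every peptide on the calibrated part of the GU scale. The
    glycation coefficient equals ``gu_shift_mean``, so predictor and
    simulator share one model family by construction.
    """
    rng = _rng(config, 2)
    residue_gu = {r: float(rng.uniform(0.0, 0.6)) for r in sorted(_ALPHABET)}
    return CoefficientTable(
        residue_gu=residue_gu,
        term_gu={"intercept": 2.0},
        modification_gu={"glycation": config.gu_shift_mean},
    )


def simulate_ladder(config: SimulationConfig, run_offset: float = 0.0) -> LadderTable:
    """A dextran ladder obeying rt = a + offset + b*ln(GU) + noise.

    The rung noise stream depends only on the seed, not the offset, so
    bracketing runs that differ only in offset share their noise and
    average back to the offset-free ladder. Draws are repeated (seeded)
    until the noisy ladder is monotone.
    """
    rng = _rng(config, 3)
    lo, hi = config.ladder_gu_range
    gu = np.arange(lo, hi + 1)
    clean = config.ladder_a + run_offset + config.ladder_b * np.log(gu)
    for _ in range(100):
        noise = rng.normal(0.0, config.ladder_noise_sd_min, size=gu.size)
        rt = clean + noise
        if np.all(np.diff(rt) > 0):
            break
    else:  # pragma: no cover - noise far above default would be needed
        rt = clean
    label = f"dextran(offset={run_offset:+.3f})"
    return LadderTable(run_label=label, rungs=tuple(zip(gu.tolist(), rt.tolist())))


def _ladder_law_rt(gu: float, config: SimulationConfig) -> float:
    return config.ladder_a + config.ladder_b * float(np.log(gu))


def _pick_charge(mass: float, charges: tuple[int, ...]) -> int:
    """Smallest configured charge putting the ion inside m/z 300-2000."""
    for z in sorted(charges):
        if compute_mz(mass, z) <= 2000.0:
            return z
    return max(charges)


def simulate_features(
    proteins: list[ProteinRecord], config: SimulationConfig
) -> tuple[list[FeatureObservation], list[PlantedGlycoform]]:
    """MS1 features for unmodified tryptic peptides and planted glycoforms.

    Every tryptic peptide (0..max_missed missed cleavages) yields one
    unmodified feature at its model GU plus N(0, rt_noise_gu_sd) GU noise.
    Each admissible glycation site is planted with probability
    ``glycation_fraction``: a +162.05282 Da feature whose GU sits
    base + N(gu_shift_mean, gu_shift_sd^2). All m/z values carry
    multiplicative N(0, mz_jitter_ppm_sd) ppm jitter. The returned truth
    table records every planted species, glycated and unmodified.
    """
    rng = _rng(config, 4)
    table = simulate_coefficient_table(config)
    features: list[FeatureObservation] = []
    truth: list[PlantedGlycoform] = []

    def _emit(mass: float, gu: float, intensity: float):
        z = _pick_charge(mass, config.charges)
        theo = compute_mz(mass, z)
        jitter = rng.normal(0.0, config.mz_jitter_ppm_sd) * 1e-6
        obs_mz = theo * (1.0 + jitter)
        rt = _ladder_law_rt(gu, config)
        features.append(
            FeatureObservation(
                mz=obs_mz,
                rt_min=rt,
                intensity=intensity,
                charge=z if config.annotate_charge else None,
            )
        )
        return z, obs_mz

    for protein in proteins:
        for peptide in digest(protein, TRYPSIN, config.max_missed):
            fixed = apply_fixed_modifications(peptide.sequence)
            base_mass = peptide_mass(peptide.sequence, fixed).monoisotopic_mass
            base_pred = predict_gu(peptide, table)
            obs_gu = base_pred.predicted_gu + rng.normal(0.0, config.rt_noise_gu_sd)
            intensity = float(rng.lognormal(mean=11.5, sigma=0.8))
            z, obs_mz = _emit(base_mass, obs_gu, intensity)
            truth.append(
                PlantedGlycoform(
                    protein_id=protein.id,
                    sequence=peptide.sequence,
                    start=peptide.start,
                    end=peptide.end,
                    site="-",
                    charge=z,
                    mz=obs_mz,
                    gu=obs_gu,
                    shift_gu=0.0,
                )
            )
            for form in enumerate_glycoforms(peptide, TRYPSIN, max_glycations=1):
                if rng.uniform() >= config.glycation_fraction:
                    continue
                shift = rng.normal(config.gu_shift_mean, config.gu_shift_sd)
                glyco_gu = base_pred.predicted_gu + shift
                glyco_mass = base_mass + GLYCATION.delta_monoisotopic
                intensity = float(rng.lognormal(mean=7.5, sigma=0.8))
                z, obs_mz = _emit(glyco_mass, glyco_gu, intensity)
                truth.append(
                    PlantedGlycoform(
                        protein_id=protein.id,
                        sequence=peptide.sequence,
                        start=peptide.start,
                        end=peptide.end,
                        site=str(form.sites[0]),
                        charge=z,
                        mz=obs_mz,
                        gu=glyco_gu,
                        shift_gu=float(shift),
                    )
                )
    return features, truth


def write_truth_table(truth: list[PlantedGlycoform], path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["protein_id", "sequence", "start", "end", "site",
             "charge", "mz", "gu", "shift_gu"]
        )
        for t in truth:
            writer.writerow(
                [t.protein_id, t.sequence, t.start, t.end, t.site,
                 t.charge, f"{t.mz:.4f}", f"{t.gu:.4f}", f"{t.shift_gu:.4f}"]
            )
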