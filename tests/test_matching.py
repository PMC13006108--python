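"""MS1 feature matching, tie-breaking and the end-to-end screen."""

import math

import numpy as np
import pytest

from glycogu.calibration import CalibrationCurve, fit_calibration
from glycogu.digestion import TRYPSIN
from glycogu.masses import mz as compute_mz, ppm_error
from glycogu.matching import (
    Candidate,
    FeatureObservation,
    match,
    screen_glycated,
)
from glycogu.retention import RetentionPrediction
from glycogu.simulate import (
    SimulationConfig,
    simulate_coefficient_table,
    simulate_features,
    simulate_ladder,
    simulate_proteins,
)

CURVE = CalibrationCurve(
    intercept_a=2.0, slope_b=3.0, fit_rmse=0.0, n_rungs=14,
    source_runs=("synthetic",),
    rt_range=(2.0 + 3.0 * math.log(2), 2.0 + 3.0 * math.log(15)),
)


def _cand(sequence, mass, gu, mods=()):
    return Candidate(
        sequence=sequence,
        monoisotopic_mass=mass,
        prediction=RetentionPrediction(predicted_gu=gu, components=(("base", gu),)),
        modifications=mods,
    )


def _feature_at(gu, mz_value, intensity=100.0, charge=None):
    rt = CURVE.intercept_a + CURVE.slope_b * math.log(gu)
    return FeatureObservation(mz=mz_value, rt_min=rt, intensity=intensity,
                              charge=charge)


def brute_force_match(candidates, features, curve, ppm_tol, gu_window, charges,
                      all_matches=False):
    """All-pairs oracle with the same in-window and tie-break contract."""
    per_feature = {}
    for fi, f in enumerate(features):
        gu = math.exp((f.rt_min - curve.intercept_a) / curve.slope_b)
        entries = []
        for ci, c in enumerate(candidates):
            for z in sorted(set(charges)):
                if f.charge is not None and f.charge != z:
                    continue
                theo = compute_mz(c.monoisotopic_mass, z)
                err = ppm_error(f.mz, theo)
                delta = gu - c.predicted_gu
                if abs(err) <= ppm_tol and abs(delta) <= gu_window:
                    entries.append(
                        ((abs(err), abs(delta), len(c.sequence), c.sequence, z),
                         ci, z)
                    )
        entries.sort(key=lambda e: e[0])
        if entries:
            per_feature[fi] = entries if all_matches else entries[:1]
    out = set()
    for fi, entries in per_feature.items():
        for _, ci, z in entries:
            out.add((ci, z, fi))
    return out


class TestMatchWindows:
    def test_in_window_match_reports_errors(self):
        cand = _cand("PEPTIDEK", 1000.0 - 1.007276, 7.85)
        feature = _feature_at(7.84, 1000.05)
        (result,) = match([cand], [feature], CURVE)
        assert result.ppm_error == pytest.approx(50.0, abs=0.01)
        assert result.delta_gu == pytest.approx(-0.01, abs=1e-6)
        assert result.charge == 1

    def test_feature_beyond_ppm_tolerance_unmatched(self):
        cand = _cand("PEPTIDEK", 1000.0 - 1.007276, 7.85)
        feature = _feature_at(7.85, 1000.0 * (1 + 150e-6))
        assert match([cand], [feature], CURVE) == []

    def test_feature_beyond_gu_window_unmatched(self):
        cand = _cand("PEPTIDEK", 1000.0 - 1.007276, 7.85)
        feature = _feature_at(7.85 + 0.6, 1000.0)
        assert match([cand], [feature], CURVE) == []

    def test_empty_inputs(self):
        assert match([], [_feature_at(5.0, 500.0)], CURVE) == []
        assert match([_cand("AK", 200.0, 5.0)], [], CURVE) == []

    def test_charge_annotation_restricts_charges(self):
        mass = 1000.0
        cand = _cand("PEPTIDEK", mass, 5.0)
        f2 = _feature_at(5.0, compute_mz(mass, 2), charge=2)
        (res,) = match([cand], [f2], CURVE)
        assert res.charge == 2
        f_wrong = _feature_at(5.0, compute_mz(mass, 2), charge=3)
        assert match([cand], [f_wrong], CURVE) == []


class TestTieBreaks:
    def test_candidate_tie_broken_by_delta_gu(self):
        mass = 1200.0
        a = _cand("AAAAAAK", mass, 6.00)
        b = _cand("CCCCCCK", mass, 6.20)
        feature = _feature_at(6.18, compute_mz(mass, 1))
        (res,) = match([a, b], [feature], CURVE)
        assert res.candidate.sequence == "CCCCCCK"

    def test_then_by_length_then_sequence(self):
        mass = 900.0
        long_c = _cand("AAAAAAAAK", mass, 5.0)
        short_c = _cand("WWK", mass, 5.0)
        feature = _feature_at(5.0, compute_mz(mass, 1))
        (res,) = match([long_c, short_c], [feature], CURVE)
        assert res.candidate.sequence == "WWK"
        lex_a = _cand("AAK", mass, 5.0)
        lex_b = _cand("CCK", mass, 5.0)
        (res,) = match([lex_b, lex_a], [feature], CURVE)
        assert res.candidate.sequence == "AAK"

    def test_all_matches_emits_every_pair(self):
        mass = 900.0
        a = _cand("AAK", mass, 5.0)
        b = _cand("CCK", mass, 5.0)
        feature = _feature_at(5.0, compute_mz(mass, 1))
        assert len(match([a, b], [feature], CURVE, all_matches=True)) == 2


class TestOracleEquivalence:
    def _random_instance(self, rng, n_cand=50, n_feat=200):
        candidates = []
        for i in range(n_cand):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     size=rng.integers(3, 15)))
            mass = float(rng.uniform(400, 3000))
            gu = float(rng.uniform(2.5, 12.0))
            candidates.append(_cand(seq, mass, gu))
        features = []
        for _ in range(n_feat):
            base = candidates[rng.integers(n_cand)]
            z = int(rng.integers(1, 4))
            jitter = 1 + rng.normal(0, 40) * 1e-6
            gu = base.predicted_gu + rng.normal(0, 0.3)
            gu = max(gu, 1.1)
            features.append(
                _feature_at(gu, compute_mz(base.monoisotopic_mass, z) * jitter,
                            charge=int(z) if rng.uniform() < 0.3 else None)
            )
        return candidates, features

    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("all_matches", [False, True])
    def test_identical_to_all_pairs_oracle(self, seed, all_matches):
        rng = np.random.default_rng(seed)
        candidates, features = self._random_instance(rng)
        results = match(candidates, features, CURVE, 100.0, 0.5, (1, 2, 3, 4),
                        all_matches=all_matches)
        got = {
            (candidates.index(r.candidate), r.charge, features.index(r.observed))
            for r in results
        }
        expected = brute_force_match(candidates, features, CURVE, 100.0, 0.5,
                                     (1, 2, 3, 4), all_matches)
        assert got == expected

    def test_shrinking_tolerances_never_adds_matches(self):
        rng = np.random.default_rng(7)
        candidates, features = self._random_instance(rng)

        def keys(ppm, window):
            return {
                (r.candidate.sequence, r.charge, r.observed.mz)
                for r in match(candidates, features, CURVE, ppm, window,
                               (1, 2, 3, 4), all_matches=True)
            }

        wide = keys(100.0, 0.5)
        assert keys(50.0, 0.5) <= wide
        assert keys(100.0, 0.25) <= wide
        assert keys(30.0, 0.1) <= keys(60.0, 0.2) <= wide


class TestScreen:
    def _setup(self, seed=11, **kw):
        config = SimulationConfig(seed=seed, n_proteins=2,
                                  protein_length_range=(60, 100), **kw)
        proteins = simulate_proteins(config)
        curve = fit_calibration(simulate_ladder(config))
        table = simulate_coefficient_table(config)
        features, truth = simulate_features(proteins, config)
        return config, proteins, curve, table, features, truth

    def test_planted_glycoform_recovered_with_correct_site(self):
        _, proteins, curve, table, features, truth = self._setup()
        planted = [t for t in truth if t.site != "-"]
        assert planted, "simulation must plant at least one glycoform"
        matched = []
        for protein in proteins:
            report = screen_glycated(protein, TRYPSIN, table, features, curve)
            matched.extend(report.glycated_matches)
        matched_keys = {(round(m.observed.mz, 4), m.peptide_sequence)
                        for m in matched}
        for t in planted:
            assert (round(t.mz, 4), t.sequence) in matched_keys
        # unambiguous planted lysine sites carry the right verdict
        by_key = {(round(m.observed.mz, 4), m.peptide_sequence): m for m in matched}
        for t in planted:
            m = by_key[(round(t.mz, 4), t.sequence)]
            if m.site_assignment.verdict == "lysine":
                assert t.site.startswith("K")

    def test_partner_undetected_flag(self):
        _, proteins, curve, table, features, truth = self._setup()
        # drop every unmodified feature: glycated matches must still appear,
        # flagged as lacking their unmodified partner
        glyc_mzs = {round(t.mz, 4) for t in truth if t.site != "-"}
        only_glycated = [f for f in features if round(f.mz, 4) in glyc_mzs]
        flagged = []
        for protein in proteins:
            report = screen_glycated(protein, TRYPSIN, table, only_glycated, curve)
            flagged.extend(report.glycated_matches)
        assert flagged
        assert all(m.note == "unmodified partner undetected" for m in flagged)

    def test_empty_feature_table_reports_all_candidates_unmatched(self):
        _, proteins, curve, table, _, _ = self._setup()
        report = screen_glycated(proteins[0], TRYPSIN, table, [], curve)
        assert report.matches == ()
        assert len(report.unmatched_glycated) > 0
        assert report.n_candidates > len(report.unmatched_glycated)
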