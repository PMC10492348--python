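"""Matching engine: coverage, cosine, isomer discrimination, run identification."""

import dataclasses

import numpy as np
import pytest

from qmarker import (
    MatchParams,
    SampleFeature,
    SimParams,
    cosine_similarity,
    diagnostic_coverage,
    identify_run,
    match_feature,
    read_features,
    simulate_feature,
    simulate_run,
    write_features,
)


def _feature_from(record, rt=None, extra=(), drop=(), feature_id="F"):
    """A noise-free feature carrying the record's printed fragments."""
    peaks = [(mz, 1e5) for mz in record.fragments if mz not in drop]
    peaks += [(mz, 1e5) for mz in extra]
    return SampleFeature(
        feature_id=feature_id,
        rt_min=record.rt_min if rt is None else rt,
        precursor_mz=record.theoretical_mz,
        polarity=record.ion.polarity,
        peaks=peaks,
    )


class TestDiagnosticCoverage:
    def test_all_diagnostics_present(self, library):
        daidzein = library["daidzein"]
        feat = _feature_from(daidzein)
        assert diagnostic_coverage(feat, daidzein, 0.005) == 1.0

    def test_empty_peak_list(self, library):
        feat = SampleFeature("F", 10.49, 253.0501, "negative", [])
        assert diagnostic_coverage(feat, library["daidzein"], 0.005) == 0.0

    def test_partial_coverage_counted_exactly(self, library):
        daidzein = library["daidzein"]
        feat = SampleFeature(
            "F", 10.49, 253.0501, "negative",
            [(253.0505, 1e5), (223.0395, 1e5)],  # 2 of 4 diagnostics
        )
        assert diagnostic_coverage(feat, daidzein, 0.005) == 0.5

    def test_one_peak_cannot_satisfy_two_fragments(self, library):
        hesperetin = library["hesperetin"]  # diagnostics 301.0715/164.0104/108.0206
        feat = SampleFeature("F", 11.08, 301.0712, "negative", [(301.0715, 1e5)])
        assert diagnostic_coverage(feat, hesperetin, 0.005) == pytest.approx(1 / 3)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        s = [(100.0, 4.0), (200.0, 9.0), (300.0, 1.0)]
        assert cosine_similarity(s, s, 0.005) == pytest.approx(1.0)

    def test_empty_side_is_zero(self):
        s = [(100.0, 4.0)]
        assert cosine_similarity(s, [], 0.005) == 0.0
        assert cosine_similarity([], s, 0.005) == 0.0

    def test_disjoint_lists_are_zero(self):
        a = [(100.0, 1.0), (200.0, 1.0)]
        b = [(150.0, 1.0), (250.0, 1.0)]
        assert cosine_similarity(a, b, 0.005) == 0.0

    def test_partial_overlap_between_zero_and_one(self):
        a = [(100.0, 1.0), (200.0, 1.0)]
        b = [(100.0, 1.0), (300.0, 1.0)]
        assert cosine_similarity(a, b, 0.005) == pytest.approx(0.5)


class TestMatchFeature:
    def test_vitexin_beats_isovitexin(self, library):
        vitexin = library["vitexin"]
        feat = _feature_from(vitexin, feature_id="F_vit")
        results = {m.candidate_id: m for m in match_feature(feat, library)}
        assert results["vitexin"].accepted and results["vitexin"].rank == 1
        # the co-formulaic isomer elutes 0.26 min later: rejected on RT
        assert not results["isovitexin"].accepted
        assert results["isovitexin"].rt_delta_min > 0.2

    def test_glycyrrhetinic_acid_rt_is_decisive(self, library):
        std = library["glycyrrhetinic_acid_18b"]
        feat = _feature_from(std, rt=14.54, feature_id="F_18b")
        results = match_feature(feat, library)
        assert results[0].candidate_id == "glycyrrhetinic_acid_18b"
        assert results[0].accepted
        # the 18alpha epimer is not in the library: no other candidate shares
        # the precursor window
        assert len(results) == 1

    def test_far_precursor_yields_nothing(self, library):
        feat = SampleFeature("F", 10.0, 258.05, "negative", [(100.0, 1.0)])
        assert match_feature(feat, library) == []

    def test_accepted_implies_all_gates(self, library):
        run = simulate_run(library, SimParams(seed=5))
        params = MatchParams()
        for feat in run.features:
            for m in match_feature(feat, library, params):
                if m.accepted:
                    assert m.ppm_err <= params.precursor_tol_ppm
                    assert m.rt_delta_min <= params.rt_tol_min
                    assert m.diagnostic_coverage >= params.min_diagnostic_coverage
                    assert m.cosine >= params.min_cosine


class TestIdentifyRun:
    def test_caffeine_only_run(self, library):
        feat = _feature_from(library["caffeine"], feature_id="F_caf")
        result = identify_run([feat], library)
        assert result.identified_ids == ["caffeine"]
        assert result.unidentified == []

    def test_empty_run(self, library):
        result = identify_run([], library)
        assert len(result) == 0 and result.unidentified == []

    def test_full_synthetic_run_recovers_every_compound(self, library):
        run = simulate_run(library, SimParams(seed=1))
        result = identify_run(run.features, library)
        assert sorted(result.identified_ids) == sorted(r.id for r in library)
        for m in result.assignments:
            assert m.feature_id == f"F_{m.candidate_id}"

    def test_determinism(self, library):
        run = simulate_run(library, SimParams(seed=2))
        r1 = identify_run(run.features, library)
        r2 = identify_run(run.features, library)
        assert [dataclasses.asdict(m) for m in r1.assignments] == [
            dataclasses.asdict(m) for m in r2.assignments
        ]

    def test_decoy_shift_rejected(self, library):
        """Precursors offset +0.05 Da from every record are never accepted."""
        run = simulate_run(library, SimParams(seed=3, decoy_features_per_run=0))
        shifted = [
            dataclasses.replace(f, precursor_mz=f.precursor_mz + 0.05)
            for f in run.features
        ]
        result = identify_run(shifted, library)
        assert len(result) == 0

    def test_tolerance_monotonicity(self, library):
        """Enlarging any tolerance never decreases the accepted-match count."""
        run = simulate_run(library, SimParams(seed=4))
        base = MatchParams()

        def n_accepted(params):
            return sum(
                m.accepted
                for f in run.features
                for m in match_feature(f, library, params)
            )

        n0 = n_accepted(base)
        for wider in (
            dataclasses.replace(base, precursor_tol_ppm=20.0),
            dataclasses.replace(base, fragment_tol_da=0.02),
            dataclasses.replace(base, rt_tol_min=1.0),
            dataclasses.replace(base, min_diagnostic_coverage=0.3),
            dataclasses.replace(base, min_cosine=0.05),
        ):
            assert n_accepted(wider) >= n0


ISOMER_PAIRS = [
    ("vitexin", "isovitexin"),
    ("daidzein", "dihydroxyflavone_74"),
    ("naringenin", "naringenin_chalcone"),
]


class TestIsomerDiscrimination:
    @pytest.mark.parametrize("pair", ISOMER_PAIRS, ids=lambda p: f"{p[0]}-{p[1]}")
    def test_never_assigned_to_the_other(self, library, pair):
        """Simulated features from either isomer always land on their own record."""
        params = SimParams()
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            feats = []
            for rec in library:
                f = simulate_feature(rec, params, rng)
                if rec.id in pair:
                    feats.append(f)
            result = identify_run(feats, library)
            for m in result.assignments:
                assert m.feature_id == f"F_{m.candidate_id}"


class TestFeatureIO:
    def test_csv_mgf_round_trip(self, library, tmp_path):
        run = simulate_run(library, SimParams(seed=7, decoy_features_per_run=2))
        csv_path, mgf_path = tmp_path / "f.csv", tmp_path / "f.mgf"
        write_features(run.features, csv_path, mgf_path)
        reloaded = read_features(csv_path, mgf_path)
        assert len(reloaded) == len(run.features)
        for a, b in zip(run.features, reloaded):
            assert a.feature_id == b.feature_id
            assert a.polarity == b.polarity
            assert a.rt_min == pytest.approx(b.rt_min, abs=1e-4)
            assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-5)
            assert len(a.peaks) == len(b.peaks)
        # identification is unchanged through the round trip
        direct = identify_run(run.features, library)
        via_disk = identify_run(reloaded, library)
        assert direct.identified_ids == via_disk.identified_ids
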