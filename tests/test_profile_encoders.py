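import numpy as np
import pytest

from ecmforest.io_formats import (
    DisorderTrack,
    DomainAnnotation,
    PSSMProfile,
    ProteinRecord,
    SecondaryStructureTrack,
)
from ecmforest.profile_encoders import (
    AuxiliaryProfiles,
    DomainVocabulary,
    EncoderConfig,
    PSSMFeatureParams,
    build_domain_vocabulary,
    disorder_features,
    encode_all,
    encode_dataset,
    fdi_vector,
    pssm_features,
    ss_features,
)
from ecmforest.synth import PLANTED_DOMAINS, SynthConfig, generate_records

from _oracles import pssm_theta_oracle, segment_stats_oracle


def _profile(scores, residues=None):
    scores = np.asarray(scores, dtype=float)
    residues = residues or "A" * scores.shape[0]
    return PSSMProfile("p", residues, scores, aa_order="ACDEFGHIKLMNPQRSTVWY")


class TestPssmFeatures:
    def test_identical_rows_give_zero(self):
        prof = _profile(np.tile(np.arange(20), (6, 1)))
        assert np.allclose(pssm_features(prof), 0.0)

    def test_sigmoid_at_zero(self):
        # rows alternate 0 and large: sigmoid(0) = 0.5 enters the differences
        row0 = np.zeros(20)
        row1 = np.full(20, 100.0)  # sigmoid ~ 1
        prof = _profile(np.array([row0, row1] * 3))
        v = pssm_features(prof)
        # lag-1 squared difference is (0.5 - 1)^2 = 0.25 for every column
        assert np.allclose(v[:20], 0.25, atol=1e-10)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 3, size=(9, 20))
        prof = _profile(scores, residues="ACDEFGHIK")
        assert np.allclose(pssm_features(prof), pssm_theta_oracle(scores))

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            pssm_features(_profile(np.zeros((4, 20))), PSSMFeatureParams(lag_max=4))

    def test_column_reordering(self):
        # permuting file columns while permuting aa_order leaves features fixed
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(8, 20))
        base = PSSMProfile("p", "A" * 8, scores, aa_order="ACDEFGHIKLMNPQRSTVWY")
        perm = np.array(list("ARNDCQEGHILKMFPSTWYV"))
        idx = ["ACDEFGHIKLMNPQRSTVWY".index(a) for a in perm]
        shuffled = PSSMProfile("p", "A" * 8, scores[:, idx], aa_order="".join(perm))
        assert np.allclose(pssm_features(base), pssm_features(shuffled))


class TestDisorderFeatures:
    def test_all_disordered(self):
        track = DisorderTrack("t", np.full(30, 0.9))
        v = disorder_features(track)
        assert v[0] == pytest.approx(0.9)
        assert v[1] == pytest.approx(0.0)
        assert list(v[2:]) == [1, 0, 30, 30, 0, 0]

    def test_all_ordered(self):
        v = disorder_features(DisorderTrack("t", np.full(10, 0.1)))
        assert list(v[2:4]) == [0, 1]

    def test_hand_runs(self):
        v = disorder_features(DisorderTrack("t", np.array([0.9, 0.9, 0.1, 0.9])))
        # disorder segments: [2, 1]; order segments: [1]
        assert list(v[2:]) == [2, 1, 1, 2, 1, 1]

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            scores = rng.random(int(rng.integers(1, 60)))
            v = disorder_features(DisorderTrack("t", scores))
            binary = "".join("1" if s >= 0.5 else "0" for s in scores)
            o = segment_stats_oracle(binary)
            assert list(v[2:]) == [
                o["n_ones"], o["n_zeros"],
                o["min_ones"], o["max_ones"], o["min_zeros"], o["max_zeros"],
            ]

    def test_threshold_is_inclusive(self):
        v = disorder_features(DisorderTrack("t", np.array([0.5, 0.5])))
        assert v[2] == 1 and v[3] == 0


class TestSSFeatures:
    def test_all_coil(self):
        seq = "ACDEFGHIK"
        v = ss_features(SecondaryStructureTrack("t", "C" * 9), seq)
        assert v.shape == (51,)
        assert np.allclose(v[:3], [0, 0, 1])  # H, E, C fractions
        assert np.allclose(v[3:6], [0, 0, 1])  # segment shares

    def test_three_equal_segments(self):
        seq = "ACDEFGHIK"
        v = ss_features(SecondaryStructureTrack("t", "HHHEEECCC"), seq)
        assert np.allclose(v[:3], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(v[3:6], [1 / 3, 1 / 3, 1 / 3])
        # each state: one segment of length 3 -> min=max=mean=3, sd=0
        for s in range(3):
            assert np.allclose(v[9 + 4 * s : 13 + 4 * s], [3, 3, 3, 0])

    def test_joint_block_sums_to_one(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
        states = "".join(rng.choice(list("HEC"), size=40))
        v = ss_features(SecondaryStructureTrack("t", states), seq)
        assert v[21:51].sum() == pytest.approx(1.0)

    def test_segment_lengths_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n = int(rng.integers(3, 50))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
            states = "".join(rng.choice(list("HEC"), size=n))
            v = ss_features(SecondaryStructureTrack("t", states), seq)
            # check helix block against a run-length oracle on the H-mask
            binary = "".join("1" if s == "H" else "0" for s in states)
            o = segment_stats_oracle(binary)
            assert v[9] == o["min_ones"] and v[10] == o["max_ones"]

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            ss_features(SecondaryStructureTrack("t", "HEC"), "ACDE")


class TestDomainVocabulary:
    def test_count_threshold(self):
        ann = DomainAnnotation(
            {"p1": frozenset({"D1"}), "p2": frozenset({"D1", "D2"}), "p3": frozenset({"D1"})}
        )
        vocab = build_domain_vocabulary(ann, ["p1", "p2", "p3"], min_count=2)
        assert vocab.accessions == ("D1",)

    def test_unreachable_threshold_gives_empty(self):
        ann = DomainAnnotation({"p1": frozenset({"D1"})})
        vocab = build_domain_vocabulary(ann, ["p1"], min_count=25)
        assert len(vocab) == 0

    def test_ties_broken_by_accession(self):
        ann = DomainAnnotation(
            {"p1": frozenset({"B", "A"}), "p2": frozenset({"B", "A"})}
        )
        vocab = build_domain_vocabulary(ann, ["p1", "p2"], min_count=2)
        assert vocab.accessions == ("A", "B")

    def test_fdi_vector_cases(self):
        vocab = DomainVocabulary(("D1", "D2", "D3"))
        ann = DomainAnnotation({"p": frozenset({"D1"}), "q": frozenset({"D1", "D2", "D3", "X"})})
        assert list(fdi_vector("p", ann, vocab)) == [1, 0, 0]
        assert list(fdi_vector("q", ann, vocab)) == [1, 1, 1]
        assert list(fdi_vector("unknown", ann, vocab)) == [0, 0, 0]


class TestEncodeAll:
    def test_block_sizes_sum(self, full_config, small_dataset):
        records, profiles, _ = small_dataset
        names, vec = encode_all(records[0], profiles[records[0].id], full_config)
        assert len(names) == len(vec) == 315

    def test_sequence_only_blocks(self, small_dataset):
        records, profiles, _ = small_dataset
        config = EncoderConfig(blocks=("ffg", "entropy", "distribution", "transition"))
        names, vec = encode_all(records[0], profiles[records[0].id], config)
        assert len(vec) == 77

    def test_physicochemical_blocks(self, small_dataset):
        records, profiles, _ = small_dataset
        config = EncoderConfig(blocks=("pseaac", "dwt"))
        names, vec = encode_all(records[0], profiles[records[0].id], config)
        assert len(vec) == 82

    def test_missing_track_names_block(self, small_dataset):
        records, _, _ = small_dataset
        with pytest.raises(ValueError, match="pssm"):
            encode_all(records[0], AuxiliaryProfiles(), EncoderConfig(blocks=("pssm",)))

    def test_row_permutation_permutes_rows_only(self, small_dataset, full_config):
        records, profiles, labels = small_dataset
        m1 = encode_dataset(records, profiles, full_config, labels=labels)
        m2 = encode_dataset(records[::-1], profiles, full_config, labels=labels)
        assert m1.feature_names == m2.feature_names
        assert m1.ids == m2.ids[::-1]
        assert np.allclose(m1.values, m2.values[::-1])

    def test_column_order_stable_across_runs(self, small_dataset, full_config):
        records, profiles, labels = small_dataset
        m1 = encode_dataset(records, profiles, full_config, labels=labels)
        m2 = encode_dataset(records, profiles, full_config, labels=labels)
        assert m1.feature_names == m2.feature_names
        assert np.array_equal(m1.values, m2.values)
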