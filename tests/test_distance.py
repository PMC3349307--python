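import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import spearmanr

from dinuprof.distance import (
    DistanceMatrix,
    city_block,
    common_depth,
    cosine_distance,
    pairwise_matrix,
)
from dinuprof.profile import FrequencyMatrix, flatten, frequency_matrix
from dinuprof.sequence_io import DnaSequence, SequenceSet

from conftest import random_dna


def freq_matrix_strategy(d0=3):
    """Random valid frequency matrices: non-negative rows summing to 1."""
    raw = hnp.arrays(
        np.float64,
        (d0, 16),
        elements=st.floats(0.001, 1.0, allow_nan=False),
    )
    return raw.map(
        lambda a: FrequencyMatrix(
            label="r", values=a / a.sum(axis=1, keepdims=True), d0=d0
        )
    )


class TestCommonDepth:
    def test_builtin_depth(self, beta_globin):
        assert common_depth(beta_globin) == 21

    def test_small_cases(self):
        one = SequenceSet((DnaSequence(id="a", residues="ACGT"),))
        assert common_depth(one) == 1
        mixed = SequenceSet(
            tuple(
                DnaSequence(id=f"s{n}", residues="ACGT" * (n // 4) + "A" * (n % 4))
                for n in (100, 40, 83)
            )
        )
        assert common_depth(mixed) == 10


class TestCityBlock:
    def test_self_distance_zero(self, beta_globin):
        fm = frequency_matrix(beta_globin["Human"], 21)
        assert city_block(fm, fm) == 0.0

    def test_shape_mismatch(self, beta_globin):
        fa = frequency_matrix(beta_globin["Human"], 21)
        fb = frequency_matrix(beta_globin["Human"], 20)
        with pytest.raises(ValueError, match="shape"):
            city_block(fa, fb)

    @given(fa=freq_matrix_strategy(2), fb=freq_matrix_strategy(2))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_double_loop_oracle(self, fa, fb):
        expected = sum(
            abs(fa.values[i, j] - fb.values[i, j])
            for i in range(2)
            for j in range(16)
        )
        assert city_block(fa, fb) == pytest.approx(expected, abs=1e-12)

    @given(
        fa=freq_matrix_strategy(),
        fb=freq_matrix_strategy(),
        fc=freq_matrix_strategy(),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_metric_axioms(self, fa, fb, fc):
        dab = city_block(fa, fb)
        dba = city_block(fb, fa)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-12)
        assert city_block(fa, fa) == 0.0
        dac = city_block(fa, fc)
        dcb = city_block(fc, fb)
        assert dab <= dac + dcb + 1e-9


class TestCosineDistance:
    def test_scale_invariance(self, rng):
        v = rng.random(32)
        assert cosine_distance(v, 3.7 * v) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_unit_vectors(self):
        e1 = np.zeros(8)
        e2 = np.zeros(8)
        e1[0] = 1.0
        e2[3] = 1.0
        assert cosine_distance(e1, e2) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            cosine_distance(np.ones(4), np.ones(5))
        with pytest.raises(ValueError, match="zero"):
            cosine_distance(np.zeros(4), np.ones(4))

    @given(
        va=hnp.arrays(np.float64, 32,
                      elements=st.one_of(st.just(0.0), st.floats(1e-3, 1.0))),
        vb=hnp.arrays(np.float64, 32,
                      elements=st.one_of(st.just(0.0), st.floats(1e-3, 1.0))),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounded_and_symmetric_on_nonnegative(self, va, vb):
        if va.sum() == 0 or vb.sum() == 0:
            return
        d = cosine_distance(va, vb)
        assert -1e-12 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(cosine_distance(vb, va), abs=1e-12)


@pytest.fixture(scope="module")
def dms(beta_globin):
    return {m: pairwise_matrix(beta_globin, m) for m in ("d1", "d2")}


class TestPairwiseMatrix:
    def test_symmetry_zero_diagonal(self, dms):
        for dm in dms.values():
            np.testing.assert_array_equal(dm.values, dm.values.T)
            np.testing.assert_array_equal(np.diag(dm.values), 0.0)
            assert np.all(dm.values >= 0)

    def test_labels_follow_input_order(self, dms, beta_globin):
        assert dms["d1"].labels == beta_globin.labels

    def test_d2_entries_within_unit_interval(self, dms):
        assert np.all(dms["d2"].values <= 1.0)

    @pytest.mark.parametrize(
        "metric,pair,expected",
        [
            ("d1", ("Human", "Chimpanzee"), 2.5567),
            ("d1", ("Goat", "Bovine"), 2.3438),
            ("d1", ("Lemur", "Gallus"), 9.0347),
            ("d2", ("Human", "Chimpanzee"), 0.0087),
            ("d2", ("Goat", "Bovine"), 0.0109),
            ("d2", ("Lemur", "Gallus"), 0.1139),
        ],
    )
    def test_published_benchmark_cells(self, dms, metric, pair, expected):
        assert dms[metric][pair] == pytest.approx(expected, abs=5e-5)

    def test_farthest_pair_is_lemur_gallus(self, dms):
        """Gallus (the only non-mammal) against Lemur gives the largest
        distance on both measures."""
        for dm in dms.values():
            iu = np.triu_indices(len(dm.labels), k=1)
            k = np.argmax(dm.values[iu])
            assert {dm.labels[iu[0][k]], dm.labels[iu[1][k]]} == {"Lemur", "Gallus"}

    def test_primates_and_bovids_are_closest(self, dms):
        """Human-Gorilla and Goat-Bovine rank among the closest pairs on
        both measures, far below the median pairwise distance."""
        for dm in dms.values():
            iu = np.triu_indices(len(dm.labels), k=1)
            med = np.median(dm.values[iu])
            for pair in (("Human", "Gorilla"), ("Goat", "Bovine"),
                         ("Human", "Chimpanzee")):
                assert dm[pair] < med

    def test_measures_rank_agree(self, dms):
        iu = np.triu_indices(11, k=1)
        rho = spearmanr(dms["d1"].values[iu], dms["d2"].values[iu]).statistic
        assert rho > 0.9

    def test_unequal_lengths_share_depth_without_truncation(self, rng):
        """The longer sequence's surplus residues still feed pairs at d <= d0."""
        a = random_dna(rng, 60, "a")
        b = random_dna(rng, 100, "b")
        pair = SequenceSet((a, b))
        d0 = common_depth(pair)
        assert d0 == 15
        fb = frequency_matrix(b, d0)
        fb_trunc = frequency_matrix(
            DnaSequence(id="bt", residues=b.residues[:60]), d0
        )
        assert not np.allclose(fb.values, fb_trunc.values)

    def test_bad_metric_rejected(self, beta_globin):
        with pytest.raises(ValueError, match="metric"):
            pairwise_matrix(beta_globin, "euclidean")


class TestDistanceMatrixIO:
    @pytest.fixture()
    def dm(self):
        values = np.array([[0.0, 1.25], [1.25, 0.0]])
        return DistanceMatrix(
            labels=("a", "b"), values=values, metric_name="d1", d0=2
        )

    def test_tsv_full_and_upper(self, dm, tmp_path):
        p = tmp_path / "m.tsv"
        dm.write(p, fmt="tsv", precision=2)
        lines = p.read_text().splitlines()
        assert lines[0] == "Species\ta\tb"
        assert lines[1] == "a\t0.00\t1.25"
        dm.write(p, fmt="tsv", precision=2, upper=True)
        assert p.read_text().splitlines()[2] == "b\t\t0.00"

    def test_phylip_square(self, dm, tmp_path):
        p = tmp_path / "m.phy"
        dm.write(p, fmt="phylip")
        lines = p.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[1].split() == ["a", "0.0000", "1.2500"]
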