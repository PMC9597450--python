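"""Karyotype descriptors, asymmetry indices, Stebbins classes, ideograms."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sesamediv.errors import DegenerateChromosomeError, UndefinedCVError
from sesamediv.karyotype import (
    ChromosomeMeasurement,
    ClassThresholds,
    KaryotypeSet,
    NM,
    NSM,
    NST,
    NT,
    chromosome_descriptors,
    classify_chromosome,
    ideogram_table,
    karyotype_formula,
    karyotype_summary,
    read_karyotypes,
    stebbins_category,
    write_karyotypes,
)


def _chrom(i, s, l):
    return ChromosomeMeasurement(index=i, short_arm=s, long_arm=l)


def _set(arms, genotype="T"):
    chroms = [_chrom(i + 1, s, l) for i, (s, l) in enumerate(arms)]
    return KaryotypeSet(genotype, chroms)


class TestDescriptors:
    def test_metacentric(self):
        d = chromosome_descriptors(_chrom(1, 5, 5))
        assert (d.arm_ratio, d.centromeric_index, d.m_value) == (1.0, 0.5, 0.0)

    def test_telocentric_infinite_ratio(self):
        d = chromosome_descriptors(_chrom(1, 0, 4))
        assert math.isinf(d.arm_ratio)
        assert d.centromeric_index == 0.0 and d.m_value == 1.0

    def test_exact_arithmetic(self):
        d = chromosome_descriptors(_chrom(1, 2, 6))
        assert (d.arm_ratio, d.centromeric_index, d.m_value) == (3.0, 0.25, 0.5)

    def test_arms_normalised_on_input(self):
        c = _chrom(1, 7, 3)  # swapped on construction
        assert c.short_arm == 3 and c.long_arm == 7

    def test_zero_length_rejected(self):
        with pytest.raises(DegenerateChromosomeError):
            _chrom(1, 0, 0)


@pytest.mark.parametrize(
    "ratio, expected",
    [(1.0, NM), (1.69, NM), (2.0, NSM), (2.99, NSM), (3.0, NST), (5.0, NST), (7.0, NT), (20.0, NT)],
)
def test_levan_band_classification(ratio, expected):
    assert classify_chromosome(_chrom(1, 1.0, ratio)) is not None
    assert classify_chromosome(_chrom(1, 1.0, ratio)) == expected


def test_classification_thresholds_configurable():
    c = _chrom(1, 1.0, 2.0)
    assert classify_chromosome(c, ClassThresholds(nm_max=2.5)) == NM


class TestFormula:
    def test_all_metacentric(self):
        ks = _set([(5, 5)] * 13)
        assert karyotype_formula(ks) == "26 nm"

    def test_published_class_mix(self):
        # 1 nsm(-), 6 nst, 6 nm haploid -> doubled diploid counts
        arms = [(1.0, 2.0)] + [(1.0, 4.0)] * 6 + [(1.0, 1.2)] * 6
        assert karyotype_formula(_set(arms)) == "2 nsm (−)+12 nst+12 nm"

    def test_counts_match_classification_tally(self, rng):
        arms = [(float(s), float(l)) for s, l in rng.uniform(0.5, 8, (13, 2))]
        ks = _set(arms)
        tally = {}
        for c in ks.chromosomes:
            tally[classify_chromosome(c)] = tally.get(classify_chromosome(c), 0) + 1
        total = sum(int(part.split()[0]) for part in karyotype_formula(ks).split("+"))
        assert total == 2 * 13 == 2 * sum(tally.values())


class TestSummary:
    def test_identical_metacentrics_fully_symmetric(self):
        s = karyotype_summary(_set([(4, 4)] * 13))
        assert s.tf_percent == pytest.approx(50.0)
        assert s.ask_percent == pytest.approx(50.0)
        assert s.s_percent == pytest.approx(100.0)
        assert s.a_watanabe == 0.0 and s.mca == 0.0
        assert s.cv_cl == 0.0 and s.cv_ci == 0.0
        assert s.a1 == pytest.approx(0.0) and s.a2 == 0.0

    def test_pooled_short_arm_fraction(self):
        """Arm split 0.415 per chromosome -> TF% 41.50, AsK% 58.50."""
        arms = [(0.415 * cl, 0.585 * cl) for cl in np.linspace(5, 12, 13)]
        s = karyotype_summary(_set(arms))
        assert s.tf_percent == pytest.approx(41.50)
        assert s.ask_percent == pytest.approx(58.50)

    def test_every_index_matches_independent_oracle(self, rng):
        """Formula-by-formula recomputation with raw numpy on a random set."""
        arms = np.sort(rng.uniform(0.5, 9, (13, 2)), axis=1)
        s = karyotype_summary(_set([tuple(a) for a in arms]))
        short, long_ = arms[:, 0], arms[:, 1]
        cl = short + long_
        ci = short / cl
        assert s.hcl == pytest.approx(cl.sum())
        assert s.tf_percent == pytest.approx(100 * short.sum() / cl.sum())
        assert s.ask_percent == pytest.approx(100 * long_.sum() / cl.sum())
        assert s.s_percent == pytest.approx(100 * cl.min() / cl.max())
        assert s.ci_mean == pytest.approx(ci.mean())
        assert s.a_watanabe == pytest.approx(((long_ - short) / cl).mean())
        assert s.mca == pytest.approx(100 * s.a_watanabe)
        assert s.cv_cl == pytest.approx(100 * cl.std(ddof=1) / cl.mean())
        assert s.cv_ci == pytest.approx(100 * ci.std(ddof=1) / ci.mean())
        assert s.a1 == pytest.approx(1 - (short / long_).mean())
        assert s.a2 == pytest.approx(s.cv_cl / 100)
        assert s.ai == pytest.approx(s.cv_cl * s.cv_ci / 100)

    def test_population_sd_option(self, rng):
        arms = np.sort(rng.uniform(1, 5, (8, 2)), axis=1)
        ks = _set([tuple(a) for a in arms])
        cl = arms.sum(axis=1)
        s = karyotype_summary(ks, sample_sd=False)
        assert s.cv_cl == pytest.approx(100 * cl.std(ddof=0) / cl.mean())

    def test_needs_two_chromosomes(self):
        with pytest.raises(UndefinedCVError):
            karyotype_summary(_set([(2, 3)]))


class TestStebbins:
    def test_most_symmetric_cell(self):
        arms = [(c / 2, c / 2) for c in np.linspace(5.0, 6.0, 13)]
        assert stebbins_category(_set(arms)) == "1A"

    def test_rule_application_2a_and_2b(self):
        # 4/13 chromosomes with arm ratio > 2 -> row 2; the largest/smallest
        # chromosome-length ratio R picks the column letter
        def build(r_target):
            arms = [(1.0, 2.5)] * 4 + [(2.0, 2.0)] * 8  # CLs 3.5 and 4.0
            longest = 3.5 * r_target
            arms.append((longest / 2, longest / 2))
            return _set(arms)

        assert stebbins_category(build(1.95)) == "2A"
        assert stebbins_category(build(2.5)) == "2B"

    def test_row_digit_boundaries(self):
        all_meta = _set([(2, 2)] * 4)
        assert stebbins_category(all_meta)[0] == "1"
        all_asym = _set([(1, 3)] * 4)
        assert stebbins_category(all_asym)[0] == "4"
        over_half = _set([(1, 3)] * 3 + [(2, 2)])
        assert stebbins_category(over_half)[0] == "3"

    def test_telocentric_counts_as_asymmetric(self):
        ks = _set([(0, 3), (2, 2)])
        assert stebbins_category(ks)[0] == "2"


class TestInvariances:
    @given(
        st.lists(
            st.tuples(
                st.floats(0.2, 10.0, allow_nan=False),
                st.floats(0.2, 10.0, allow_nan=False),
            ),
            min_size=3,
            max_size=15,
        ),
        st.floats(0.1, 40.0),
    )
    def test_scale_invariance(self, arms, k):
        s1 = karyotype_summary(_set(arms))
        s2 = karyotype_summary(_set([(s * k, l * k) for s, l in arms]))
        assert s2.hcl == pytest.approx(k * s1.hcl, rel=1e-9)
        for attr in ("tf_percent", "ask_percent", "s_percent", "ci_mean",
                     "a_watanabe", "mca", "cv_cl", "cv_ci", "a1", "a2"):
            assert getattr(s2, attr) == pytest.approx(getattr(s1, attr), rel=1e-7, abs=1e-10)
        assert s2.stebbins == s1.stebbins and s2.formula == s1.formula

    @given(
        st.lists(
            st.tuples(st.floats(0.2, 10.0), st.floats(0.2, 10.0)),
            min_size=3,
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, arms, rnd):
        s1 = karyotype_summary(_set(arms))
        shuffled = list(arms)
        rnd.shuffle(shuffled)
        s2 = karyotype_summary(_set(shuffled))
        for attr in ("hcl", "tf_percent", "a_watanabe", "cv_cl", "cv_ci", "a1", "a2"):
            assert getattr(s2, attr) == pytest.approx(getattr(s1, attr), rel=1e-9)
        assert s2.stebbins == s1.stebbins and s2.formula == s1.formula


class TestIdeogram:
    def test_single_chromosome_coordinates(self):
        ks = KaryotypeSet("T", [_chrom(1, 2, 3)])
        t = ideogram_table(ks)
        assert t.iloc[0]["centromere"] == 2 and t.iloc[0]["end"] == 5

    def test_by_length_sorts_descending(self):
        ks = _set([(2, 3), (3, 5)])
        t = ideogram_table(ks, order="by_length")
        assert list(t["end"]) == [8, 5]

    def test_offsets_are_prefix_sums(self, rng):
        arms = np.sort(rng.uniform(0.5, 6, (13, 2)), axis=1)
        ks = _set([tuple(a) for a in arms])
        t = ideogram_table(ks, order="by_index")
        for row, (s, l) in zip(t.itertuples(), arms):
            assert row.centromere == pytest.approx(s)
            assert row.end == pytest.approx(s + l)


def test_karyotype_file_round_trip(tmp_path, rng):
    arms = np.sort(rng.uniform(1, 6, (13, 2)), axis=1)
    ksets = [_set([tuple(a) for a in arms], genotype="G1")]
    ksets[0].diploid_number = 26
    path = tmp_path / "karyo.tsv"
    write_karyotypes(ksets, path)
    back = read_karyotypes(path)
    assert back[0].genotype == "G1" and back[0].n == 13
    s1 = karyotype_summary(ksets[0])
    s2 = karyotype_summary(back[0])
    assert s1.tf_percent == pytest.approx(s2.tf_percent)
    assert s1.formula == s2.formula
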