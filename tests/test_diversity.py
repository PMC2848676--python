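"""Hill numbers, Jost partitioning, evenness and Bray-Curtis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flumeflux.diversity import (OtuTable, TrflpProfile, bray_curtis, evenness,
                                 filter_core_taxa, hill_number, mean_pairwise_bc,
                                 partition_diversity, profile_to_abundances)


def random_communities(draw_seed, n, s):
    rng = np.random.default_rng(draw_seed)
    P = rng.dirichlet(np.full(s, 0.5), size=n)
    return P


class TestProfileFiltering:
    def test_size_window_excludes_primer_fragments(self):
        prof = TrflpProfile([25.0, 100.0], [500.0, 500.0])
        sizes, p = profile_to_abundances(prof)
        assert list(sizes) == [100.0] and p[0] == 1.0

    def test_single_peak_normalizes_to_one(self):
        sizes, p = profile_to_abundances(TrflpProfile([100.0], [42.0]))
        assert p[0] == 1.0

    def test_two_percent_noise_threshold(self):
        # 1.5 < 2% of max height 100 -> dropped; remaining renormalized
        prof = TrflpProfile([100.0, 200.0, 300.0], [100.0, 50.0, 1.5])
        _, p = profile_to_abundances(prof)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_all_filtered_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            profile_to_abundances(TrflpProfile([10.0, 950.0], [5.0, 5.0]))


class TestHillNumber:
    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0, 3.5])
    def test_uniform_gives_species_count(self, q):
        assert hill_number([0.5, 0.5], q) == pytest.approx(2.0)

    def test_single_species(self):
        assert hill_number([1.0], 1.0) == pytest.approx(1.0)

    def test_inverse_simpson_hand_value(self):
        # sum p^2 = 0.36+0.09+0.01 = 0.46
        assert hill_number([0.6, 0.3, 0.1], 2.0) == pytest.approx(1 / 0.46)

    def test_continuous_at_q_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            assert hill_number(p, 0.999) == pytest.approx(hill_number(p, 1.0), rel=1e-2)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            hill_number([-0.1, 1.1], 1.0)


class TestPartition:
    def test_identical_communities_have_beta_one(self):
        p = np.array([0.4, 0.35, 0.25])
        part = partition_diversity([p, p, p], q=1.0)
        assert part.beta == pytest.approx(1.0)

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0])
    def test_disjoint_uniform_communities_have_beta_n(self, q):
        tables = np.kron(np.eye(3), np.full((1, 4), 0.25))
        part = partition_diversity(tables, q=q)
        assert part.beta == pytest.approx(3.0)
        assert part.gamma == pytest.approx(12.0)

    def test_hand_computed_shannon_partition(self):
        # communities (1,0) and (.5,.5): pooled=(.75,.25), H=0.5623;
        # gamma=e^H=1.7548, alpha=exp((0+ln2)/2)=sqrt(2), beta=gamma/alpha
        part = partition_diversity([[1.0, 0.0], [0.5, 0.5]], q=1.0)
        assert part.gamma == pytest.approx(1.7548, abs=1e-4)
        assert part.alpha == pytest.approx(1.4142, abs=1e-4)
        assert part.beta == pytest.approx(1.2409, abs=1e-4)

    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0, 3.0])
    def test_multiplicative_identity_random_tables(self, q):
        for seed in range(20):
            P = random_communities(seed, n=4, s=12)
            part = partition_diversity(P, q=q)
            assert part.gamma == pytest.approx(part.alpha * part.beta, abs=1e-9)
            assert 1.0 - 1e-9 <= part.beta <= 4.0 + 1e-9

    def test_beta_invariant_to_otu_relabeling(self):
        P = random_communities(5, n=3, s=10)
        perm = np.random.default_rng(1).permutation(10)
        a = partition_diversity(P, q=1.0)
        b = partition_diversity(P[:, perm], q=1.0)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_duplicating_all_communities_preserves_gamma_and_beta(self):
        P = random_communities(9, n=3, s=8)
        a = partition_diversity(P, q=2.0)
        b = partition_diversity(np.vstack([P, P]), q=2.0)
        assert b.gamma == pytest.approx(a.gamma)
        assert b.beta == pytest.approx(a.beta)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 6), st.integers(2, 15),
       st.sampled_from([0.0, 1.0, 2.0]))
def test_partition_identity_property(seed, n, s, q):
    """gamma = alpha * beta to 1e-9 for arbitrary random community sets."""
    P = random_communities(seed, n, s)
    part = partition_diversity(P, q=q)
    assert abs(part.gamma - part.alpha * part.beta) < 1e-9


class TestEvenness:
    def test_uniform_is_perfectly_even(self):
        he, pi = evenness([0.25] * 4)
        assert he == pytest.approx(1.0) and pi == pytest.approx(1.0)

    def test_hand_computed_two_species(self):
        he, pi = evenness([0.75, 0.25])  # D1 = 1.7548
        assert he == pytest.approx(0.8774, abs=1e-4)
        assert pi == pytest.approx(0.8113, abs=1e-4)

    def test_single_species_is_an_error(self):
        with pytest.raises(ValueError):
            evenness([1.0])


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert bray_curtis([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_value_and_symmetry(self):
        assert bray_curtis([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.5)
        assert bray_curtis([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.5)

    def test_bounded_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x, y = rng.uniform(0, 1, (2, 6))
            assert 0.0 <= bray_curtis(x, y) <= 1.0

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])


class TestMeanPairwiseBC:
    def test_identical_samples_give_zero(self):
        p = np.array([0.3, 0.7])
        assert mean_pairwise_bc([p, p, p]) == 0.0

    def test_four_samples_average_six_pairs(self):
        # two identical pairs with full turnover between them:
        # 4 of 6 pairs at 1, 2 at 0 -> mean 2/3
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert mean_pairwise_bc([a, a, b, b]) == pytest.approx(4 / 6)


class TestCoreTaxa:
    def _table(self):
        idx = pd.MultiIndex.from_tuples(
            [(f, h, 0) for f in (0, 1) for h in ("crest", "trough")],
            names=["flume", "microhabitat", "date"])
        # otu_a everywhere; otu_b only in flume 0's crest; otu_c widespread
        df = pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.5, 0.0, 0.5],
             [0.5, 0.0, 0.5], [0.4, 0.0, 0.6]],
            index=idx, columns=["otu_a", "otu_b", "otu_c"])
        return OtuTable(df)

    def test_taxon_missing_from_one_flume_dropped(self):
        # otu_b absent from flume 1 entirely -> dropped under all_flumes
        core = filter_core_taxa(self._table(), "all_flumes")
        assert list(core.data.columns) == ["otu_a", "otu_c"]

    def test_rows_renormalized_by_retained_mass(self):
        core = filter_core_taxa(self._table(), "all_flumes")
        np.testing.assert_allclose(core.data.sum(axis=1), 1.0)
        # first row: (0.5, 0.0) over retained mass 0.5 -> (1.0, 0.0)
        np.testing.assert_allclose(core.data.iloc[0], [1.0, 0.0])

    def test_microhabitat_scope(self):
        core = filter_core_taxa(self._table(), "all_microhabitats")
        # otu_b never occurs in a trough sample -> dropped
        assert "otu_b" not in core.data.columns
        assert {"otu_a", "otu_c"} == set(core.data.columns)

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            filter_core_taxa(self._table(), "everywhere")
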