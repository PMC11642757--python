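"""Embryo geometry, lineage, spatial placement, biopsy and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from mosaicabc import (
    ErrorRates,
    ModelConfig,
    classify_biopsy,
    classify_counts,
    make_geometry,
    place_aneuploid,
    simulate_biopsy_proportions,
    simulate_lineage,
    simulate_lineages,
    take_biopsy,
)
from mosaicabc.embryo_model import Biopsy, simulate_biopsy_counts


class TestGeometry:
    def test_positions_unit_norm(self, geometry):
        assert np.allclose(np.linalg.norm(geometry.positions, axis=1), 1.0, atol=1e-9)

    def test_deterministic(self, geometry):
        again = make_geometry.__wrapped__(256)  # bypass the cache
        assert np.array_equal(geometry.positions, again.positions)
        assert np.array_equal(geometry.neighbor_order, again.neighbor_order)

    def test_neighbor_orders_are_permutations(self, geometry):
        for i in (0, 17, 255):
            row = geometry.neighbor_order[i]
            assert sorted(row) == sorted(set(range(256)) - {i})

    def test_near_uniform_packing(self, geometry):
        """Nearest-neighbor distances of the lattice vary little."""
        d = squareform(pdist(geometry.positions))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.25

    def test_invalid_cell_count(self):
        with pytest.raises(ValueError):
            make_geometry(0)


class TestLineage:
    def test_meiotic_certainty(self, rng):
        cfg = ModelConfig()
        out = simulate_lineage(ErrorRates(1.0, 0.3), cfg, rng)
        assert out.is_meiotic and out.n_aneuploid == 256
        assert np.all(simulate_lineages(ErrorRates(1.0, 0.0), cfg, 50, rng) == 256)

    def test_no_error_sources(self, rng):
        cfg = ModelConfig()
        assert simulate_lineage(ErrorRates(0.0, 0.0), cfg, rng).n_aneuploid == 0
        assert np.all(simulate_lineages(ErrorRates(0.0, 0.0), cfg, 50, rng) == 0)

    @pytest.mark.parametrize("convention", ["per_daughter", "per_division_both_daughters"])
    def test_mean_aneuploid_fraction_closed_form(self, rng, convention):
        """E[aneuploid fraction] = m + (1-m)(1 - (1-p)^R) under both
        conventions (they share the per-cell marginal)."""
        m, p, n = 0.0, 0.015, 100_000
        cfg = ModelConfig(mitotic_convention=convention)
        n_an = simulate_lineages(ErrorRates(m, p), cfg, n, rng)
        frac = n_an / 256
        expected = m + (1 - m) * (1 - (1 - p) ** 8)
        se = frac.std() / np.sqrt(n)
        assert abs(frac.mean() - expected) < 3 * se + 1e-12

    def test_fully_euploid_probability_closed_form(self, rng):
        """Under per-daughter errors P(no aneuploid cell) = (1-m)(1-p)^510
        (510 = sum of 2^k daughter draws over 8 rounds)."""
        p, n = 0.015, 1_000_000
        n_an = simulate_lineages(ErrorRates(0.0, p), ModelConfig(), n, rng)
        expected = (1 - p) ** 510
        observed = np.mean(n_an == 0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_fully_aneuploid_at_least_meiotic(self, rng):
        m = 0.3
        n_an = simulate_lineages(ErrorRates(m, 0.1), ModelConfig(), 50_000, rng)
        frac_full = np.mean(n_an == 256)
        assert frac_full >= m - 3 * np.sqrt(m * (1 - m) / 50_000)

    @pytest.mark.parametrize("convention", ["per_daughter", "per_division_both_daughters"])
    def test_matches_explicit_tree_simulation(self, convention):
        """The binomial-recursion lineage simulator and an explicit per-cell
        binary-tree simulation give indistinguishable aneuploid-count
        distributions at 4 division rounds (chi-square, alpha=0.001)."""

        def tree_sim(mitotic, n_rounds, rng):
            cells = np.zeros(1, dtype=bool)  # True = aneuploid
            for _ in range(n_rounds):
                parents = np.repeat(cells, 2)
                if convention == "per_daughter":
                    err = rng.random(parents.size) < mitotic
                else:
                    err = np.repeat(rng.random(cells.size) < mitotic, 2)
                cells = parents | err
            return int(cells.sum())

        p, reps = 0.08, 20_000
        cfg = ModelConfig(n_rounds=4, n_cells=16, mitotic_convention=convention)
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(8)
        fast = simulate_lineages(ErrorRates(0.0, p), cfg, reps, rng1)
        slow = np.array([tree_sim(p, 4, rng2) for _ in range(reps)])
        bins = np.arange(18)
        c_fast = np.histogram(fast, bins=bins)[0]
        c_slow = np.histogram(slow, bins=bins)[0]
        keep = (c_fast + c_slow) >= 10  # pool sparse cells
        table = np.vstack([
            np.append(c_fast[keep], c_fast[~keep].sum()),
            np.append(c_slow[keep], c_slow[~keep].sum()),
        ])
        table = table[:, table.sum(axis=0) > 0]
        _, pval, _, _ = sps.chi2_contingency(table)
        assert pval > 0.001


class TestPlacement:
    def test_degenerate_counts(self, geometry, rng):
        assert not place_aneuploid(geometry, 0, 0.5, rng).ploidy.any()
        assert place_aneuploid(geometry, 256, 0.5, rng).ploidy.all()

    def test_out_of_range(self, geometry, rng):
        with pytest.raises(ValueError):
            place_aneuploid(geometry, 257, 0.5, rng)
        with pytest.raises(ValueError):
            place_aneuploid(geometry, -1, 0.5, rng)

    def test_zero_dispersal_single_patch(self, geometry, rng):
        """At dispersal 0 the aneuploid cells form one connected component
        of the k=6 nearest-neighbor adjacency graph."""
        d = squareform(pdist(geometry.positions))
        np.fill_diagonal(d, np.inf)
        knn = np.argsort(d, axis=1)[:, :6]
        rows = np.repeat(np.arange(256), 6)
        adj = csr_matrix((np.ones(rows.size), (rows, knn.ravel())), shape=(256, 256))
        adj = adj + adj.T
        for _ in range(20):
            emb = place_aneuploid(geometry, 20, 0.0, rng)
            ids = np.flatnonzero(emb.ploidy)
            sub = adj[np.ix_(ids, ids)]
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1

    def test_full_dispersal_uniform_marginal(self, geometry):
        """At dispersal 1 every cell is aneuploid with equal frequency."""
        rng = np.random.default_rng(99)
        reps, n_an = 20_000, 64
        counts = np.zeros(256)
        for _ in range(reps):
            emb = place_aneuploid(geometry, n_an, 1.0, rng)
            counts += emb.ploidy
        _, pval = sps.chisquare(counts, f_exp=reps * n_an / 256)
        assert pval > 0.001


class TestBiopsy:
    def test_homogeneous_embryos(self, geometry, rng):
        full = place_aneuploid(geometry, 256, 1.0, rng)
        empty = place_aneuploid(geometry, 0, 1.0, rng)
        for idx in (0, 100, 255):
            assert take_biopsy(full, idx).aneuploid_count == 5
            assert take_biopsy(empty, idx).aneuploid_count == 0

    def test_invalid_index(self, geometry, rng):
        emb = place_aneuploid(geometry, 10, 1.0, rng)
        with pytest.raises(ValueError):
            take_biopsy(emb, 256)

    def test_hypergeometric_at_full_dispersal(self, rng):
        """At dispersal 1 the biopsy count given n_aneuploid is
        hypergeometric (uniform random subset); TV distance < 0.01."""
        n_an, reps = 64, 200_000
        cfg = ModelConfig(dispersal=1.0)
        counts, _ = simulate_biopsy_counts(np.full(reps, n_an), cfg, rng)
        observed = np.bincount(counts, minlength=6) / reps
        expected = sps.hypergeom.pmf(np.arange(6), 256, n_an, 5)
        assert 0.5 * np.abs(observed - expected).sum() < 0.01


class TestClassification:
    @pytest.mark.parametrize(
        "count,threshold_cls,any_cls",
        [
            (0, "euploid", "euploid"),
            (1, "mosaic", "mosaic"),
            (2, "mosaic", "mosaic"),
            (3, "mosaic", "mosaic"),
            (4, "aneuploid", "mosaic"),  # the only point of disagreement
            (5, "aneuploid", "aneuploid"),
        ],
    )
    def test_both_rules(self, count, threshold_cls, any_cls):
        b = Biopsy(cell_ids=np.arange(5), aneuploid_count=count)
        assert classify_biopsy(b, "threshold_20_70") == threshold_cls
        assert classify_biopsy(b, "any_but_not_all") == any_cls

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            classify_counts(np.array([1]), 5, "nonsense")


class TestBiopsyProportions:
    def test_degenerate_thetas(self, rng):
        cfg = ModelConfig()
        assert np.allclose(
            simulate_biopsy_proportions(ErrorRates(1.0, 0.2), cfg, 500, rng).as_array(),
            [0, 0, 1],
        )
        assert np.allclose(
            simulate_biopsy_proportions(ErrorRates(0.0, 0.0), cfg, 500, rng).as_array(),
            [1, 0, 0],
        )

    def test_euploid_proportion_matches_semianalytic_oracle(self, rng):
        """Cross-check of the full pipeline at dispersal 1 against an
        independent route: the euploid-biopsy proportion equals the lineage
        average of the exact hypergeometric zero-draw probability."""
        theta, n = ErrorRates(0.58, 0.015), 300_000
        cfg = ModelConfig(dispersal=1.0)
        observed = simulate_biopsy_proportions(theta, cfg, n, rng).prop_euploid
        n_an = simulate_lineages(theta, cfg, n, rng)
        p0 = sps.hypergeom.pmf(0, 256, n_an, 5)
        expected = p0.mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * se

    def test_monotone_in_error_rates(self, rng):
        """Aneuploid-biopsy proportion rises with the meiotic rate; the
        euploid proportion falls with the mitotic rate."""
        cfg = ModelConfig(dispersal=1.0)
        n = 30_000
        a_low = simulate_biopsy_proportions(ErrorRates(0.2, 0.02), cfg, n, rng).prop_aneuploid
        a_high = simulate_biopsy_proportions(ErrorRates(0.6, 0.02), cfg, n, rng).prop_aneuploid
        assert a_low < a_high
        e_low = simulate_biopsy_proportions(ErrorRates(0.3, 0.005), cfg, n, rng).prop_euploid
        e_high = simulate_biopsy_proportions(ErrorRates(0.3, 0.05), cfg, n, rng).prop_euploid
        assert e_high < e_low

    @given(
        meiotic=st.floats(0.0, 1.0),
        mitotic=st.floats(0.0, 1.0),
        dispersal=st.sampled_from([0.0, 0.3, 0.5, 1.0]),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_summary_is_simplex(self, meiotic, mitotic, dispersal):
        stats = simulate_biopsy_proportions(
            ErrorRates(meiotic, mitotic),
            ModelConfig(dispersal=dispersal),
            64,
            np.random.default_rng(0),
        )
        v = stats.as_array()
        assert np.all(v >= 0) and np.all(v <= 1)
        assert abs(v.sum() - 1.0) < 1e-12
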