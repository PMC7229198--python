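"""Cell/gene QC boundaries, log2(CPM+1), and the monotonicity property."""

import numpy as np
import pytest

from orthostage import (
    QCConfig,
    common_genes,
    filter_cells,
    filter_genes_by_phenotype,
    filter_genes_min_count,
    log2_cpm,
)

from conftest import make_counts


class TestFilterCells:
    def test_gene_detection_boundary_at_paper_scale(self):
        """4,499 detected genes removed; 4,500 kept."""
        n_genes = 5_000
        config = QCConfig(min_total_counts=None, max_total_counts=60_000,
                          min_genes_detected=4_500)
        counts = np.zeros((2, n_genes), dtype=int)
        counts[0, :4_499] = 1
        counts[1, :4_500] = 1
        retained, report = filter_cells(make_counts(counts), config)
        assert retained.cell_ids == ["c1"]
        assert list(report["retained"]) == [False, True]

    def test_max_counts_boundary(self):
        """60,000 total counts kept ("more than" removed); 60,001 removed."""
        n_genes = 5_000
        config = QCConfig(min_total_counts=None, max_total_counts=60_000,
                          min_genes_detected=4_500)
        counts = np.ones((2, n_genes), dtype=int)
        counts[0, 0] = 60_000 - (n_genes - 1)      # total exactly 60,000
        counts[1, 0] = 60_001 - (n_genes - 1)      # total 60,001
        retained, _ = filter_cells(make_counts(counts), config)
        assert retained.cell_ids == ["c0"]

    def test_min_counts_boundary(self):
        """12,499 total removed ("fewer than"); 12,500 kept."""
        config = QCConfig(min_total_counts=12_500, max_total_counts=60_000,
                          min_genes_detected=None)
        counts = np.array([[12_499, 0], [12_500, 0]])
        retained, _ = filter_cells(make_counts(counts), config)
        assert retained.cell_ids == ["c1"]

    def test_lower_bound_can_be_disabled(self):
        config = QCConfig(min_total_counts=None, max_total_counts=60_000,
                          min_genes_detected=1)
        counts = np.array([[5, 0]])
        retained, _ = filter_cells(make_counts(counts), config)
        assert retained.n_cells == 1

    def test_empty_matrix_warns(self):
        m = make_counts(np.zeros((0, 3), dtype=int), phenotype=[], individual=[])
        with pytest.warns(UserWarning, match="empty"):
            retained, _ = filter_cells(m, QCConfig())
        assert retained.n_cells == 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            QCConfig(min_total_counts=100, max_total_counts=50)
        with pytest.raises(ValueError):
            QCConfig(min_cell_fraction=0.0)


class TestLog2CPM:
    def test_zero_count_maps_to_zero(self):
        m = make_counts([[0, 10]])
        assert log2_cpm(m)[0, 0] == 0.0

    def test_count_one_in_a_million_total(self):
        m = make_counts([[1, 999_999]])
        assert log2_cpm(m)[0, 0] == pytest.approx(1.0)  # log2(1 + 1) = 1

    def test_uniform_cell_closed_form(self):
        g = 8
        m = make_counts([[5] * g])
        expected = np.log2(1 + 1e6 / g)
        np.testing.assert_allclose(log2_cpm(m), expected)

    def test_zero_total_cell_is_an_error(self):
        m = make_counts([[0, 0]])
        with pytest.raises(ValueError, match="zero total"):
            log2_cpm(m)


class TestGeneFilters:
    def test_fraction_boundary_inclusive(self):
        """Above cutoff in exactly 10% of one group's cells -> retained."""
        log = np.zeros((10, 2))
        log[0, 0] = 2.0  # gene 0 above cutoff 1 in exactly 1/10 cells
        kept = filter_genes_by_phenotype(log, ["g0", "g1"], ["p"] * 10, cutoff=1.0)
        assert kept == ["g0"]

    def test_below_fraction_in_every_group_removed(self):
        log = np.zeros((100, 1))
        log[:9, 0] = 2.0  # 9% of the single group
        assert filter_genes_by_phenotype(log, ["g0"], ["p"] * 100, cutoff=1.0) == []

    def test_exactly_at_cutoff_is_not_above(self):
        log = np.full((10, 1), 1.0)
        assert filter_genes_by_phenotype(log, ["g0"], ["p"] * 10, cutoff=1.0) == []

    def test_any_single_group_suffices(self):
        log = np.zeros((20, 1))
        log[:10, 0] = 5.0  # all of group A, none of group B
        labels = ["A"] * 10 + ["B"] * 10
        assert filter_genes_by_phenotype(log, ["g0"], labels, cutoff=1.0) == ["g0"]

    def test_min_count_boundary_and_all_zero_gene(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[0, 0] = 1  # 1 count in exactly 10% of the group
        m = make_counts(counts)
        kept = filter_genes_min_count(m, ["p"] * 10, min_count=1, min_cell_fraction=0.10)
        assert kept == ["g0"]

    def test_min_count_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 3, size=(15, 8))
            labels = rng.choice(["x", "y", "z"], size=15)
            m = make_counts(counts)
            kept = set(filter_genes_min_count(m, labels, 1, 0.25))
            expected = set()
            for j in range(8):
                for g in ("x", "y", "z"):
                    mask = labels == g
                    if mask.sum() and (counts[mask, j] >= 1).mean() >= 0.25:
                        expected.add(f"g{j}")
            assert kept == expected


class TestCommonGenes:
    def test_disjoint_and_identical(self):
        assert common_genes(["a", "b"], ["c"]) == []
        assert common_genes(["b", "a"], ["a", "b"]) == ["a", "b"]

    def test_ortholog_map_translates_namespace(self):
        mapped = common_genes(["HUM1", "HUM2"], ["MAC9"], {"MAC9": "HUM2"})
        assert mapped == ["HUM2"]


def relax(config: QCConfig) -> QCConfig:
    return QCConfig(
        min_total_counts=None if config.min_total_counts is None else config.min_total_counts - 5,
        max_total_counts=config.max_total_counts + 5,
        min_genes_detected=max(0, config.min_genes_detected - 1),
        gene_cutoff_log2cpm=config.gene_cutoff_log2cpm - 0.5,
        min_cell_fraction=max(0.01, config.min_cell_fraction - 0.05),
    )


class TestMonotonicity:
    def test_relaxing_thresholds_never_shrinks_retained_sets(self):
        """Over 50 random matrices, every relaxed threshold keeps a superset."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            counts = rng.integers(0, 30, size=(12, 15))
            labels = rng.choice(["u", "v"], size=12)
            m = make_counts(counts, phenotype=labels)
            base = QCConfig(
                min_total_counts=int(rng.integers(50, 200)),
                max_total_counts=int(rng.integers(250, 500)),
                min_genes_detected=int(rng.integers(2, 12)),
                gene_cutoff_log2cpm=float(rng.uniform(5, 13)),
                min_cell_fraction=float(rng.uniform(0.1, 0.6)),
            )
            loose = relax(base)
            cells_base, _ = filter_cells(m, base)
            cells_loose, _ = filter_cells(m, loose)
            assert set(cells_base.cell_ids) <= set(cells_loose.cell_ids)
            if cells_base.n_cells:
                log = log2_cpm(cells_base)
                genes_base = set(
                    filter_genes_by_phenotype(
                        log, m.feature_ids, cells_base.cell_meta["phenotype"].to_numpy(),
                        base.gene_cutoff_log2cpm, base.min_cell_fraction,
                    )
                )
                genes_loose = set(
                    filter_genes_by_phenotype(
                        log, m.feature_ids, cells_base.cell_meta["phenotype"].to_numpy(),
                        loose.gene_cutoff_log2cpm, loose.min_cell_fraction,
                    )
                )
                assert genes_base <= genes_loose
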