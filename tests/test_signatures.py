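"""Expression-correlation signatures of transitions and attractors."""

import numpy as np
import pytest

from waddyn.signatures import (
    ExpressionMatrix,
    NoDefinedPairsError,
    cell_cell_corr,
    gene_gene_corr,
    standardize_genes,
    transition_report,
)


def _matrix(values, prefix="c"):
    values = np.asarray(values, float)
    cells = [f"{prefix}{i}" for i in range(values.shape[0])]
    genes = [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, cells, genes)


def test_collinear_genes_fully_correlated():
    t = np.array([1.0, 2.0, 3.0])
    m = _matrix(np.stack([1 * t + 0.0, 2 * t + 1.0], axis=1))
    result = gene_gene_corr(m)
    assert result.matrix.loc["g0", "g1"] == pytest.approx(1.0)
    assert result.mean_abs_offdiag == pytest.approx(1.0)


def test_anticollinear_genes_fully_anticorrelated():
    t = np.array([1.0, 2.0, 3.0])
    m = _matrix(np.stack([t, -t], axis=1))
    result = gene_gene_corr(m)
    assert result.matrix.loc["g0", "g1"] == pytest.approx(-1.0)
    assert result.mean_abs_offdiag == pytest.approx(1.0)


def test_gene_corr_matches_hand_computation():
    m = _matrix([[1, 2], [2, 2], [3, 5]])
    x, y = m.values[:, 0], m.values[:, 1]
    xc, yc = x - x.mean(), y - y.mean()
    hand = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    assert gene_gene_corr(m).matrix.loc["g0", "g1"] == pytest.approx(hand)


def test_constant_gene_flagged_undefined():
    m = _matrix([[1.0, 5.0, 0.1], [2.0, 5.0, 0.3], [3.0, 5.0, 0.2]])
    result = gene_gene_corr(m)
    assert result.undefined_genes == ["g1"]
    assert np.isnan(result.matrix.loc["g1", "g0"])
    assert not np.isnan(result.matrix.loc["g0", "g2"])
    assert np.isfinite(result.mean_abs_offdiag)


def test_all_constant_genes_error():
    with pytest.raises(NoDefinedPairsError):
        gene_gene_corr(_matrix(np.ones((3, 3))))


def test_identical_cells_fully_correlated():
    m = _matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert cell_cell_corr(m).mean_corr == pytest.approx(1.0)


def test_opposite_cells_anticorrelated():
    m = _matrix([[1.0, -1.0], [-1.0, 1.0]])
    assert cell_cell_corr(m).mean_corr == pytest.approx(-1.0)


def test_cell_corr_matches_brute_force(rng):
    v = rng.normal(size=(4, 3))
    m = _matrix(v)
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    brute = np.mean([np.corrcoef(v[i], v[j])[0, 1] for i, j in pairs])
    result = cell_cell_corr(m)
    assert result.mean_corr == pytest.approx(brute)
    assert result.n_pairs == 6


def test_constant_cell_excluded_and_reported():
    m = _matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [1.0, 2.5, 2.9]])
    result = cell_cell_corr(m)
    assert result.excluded_cells == ["c1"]
    assert result.n_pairs == 1


def test_minimum_shape_enforced():
    with pytest.raises(ValueError):
        gene_gene_corr(_matrix([[1.0, 2.0]]))  # one cell
    with pytest.raises(ValueError):
        cell_cell_corr(ExpressionMatrix(np.ones((3, 1)), ["a", "b", "c"], ["g"]))


def test_affine_rescaling_invariance(rng):
    v = rng.normal(size=(12, 4))
    m1 = _matrix(v)
    m2 = _matrix(v * np.array([2.0, 0.5, 3.0, 1.0]) + np.array([1.0, -2.0, 0.0, 4.0]))
    assert gene_gene_corr(m1).mean_abs_offdiag == pytest.approx(
        gene_gene_corr(m2).mean_abs_offdiag
    )


def test_transition_group_shows_high_gene_corr(rng):
    # cells spread along a line in gene space (in transit) vs an isotropic
    # cloud (settled): the transit group has the higher mean |gene-gene|
    t = rng.uniform(0, 1, 30)
    transit = np.stack([2 * t, -1.5 * t, 3 * t], axis=1) + 0.05 * rng.normal(size=(30, 3))
    settled = 0.3 * rng.normal(size=(30, 3)) + 1.0
    ids = [f"t{i}" for i in range(30)] + [f"s{i}" for i in range(30)]
    m = ExpressionMatrix(np.vstack([transit, settled]), ids, ["g0", "g1", "g2"])
    report = transition_report(m, {"transit": ids[:30], "settled": ids[30:]})
    by_group = report.set_index("group")
    assert (
        by_group.loc["transit", "mean_abs_gene_gene"]
        > by_group.loc["settled", "mean_abs_gene_gene"]
    )


def test_single_group_reproduces_whole_matrix(rng):
    v = rng.normal(size=(8, 3))
    m = _matrix(v)
    report = transition_report(m, {"all": list(m.cell_ids)})
    assert report.iloc[0].mean_abs_gene_gene == pytest.approx(
        gene_gene_corr(m).mean_abs_offdiag
    )
    assert report.iloc[0].mean_cell_cell == pytest.approx(cell_cell_corr(m).mean_corr)


def test_empty_partition_gives_empty_report():
    m = _matrix(np.empty((0, 3)))
    report = transition_report(m, {})
    assert len(report) == 0


def test_small_group_skipped_with_notice(rng):
    v = rng.normal(size=(3, 3))
    m = _matrix(v)
    report = transition_report(m, {"solo": [m.cell_ids[0]], "rest": m.cell_ids[1:]})
    solo = report.set_index("group").loc["solo"]
    assert np.isnan(solo.mean_abs_gene_gene)
    assert "skipped" in solo.notice


def test_partition_must_cover_all_cells(rng):
    m = _matrix(rng.normal(size=(4, 2)))
    with pytest.raises(ValueError):
        transition_report(m, {"some": m.cell_ids[:2]})


def test_standardize_genes_zero_mean_unit_sd(rng):
    m = _matrix(rng.normal(size=(10, 3)) * 5 + 2)
    z = standardize_genes(m)
    assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.values.std(axis=0), 1.0)


def test_csv_and_tsv_round_trip(tmp_path, rng):
    m = _matrix(rng.normal(size=(5, 4)))
    for name, sep in (("expr.csv", ","), ("expr.tsv", "\t")):
        path = tmp_path / name
        m.to_csv(path, sep=sep)
        loaded = ExpressionMatrix.from_csv(path)
        assert loaded.cell_ids == m.cell_ids
        assert loaded.gene_ids == m.gene_ids
        assert np.allclose(loaded.values, m.values)


def test_matrix_validation():
    with pytest.raises(ValueError):
        ExpressionMatrix(np.array([[1.0, np.nan]]), ["c0"], ["g0", "g1"])
    with pytest.raises(ValueError):
        ExpressionMatrix(np.ones((2, 2)), ["c0", "c0"], ["g0", "g1"])
    with pytest.raises(ValueError):
        ExpressionMatrix(np.ones((2, 2)), ["c0", "c1"], ["g0"])
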