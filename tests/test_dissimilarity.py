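"""Morisita-Horn dissimilarity and the Patefield null model."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regalforage import (OneSexAbsentError, SexPlantTable, morisita_horn,
                         null_test, patefield_sample, year_table)
from regalforage.dissimilarity import _patefield_first_rows

from conftest import make_dataset
from oracles import (empirical_first_row_distribution,
                     exact_label_shuffle_distribution,
                     morisita_horn_reference, total_variation)


def table_of(rows, species=("A", "B")):
    import pandas as pd

    return SexPlantTable(pd.DataFrame(rows, index=["F", "M"],
                                      columns=list(species[:len(rows[0])])))


@pytest.mark.parametrize(
    "x, y, expected",
    [([1, 1], [1, 1], 0.0), ([2, 0], [0, 2], 1.0), ([3, 1], [1, 3], 0.4)],
)
def test_hand_values_exact(x, y, expected):
    assert morisita_horn(x, y) == pytest.approx(expected, abs=1e-12)
    assert morisita_horn(x, y) == pytest.approx(
        morisita_horn_reference(x, y), abs=1e-12)


def test_empty_assemblage_rejected():
    with pytest.raises(ValueError):
        morisita_horn([0, 0], [1, 1])


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    st.lists(st.integers(0, 40), min_size=2, max_size=8).filter(lambda v: sum(v) > 0),
    st.lists(st.integers(0, 40), min_size=2, max_size=8).filter(lambda v: sum(v) > 0),
    st.integers(2, 7),
)
def test_symmetry_and_scale_invariance(x, y, k):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    d = morisita_horn(x, y)
    assert 0.0 <= d <= 1.0
    assert morisita_horn(y, x) == pytest.approx(d, abs=1e-12)
    assert morisita_horn([k * v for v in x], y) == pytest.approx(d, rel=1e-9)


def test_year_table_basic_and_one_sex_absent():
    ds = make_dataset([(2001, 180, "F", "A"), (2001, 181, "M", "B"),
                       (2002, 180, "M", "A")])
    t = year_table(ds, 2001)
    assert t.data.to_numpy().tolist() == [[1, 0], [0, 1]]
    assert t.grand_total == 2
    with pytest.raises(OneSexAbsentError):
        year_table(ds, 2002)


def test_year_table_matches_generator_truth(default_season):
    ds, truth = default_season
    cfgless = ds.records[~ds.records["plant_species"].str.contains("spp")]
    year = ds.years[5]
    t = year_table(ds, year)
    want = truth.counts[truth.counts.year == year]["count"].sum()
    assert t.grand_total == want


def test_patefield_preserves_margins(rng):
    rows, cols = [7, 5], [3, 3, 4, 2]
    for _ in range(50):
        t = patefield_sample(rows, cols, rng)
        assert t.sum(axis=1).tolist() == rows
        assert t.sum(axis=0).tolist() == cols
        assert (t >= 0).all()


def test_patefield_single_column_is_forced(rng):
    t = patefield_sample([3, 3], [6], rng)
    assert t.tolist() == [[3], [3]]


def test_patefield_margin_mismatch_raises(rng):
    with pytest.raises(ValueError):
        patefield_sample([3, 3], [3, 2], rng)


def test_patefield_matches_hypergeometric_probability(rng):
    """Margins (3,3) x (3,3): P(cell11 = 1) = C(3,1)C(3,2)/C(6,3) = 0.45."""
    draws = _patefield_first_rows([3, 3], 3, 20_000, rng)
    freq = np.mean(draws[:, 0] == 1)
    assert freq == pytest.approx(0.45, abs=0.012)


def test_patefield_distribution_matches_label_shuffle_oracle(rng):
    """Sampler distribution equals the exact label-shuffle enumeration on a
    handful of small margins (three-way sweep lives in the acceptance suite)."""
    cases = [([3, 3], [3, 3]), ([4, 2], [2, 2, 2]), ([5, 3], [4, 4])]
    for rows_m, cols_m in cases:
        exact = exact_label_shuffle_distribution(rows_m, cols_m)
        draws = _patefield_first_rows(cols_m, rows_m[0], 40_000, rng)
        emp = empirical_first_row_distribution(draws)
        assert total_variation(exact, emp) < 0.01


def test_patefield_agrees_with_r2dtable():
    """Cross-check against R's stats::r2dtable (the reference Patefield
    implementation): cell(1,1) distribution on margins (5,4) x (4,5)."""
    script = (
        'set.seed(7); t <- r2dtable(40000, c(5,4), c(4,5));'
        'cat(tabulate(sapply(t, function(m) m[1,1]) + 1, 6) / 40000)'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    r_probs = np.array([float(v) for v in out.stdout.split()])
    rng = np.random.default_rng(7)
    draws = _patefield_first_rows([4, 5], 5, 40_000, rng)
    ours = np.bincount(draws[:, 0], minlength=6) / 40_000
    assert np.abs(r_probs - ours).sum() / 2 < 0.015


def test_morisita_horn_agrees_with_vegan():
    """vegan::vegdist(method='horn') is an independent implementation of the
    abundance-based Horn-Morisita dissimilarity."""
    x, y = [3, 1, 7, 0], [1, 3, 2, 5]
    script = (
        'suppressMessages(library(vegan));'
        'm <- rbind(c(3,1,7,0), c(1,3,2,5));'
        'cat(sprintf("%.15f", as.numeric(vegdist(m, method="horn"))))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    assert morisita_horn(x, y) == pytest.approx(float(out.stdout), abs=1e-9)


def test_null_test_single_plant_degenerate(rng):
    res = null_test(table_of([[4], [6]], species="A"), n_reps=100, rng=rng)
    assert res.observed_dmh == 0.0
    assert (res.ci_lower, res.ci_upper) == (0.0, 0.0)
    assert res.classification == "within"


def test_null_test_disjoint_table_always_above(rng):
    res = null_test(table_of([[50, 0], [0, 50]]), n_reps=1000, rng=rng)
    assert res.observed_dmh == pytest.approx(1.0)
    assert res.classification == "above"


def test_null_test_bitwise_reproducible():
    t = table_of([[12, 3, 5], [2, 9, 4]], species=("A", "B", "C"))
    a = null_test(t, n_reps=500, rng=123)
    b = null_test(t, n_reps=500, rng=123)
    assert a.observed_dmh == b.observed_dmh
    assert np.array_equal(a.null_values, b.null_values)
    assert (a.ci_lower, a.ci_upper, a.classification) == \
        (b.ci_lower, b.ci_upper, b.classification)
    assert a.seed == 123


def test_sd_ci_method_flag(rng):
    t = table_of([[12, 3, 5], [2, 9, 4]], species=("A", "B", "C"))
    res = null_test(t, n_reps=2000, rng=rng, ci_method="sd")
    mu, sd = res.null_values.mean(), res.null_values.std(ddof=1)
    assert res.ci_upper == pytest.approx(mu + 1.959964 * sd, rel=1e-4)
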