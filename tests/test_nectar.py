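"""Outlier screening, heterogeneous-variance contrasts, Bonferroni families."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regalforage import (add_totals, bonferroni_family,
                         exclude_sparse_compounds, group_contrast,
                         remove_outliers, simulate_nectar_panel)
from regalforage.association import FEMALE_ASSOCIATED, MALE_ASSOCIATED

LABELS = {"Fem1": FEMALE_ASSOCIATED, "Fem2": FEMALE_ASSOCIATED,
          "Mal1": MALE_ASSOCIATED, "Mal2": MALE_ASSOCIATED}


def panel(values_by_species, compound="sugar"):
    rows = []
    for sp, values in values_by_species.items():
        for i, v in enumerate(values):
            rows.append((sp, f"{sp}_{i}", compound, float(v)))
    return pd.DataFrame(rows, columns=["species", "sample_id", "compound",
                                       "concentration"])


def test_constant_values_never_screened():
    df = panel({"A": [1, 1, 1, 1, 1]})
    kept, report = remove_outliers(df, k=2)
    assert report.n_removed == 0 and len(kept) == 5


def test_outlier_rule_matches_direct_arithmetic():
    """(1,1,1,1,100): mean 20.8, sample SD 44.27, so z(100) = 1.789 -- the
    spike survives k=2 but is removed at k=1.5 (brute-force verification
    of the k * SD rule with the candidate included in its own group)."""
    values = [1, 1, 1, 1, 100]
    mean = np.mean(values)
    sd = np.std(values, ddof=1)
    z = abs(100 - mean) / sd
    assert z == pytest.approx(1.7889, abs=1e-4)
    df = panel({"A": values})
    _, at2 = remove_outliers(df, k=2)
    assert at2.n_removed == 0
    kept, at15 = remove_outliers(df, k=1.5)
    assert at15.n_removed == 1
    assert at15.removed.iloc[0]["concentration"] == 100
    assert at15.removed.iloc[0]["z_score"] == pytest.approx(z)
    assert len(kept) == 4


def test_injected_spike_removed_at_k4(rng):
    """A single far spike is removed at k = 4 and nothing else is.

    The candidate is included in its own group SD, which bounds |z| at
    (n-1)/sqrt(n); the panel is sized so the brute-force z of the spike
    exceeds 4 (verified directly below).
    """
    base = rng.normal(10, 0.5, size=25).tolist()
    values = base + [10 + 12 * np.std(base, ddof=1)]
    mean, sd = np.mean(values), np.std(values, ddof=1)
    assert abs(values[-1] - mean) / sd > 4  # oracle arithmetic
    kept, report = remove_outliers(panel({"A": values}), k=4)
    assert report.n_removed == 1
    assert report.removed.iloc[0]["concentration"] == values[-1]
    assert len(kept) == 25


def test_small_groups_skipped():
    df = panel({"A": [1, 100]})  # 2 values: below the screening minimum
    _, report = remove_outliers(df, k=1)
    assert report.n_removed == 0


def test_totals_sum_detected_compounds():
    rows = [
        ("A", "s1", "glucose", 2.0), ("A", "s1", "fructose", 3.0),
        ("A", "s1", "proline", 1.0),
        ("A", "s2", "glucose", 4.0),
    ]
    df = pd.DataFrame(rows, columns=["species", "sample_id", "compound",
                                     "concentration"])
    out = add_totals(df)
    tc = out[(out.sample_id == "s1") & (out.compound == "total carbohydrates")]
    ta = out[(out.sample_id == "s1") & (out.compound == "total amino acids")]
    assert tc["concentration"].item() == 5.0
    assert ta["concentration"].item() == 1.0
    # s2 total carbohydrates = glucose only (missing compounds contribute 0)
    tc2 = out[(out.sample_id == "s2") & (out.compound == "total carbohydrates")]
    assert tc2["concentration"].item() == 4.0


def test_sparse_compound_exclusion():
    rows = [("A", f"s{i}", "glucose", 1.0) for i in range(10)]
    rows += [("A", f"s{i}", "phenylalanine", 1.0) for i in range(3)]
    df = pd.DataFrame(rows, columns=["species", "sample_id", "compound",
                                     "concentration"])
    kept, sparse = exclude_sparse_compounds(df, max_missing=0.5)
    assert sparse == ("phenylalanine",)
    assert set(kept["compound"]) == {"glucose"}


def test_contrast_estimate_is_group_mean_difference(rng):
    df = panel({
        "Fem1": rng.normal(12, 0.1, 13), "Fem2": rng.normal(12, 0.1, 13),
        "Mal1": rng.normal(10, 0.1, 13), "Mal2": rng.normal(10, 0.1, 13),
    })
    res = group_contrast(df, "sugar", LABELS)
    assert 1.9 <= res.estimate <= 2.1
    assert res.p_value < 1e-6
    assert res.num_df == 1
    assert res.den_df_pooled == 48.0


def test_contrast_invariances(rng):
    df = panel({sp: rng.normal(m, s, 13)
                for sp, m, s in [("Fem1", 12, 1.0), ("Fem2", 14, 2.0),
                                 ("Mal1", 10, 0.5), ("Mal2", 9, 3.0)]})
    res = group_contrast(df, "sugar", LABELS)
    shifted = df.assign(concentration=df.concentration + 100)
    res_shift = group_contrast(shifted, "sugar", LABELS)
    assert res_shift.estimate == pytest.approx(res.estimate, abs=1e-9)
    assert res_shift.f_stat == pytest.approx(res.f_stat, rel=1e-9)
    swapped = {sp: (FEMALE_ASSOCIATED if lab == MALE_ASSOCIATED
                    else MALE_ASSOCIATED) for sp, lab in LABELS.items()}
    res_swap = group_contrast(df, "sugar", swapped)
    assert res_swap.estimate == pytest.approx(-res.estimate)
    assert res_swap.f_stat == pytest.approx(res.f_stat, rel=1e-12)
    assert res_swap.p_value == pytest.approx(res.p_value, rel=1e-9)


def test_one_species_per_group_reduces_to_welch(rng):
    """With one species per group the contrast is exactly Welch's t-test
    (independent oracle: scipy.stats.ttest_ind with equal_var=False)."""
    a = rng.normal(12, 2.0, 13)
    b = rng.normal(10, 0.4, 8)
    df = panel({"Fem1": a, "Mal1": b})
    res = group_contrast(df, "sugar",
                         {"Fem1": FEMALE_ASSOCIATED, "Mal1": MALE_ASSOCIATED})
    t, p = stats.ttest_ind(a, b, equal_var=False)
    assert res.f_stat == pytest.approx(t**2, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-6)


def test_singleton_species_excluded_with_warning(rng):
    df = panel({"Fem1": rng.normal(12, 1, 13), "Fem2": [5.0],
                "Mal1": rng.normal(10, 1, 13), "Mal2": rng.normal(10, 1, 13)})
    with pytest.warns(UserWarning, match="Fem2"):
        res = group_contrast(df, "sugar", LABELS)
    assert res.excluded_species == ("Fem2",)


@pytest.mark.parametrize("size, alpha", [(5, 0.01), (4, 0.0125), (1, 0.05)])
def test_bonferroni_family_alpha(size, alpha, rng):
    df = panel({"Fem1": rng.normal(12, 1, 13), "Mal1": rng.normal(10, 1, 13)})
    labels = {"Fem1": FEMALE_ASSOCIATED, "Mal1": MALE_ASSOCIATED}
    results = [group_contrast(df, "sugar", labels) for _ in range(size)]
    adjusted = bonferroni_family(results)
    assert all(r.alpha_adjusted == pytest.approx(alpha) for r in adjusted)
    assert all(r.significant == (r.p_value < r.alpha_adjusted)
               for r in adjusted)


def test_panel_generator_recovery_and_design():
    """delta = 2 group shift is recovered by the contrast; replicate counts
    follow the 13-per-species (8 for C. discolor) design; SD 0 gives
    constant replicates."""
    samples, truth = simulate_nectar_panel(seed=3, group_shift=2.0)
    reps = samples.groupby("species")["sample_id"].nunique()
    assert reps["Cirsium discolor"] == 8
    assert (reps.drop("Cirsium discolor") == 13).all()
    labels = {"Centaurea stoebe": FEMALE_ASSOCIATED,
              "Cirsium discolor": FEMALE_ASSOCIATED,
              "Cirsium pumilum": FEMALE_ASSOCIATED,
              "Monarda fistulosa": FEMALE_ASSOCIATED,
              "Asclepias syriaca": MALE_ASSOCIATED,
              "Asclepias tuberosa": MALE_ASSOCIATED}
    base, _ = simulate_nectar_panel(seed=3, group_shift=0.0)
    res = group_contrast(samples, "glucose", labels)
    res0 = group_contrast(base, "glucose", labels)
    assert res.estimate - res0.estimate == pytest.approx(2.0, abs=0.6)

    flat, _ = simulate_nectar_panel(
        profiles={"A": {"glucose": (5.0, 0.0)}}, seed=1)
    assert (flat["concentration"] == 5.0).all()
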