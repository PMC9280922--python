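import numpy as np
import pandas as pd
import pytest

from dbnpsy import (
    WavePanel,
    apply_eligibility,
    binarize_days,
    binarize_substance,
    build_eligibility_flags,
    derive_syndromes,
    load_cohort,
    load_panel,
)
from dbnpsy.cohort import ItemCatalog, CatalogItem
from dbnpsy.nodes import W1, W2


# ----------------------------------------------------------------- catalog


def test_default_catalog_partitions_thirty_items(catalog):
    assert len(catalog.ids) == 30
    sizes = {d: len(catalog.domain_items(d)) for d in
             ("soma6", "psych6", "hypomanic", "psychotic")}
    assert sizes == {"soma6": 6, "psych6": 6, "hypomanic": 5, "psychotic": 6}
    assert len(catalog.dynamic_ids) == 29
    assert catalog.static_ids == ("twin_status",)


def test_catalog_rejects_wrong_domain_count():
    items = tuple(
        CatalogItem(f"s{i}", f"s{i}", "soma6", "x") for i in range(5)
    )
    with pytest.raises(ValueError, match="soma6"):
        ItemCatalog(items)


# ------------------------------------------------------------- load_panel


def _w1_frame(catalog, n=3):
    rng = np.random.default_rng(0)
    cols = catalog.items_for_wave(W1)
    return pd.DataFrame(
        rng.integers(0, 2, (n, len(cols))),
        columns=cols,
        index=pd.Index([f"p{i}" for i in range(n)], name="participant_id"),
    )


def test_load_panel_identity_read(tmp_path, catalog):
    df = _w1_frame(catalog)
    path = tmp_path / "w1.csv"
    df.to_csv(path)
    panel = load_panel(path, catalog, wave=W1)
    assert panel.n == 3
    assert list(panel.participants) == ["p0", "p1", "p2"]  # row order preserved
    pd.testing.assert_frame_equal(
        panel.values.astype(int), df[list(panel.values.columns)].astype(int)
    )


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda df: df.drop(columns=["anergia"]), "anergia"),
        (lambda df: df.assign(mystery=0), "mystery"),
        (lambda df: df.assign(anergia=[2, 0, 1]), "anergia"),
        (lambda df: df.set_axis(["p0", "p0", "p2"]), "p0"),
    ],
    ids=["missing-column", "unknown-column", "non-binary-value", "duplicate-id"],
)
def test_load_panel_contract_errors(tmp_path, catalog, mutate, message):
    df = mutate(_w1_frame(catalog))
    df.index.name = "participant_id"
    path = tmp_path / "bad.csv"
    df.to_csv(path)
    with pytest.raises(ValueError, match=message):
        load_panel(path, catalog, wave=W1)


def test_load_panel_nonbinary_error_cites_row_and_column(tmp_path, catalog):
    df = _w1_frame(catalog)
    df.loc["p1", "fatigue"] = 2
    path = tmp_path / "bad.csv"
    df.to_csv(path)
    with pytest.raises(ValueError, match="p1") as err:
        load_panel(path, catalog, wave=W1)
    assert "fatigue" in str(err.value)


def test_load_cohort_wide_and_long_dialects_agree(tmp_path, catalog):
    rng = np.random.default_rng(1)
    ids = [f"p{i}" for i in range(5)]
    dyn = list(catalog.dynamic_ids)
    wide = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    for item in dyn:
        wide[f"{item}@W1"] = rng.integers(0, 2, 5)
        wide[f"{item}@W2"] = rng.integers(0, 2, 5)
    wide["twin_status"] = rng.integers(0, 2, 5)
    wide_path = tmp_path / "wide.csv"
    wide.to_csv(wide_path)

    long_rows = []
    for wave in (W1, W2):
        block = pd.DataFrame({"participant_id": ids, "wave": wave})
        for item in dyn:
            block[item] = wide[f"{item}@{wave}"].to_numpy()
        block["twin_status"] = wide["twin_status"].to_numpy()
        long_rows.append(block)
    long_path = tmp_path / "long.csv"
    pd.concat(long_rows).to_csv(long_path, index=False)

    w1a, w2a = load_cohort(wide_path, catalog)
    w1b, w2b = load_cohort(long_path, catalog)
    pd.testing.assert_frame_equal(w1a.values, w1b.values)
    pd.testing.assert_frame_equal(w2a.values, w2b.values)


# ----------------------------------------------------------- binarization


@pytest.mark.parametrize(
    "category, substance, expected",
    [
        ("daily_or_almost_daily", "tobacco", 1),
        ("daily_or_almost_daily", "alcohol", 1),
        ("daily_or_almost_daily", "cannabis", 1),
        ("weekly", "cannabis", 1),
        ("weekly", "alcohol", 0),
        ("weekly", "tobacco", 0),
        ("monthly", "cannabis", 0),
        ("never", "tobacco", 0),
        ("never", "alcohol", 0),
        ("once_or_twice", "cannabis", 0),
    ],
)
def test_binarize_substance_rules(category, substance, expected):
    assert binarize_substance(category, substance) == expected


def test_binarize_substance_unknown_inputs():
    with pytest.raises(ValueError, match="category"):
        binarize_substance("sometimes", "tobacco")
    with pytest.raises(ValueError, match="substance"):
        binarize_substance("never", "caffeine")


@pytest.mark.parametrize("count, expected", [(0, 0), (1, 1), (14, 1), (365, 1)])
def test_binarize_days(count, expected):
    assert binarize_days(count) == expected
    # idempotent on its own binary output
    assert binarize_days(binarize_days(count)) == binarize_days(count)


def test_binarize_days_rejects_negative():
    with pytest.raises(ValueError):
        binarize_days(-1)


# -------------------------------------------------------------- syndromes


def _panel_with_counts(catalog, soma, psych, hypo, psychotic):
    """One-participant panel endorsing the first k items of each domain."""
    row = {}
    for domain, k in (("soma6", soma), ("psych6", psych),
                      ("hypomanic", hypo), ("psychotic", psychotic)):
        for i, item in enumerate(catalog.domain_items(domain)):
            row[item] = int(i < k)
    for item in catalog.items_for_wave(W1):
        row.setdefault(item, 0)
    return WavePanel(pd.DataFrame([row], index=["p0"]), W1, catalog)


def test_derive_syndromes_matches_truth_table_exhaustively(catalog):
    """Count-rule flags agree with independent enumeration over all counts."""
    for soma in range(7):
        for psych in range(7):
            for hypo in range(6):
                for psyc in range(7):
                    panel = _panel_with_counts(catalog, soma, psych, hypo, psyc)
                    got = derive_syndromes(panel).iloc[0]
                    assert got["dle"] == int(soma >= 3 or psych >= 2)
                    assert got["hmle"] == int(hypo == 5)
                    assert got["ple"] == int(psyc >= 2)


def test_derive_syndromes_requires_catalog(catalog):
    panel = WavePanel(pd.DataFrame({"a": [0, 1]}, index=["p0", "p1"]), W1, None)
    with pytest.raises(ValueError, match="ItemCatalog"):
        derive_syndromes(panel)


# ------------------------------------------------------------ eligibility


def _paired_panels(catalog, n=6, seed=0, sts_for=(), missing_w2=()):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    w1 = pd.DataFrame(0, index=pd.Index(ids, name="participant_id"),
                      columns=catalog.items_for_wave(W1))
    w2 = pd.DataFrame(
        rng.integers(0, 2, (n, len(catalog.items_for_wave(W2)))),
        index=w1.index, columns=catalog.items_for_wave(W2),
    )
    soma = list(catalog.domain_items("soma6"))
    for pid in sts_for:  # plant a depression-like syndrome at wave 1
        w1.loc[pid, soma[:3]] = 1
    w2 = w2.drop(index=list(missing_w2))
    return (
        WavePanel(w1, W1, catalog),
        WavePanel(w2, W2, catalog),
    )


def test_eligibility_modes_and_roster(catalog):
    p1, p2 = _paired_panels(catalog, sts_for=["p2"], missing_w2=["p4"])
    cidi = pd.Series({"p1": 1})
    flags = build_eligibility_flags(p1, p2, cidi)

    k1, k2, roster = apply_eligibility(p1, p2, flags, mode="primary")
    reasons = roster.set_index("participant_id")["reason"]
    assert reasons["p1"] == "cidi_diagnosis_w1"  # excluded in both modes
    assert reasons["p4"] == "incomplete"
    assert reasons["p2"] == ""  # syndrome alone keeps primary eligibility
    assert set(k1.participants) == {"p0", "p2", "p3", "p5"}
    assert list(k1.participants) == list(k2.participants)

    g1, g2, roster_p = apply_eligibility(p1, p2, flags, mode="progression")
    reasons_p = roster_p.set_index("participant_id")["reason"]
    assert reasons_p["p2"] == "sts_at_w1"
    assert set(g1.participants) == {"p0", "p3", "p5"}


def test_progression_cohort_is_subset_of_primary(catalog):
    for seed in range(3):
        p1, p2 = _paired_panels(catalog, n=8, seed=seed, sts_for=["p0", "p3"])
        flags = build_eligibility_flags(p1, p2, pd.Series({"p5": 1}))
        prim, _, _ = apply_eligibility(p1, p2, flags, mode="primary")
        prog, _, _ = apply_eligibility(p1, p2, flags, mode="progression")
        assert set(prog.participants) <= set(prim.participants)


def test_roster_counts_partition_the_cohort(catalog):
    p1, p2 = _paired_panels(catalog, sts_for=["p2"], missing_w2=["p4"])
    flags = build_eligibility_flags(p1, p2, pd.Series({"p1": 1}))
    _, _, roster = apply_eligibility(p1, p2, flags, mode="progression")
    assert roster["kept"].sum() + (roster["reason"] != "").sum() == len(roster)
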