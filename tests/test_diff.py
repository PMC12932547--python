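import numpy as np
import pytest

from irmdma import (
    IRMRA_DMA,
    PA_DMA,
    ScreenConfig,
    compute_rcq,
    results_to_frame,
    run_dma,
    wild_enriched_set,
)
from irmdma.errors import ConfigurationError

from conftest import make_design, make_table


def _table_design(per_group_values, taxa):
    """per_group_values: {group: matrix taxa x n_samples} of raw levels (closed to %)."""
    rows, samples, cols = [], [], []
    for gi, (g, vals) in enumerate(per_group_values.items()):
        vals = np.asarray(vals, dtype=float)
        for r in range(vals.shape[1]):
            sid = f"{g}{r + 1}"
            rows.append((sid, f"site{gi}", "target", g, str(r + 1)))
            samples.append(sid)
            cols.append(vals[:, r])
    raw = np.column_stack(cols)
    pct = raw / raw.sum(axis=0) * 100
    return make_table(pct, taxa=taxa, samples=samples), make_design(rows)


def test_low_abundance_genus_never_significant():
    # genus at ~0.001% everywhere: clear separation, but filtered out
    rare_a = [1e-5, 1.1e-5, 0.9e-5, 1e-5, 1.05e-5, 0.95e-5]
    rare_b = [5e-5, 5.5e-5, 4.5e-5, 5e-5, 5.2e-5, 4.8e-5]
    table, design = _table_design(
        {"A": [rare_a, [1] * 6], "B": [rare_b, [1] * 6]}, taxa=["Rare", "Main"]
    )
    (rare,) = [r for r in run_dma(table, design, ["A", "B"]) if r.genus == "Rare"]
    assert rare.p < 0.05
    assert not rare.passed_abundance_filter
    assert not rare.significant


def test_identical_values_direction_none():
    table, design = _table_design(
        {"A": [[1, 2, 3], [9, 8, 7]], "B": [[1, 2, 3], [9, 8, 7]]}, taxa=["G", "H"]
    )
    for r in run_dma(table, design, ["A", "B"]):
        assert r.direction == "none"
        assert not r.significant


def test_planted_shift_detected_with_direction():
    rng = np.random.default_rng(8)
    base = rng.lognormal(0, 0.2, size=(5, 6))
    shifted = base.copy() * rng.lognormal(0, 0.01, size=(5, 6))
    shifted[0] *= 8  # 8-fold planted shift in group A
    table, design = _table_design(
        {"A": shifted, "B": base}, taxa=[f"G{i}" for i in range(5)]
    )
    results = run_dma(table, design, ["A", "B"], reference="A")
    planted = next(r for r in results if r.genus == "G0")
    assert planted.significant
    assert planted.direction == "up"


def test_sample_permutation_invariance():
    rng = np.random.default_rng(9)
    vals = {"A": rng.lognormal(0, 0.5, (6, 6)), "B": rng.lognormal(0, 0.5, (6, 6))}
    table, design = _table_design(vals, taxa=[f"G{i}" for i in range(6)])
    res1 = run_dma(table, design, ["A", "B"])
    shuffled = table.subset_samples(list(table.samples)[::-1])
    res2 = run_dma(shuffled, design, ["A", "B"])
    for r1, r2 in zip(res1, res2):
        assert (r1.genus, r1.p, r1.direction, r1.significant) == (
            r2.genus,
            r2.p,
            r2.direction,
            r2.significant,
        )


def test_irmra_requires_filter_table(two_group_table, two_group_design):
    rcq = compute_rcq(two_group_table, "Ga")
    with pytest.raises(ConfigurationError, match="filter_table"):
        run_dma(rcq, two_group_design, ["A", "B"], method=IRMRA_DMA)
    # and with the filter table the same genus universe is enforced implicitly
    results = run_dma(
        rcq, two_group_design, ["A", "B"], method=IRMRA_DMA, filter_table=two_group_table
    )
    assert {r.method for r in results} == {IRMRA_DMA}


def test_duplicate_groups_rejected(two_group_table, two_group_design):
    with pytest.raises(ConfigurationError, match="duplicate"):
        run_dma(two_group_table, two_group_design, ["A", "A"])


def test_bh_adjustment_monotone(two_group_table, two_group_design):
    raw = run_dma(two_group_table, two_group_design, ["A", "B"])
    adj = run_dma(
        two_group_table, two_group_design, ["A", "B"], config=ScreenConfig(mtc="bh")
    )
    for r_raw, r_adj in zip(raw, adj):
        assert r_adj.p_adjusted >= r_raw.p - 1e-15


def _kw_fixture():
    rng = np.random.default_rng(10)
    base = {g: rng.lognormal(0, 0.2, (4, 6)) for g in ("W", "H", "P")}
    # G0: planted wild-enriched (highest in W, significant)
    base["W"][0] *= 6
    # G1: strong signal but W is NOT the top group
    base["H"][1] *= 6
    return _table_design(base, taxa=[f"G{i}" for i in range(4)])


def test_wild_enriched_requires_top_rank_and_significance():
    table, design = _kw_fixture()
    results = run_dma(table, design, ["W", "H", "P"], reference="W")
    enriched = wild_enriched_set(results, "W", ["H", "P"])
    assert "G0" in enriched
    assert "G1" not in enriched  # significant but W not strictly highest
    insignificant = {r.genus for r in results if not r.significant}
    assert enriched.isdisjoint(insignificant)


def test_wild_enriched_target_cannot_be_comparator():
    table, design = _kw_fixture()
    results = run_dma(table, design, ["W", "H", "P"], reference="W")
    with pytest.raises(ConfigurationError, match="among the comparison groups"):
        wild_enriched_set(results, "W", ["W", "H"])


def test_results_frame_has_volcano_columns():
    table, design = _kw_fixture()
    frame = results_to_frame(run_dma(table, design, ["W", "H"], reference="W"))
    for col in ("log2_fc", "neg_log10_p", "p", "significant"):
        assert col in frame.columns
    assert len(frame) == 4
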