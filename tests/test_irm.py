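import numpy as np
import pytest

from irmdma import (
    apply_irm_threshold,
    irm_candidates,
    presence_profile,
    screen_irm,
    site_unique_genera,
    simulate_community,
    planted_signal,
)
from irmdma.errors import ConfigurationError, ValidationError

from conftest import make_design, make_table


def _one_group_design(n=3, group="G", site="x"):
    return make_design([(f"{group}{r}", site, "target", group, str(r)) for r in range(1, n + 1)])


def test_presence_profile_default_rule_any_detection():
    design = _one_group_design()
    table = make_table(
        [[0, 0, 0.01], [0, 0, 0], [100, 100, 99.99]],
        taxa=["A", "B", "C"],
        samples=design.samples,
    )
    prof = presence_profile(table, design, "G")
    assert prof["A"].present and prof["A"].prevalence == pytest.approx(1 / 3)
    assert not prof["B"].present and prof["B"].prevalence == 0
    assert prof["C"].present and prof["C"].prevalence == 1


def test_presence_profile_prevalence_rule():
    design = _one_group_design()
    table = make_table(
        [[0, 0, 0.01], [100, 100, 99.99]], taxa=["A", "C"], samples=design.samples
    )
    prof = presence_profile(table, design, "G", rule="prevalence:0.5")
    assert not prof["A"].present  # detected in only 1/3 samples
    assert prof["C"].present


def test_site_unique_genera_set_difference():
    design = _one_group_design()
    host = presence_profile(
        make_table([[1, 1, 1], [1, 1, 1], [98, 98, 98]], taxa=list("ABC"), samples=design.samples),
        design,
        "G",
    )
    comp = presence_profile(
        make_table([[0, 0, 0], [1, 1, 1], [99, 99, 99]], taxa=list("ABC"), samples=design.samples),
        design,
        "G",
    )
    assert site_unique_genera(host, comp) == {"A"}


def test_site_unique_genera_requires_same_universe():
    design = _one_group_design()
    host = presence_profile(
        make_table([[100, 100, 100]], taxa=["A"], samples=design.samples), design, "G"
    )
    comp = presence_profile(
        make_table([[100, 100, 100]], taxa=["B"], samples=design.samples), design, "G"
    )
    with pytest.raises(ValidationError, match="different taxa"):
        site_unique_genera(host, comp)


def test_irm_candidates_intersection():
    assert irm_candidates([{"X", "Y"}, {"Y", "Z"}, {"Y"}]) == {"Y"}
    assert irm_candidates([{"X"}, {"Y"}, {"Z"}]) == set()
    with pytest.raises(ConfigurationError, match=">= 2 sites"):
        irm_candidates([{"X"}])


def _three_group_fixture(means_by_group):
    """One candidate genus with given group means, plus a filler genus."""
    rows, samples, cols = [], [], []
    for g, (site, mean) in means_by_group.items():
        for r in range(1, 4):
            rows.append((f"{g}{r}", site, "target", g, str(r)))
            samples.append(f"{g}{r}")
            cols.append(mean)
    vals = np.array([cols, [100 - c for c in cols]])
    table = make_table(vals, taxa=["Cand", "Rest"], samples=samples)
    return table, make_design(rows)


def test_threshold_inclusive_pass_and_fail():
    # group means mirror a qualifying candidate (0.1147/0.0196/0.0087 >= 0.005 everywhere)
    table, design = _three_group_fixture(
        {"WFt": ("s1", 0.1147), "HFt": ("s2", 0.0196), "PFt": ("s3", 0.0087)}
    )
    (cand,) = apply_irm_threshold({"Cand"}, table, design, ["WFt", "HFt", "PFt"], 0.005)
    assert cand.passes_threshold

    # and a failing one (0.14834/0.00106/0.00042: two groups below 0.005)
    table, design = _three_group_fixture(
        {"WFt": ("s1", 0.14834), "HFt": ("s2", 0.00106), "PFt": ("s3", 0.00042)}
    )
    (cand,) = apply_irm_threshold({"Cand"}, table, design, ["WFt", "HFt", "PFt"], 0.005)
    assert not cand.passes_threshold


def test_threshold_boundary_is_inclusive():
    table, design = _three_group_fixture(
        {"WFt": ("s1", 0.005), "HFt": ("s2", 0.005), "PFt": ("s3", 0.005)}
    )
    (cand,) = apply_irm_threshold({"Cand"}, table, design, ["WFt", "HFt", "PFt"], 0.005)
    assert cand.passes_threshold


def test_screen_order_invariant_in_sites_and_samples():
    config = planted_signal(n_taxa=12)
    comm = simulate_community(config, seed=5)
    table = comm.percent_table
    cands = screen_irm(table, comm.design, 0.005)

    perm = list(table.samples)[::-1]
    shuffled = table.subset_samples(perm)
    cands_shuffled = screen_irm(shuffled, comm.design, 0.005)
    assert [c.genus for c in cands] == [c.genus for c in cands_shuffled]


def test_screen_recovers_planted_reference_taxon():
    config = planted_signal()
    comm = simulate_community(config, seed=11)
    cands = screen_irm(comm.percent_table, comm.design, 0.005)
    passing = [c.genus for c in cands if c.passes_threshold]
    assert passing == [config.irm_genus]
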