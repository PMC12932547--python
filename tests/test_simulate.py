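import numpy as np
import pytest

from irmdma import (
    GroupSpec,
    ScenarioConfig,
    TaxonEffect,
    null_load_shift,
    planted_signal,
    run_benchmark,
    scenario_from_dict,
    simulate_community,
)
from irmdma.errors import ConfigurationError


def _plain_config(**overrides):
    kwargs = dict(
        n_taxa=10,
        groups=(
            GroupSpec("A", "s1", "target", 4),
            GroupSpec("B", "s2", "target", 4),
        ),
        irm_taxon=0,
        irm_levels={"A": 1.0, "B": 1.0},
        depth=10_000,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def test_fixed_seed_is_bit_identical():
    config = _plain_config()
    c1 = simulate_community(config, seed=123)
    c2 = simulate_community(config, seed=123)
    assert (c1.counts.to_numpy() == c2.counts.to_numpy()).all()
    assert (c1.absolute.to_numpy() == c2.absolute.to_numpy()).all()


def test_closure_counts_sum_to_depth_percent_to_100():
    comm = simulate_community(null_load_shift(n_taxa=30), seed=1)
    assert (comm.counts.sum(axis=0) == comm.config.depth).all()
    np.testing.assert_allclose(comm.percent_table.data.sum(axis=0), 100.0, atol=1e-6)


def test_null_scenario_all_truth_flags_false():
    comm = simulate_community(_plain_config(), seed=2)
    assert comm.truth_differential("A", "B") == set()


def test_bloomer_shifts_load_but_not_absolute_abundances():
    config = _plain_config(
        bloomers=(TaxonEffect(1, "B", 20.0),),
        baseline_override={1: 5.0},
    )
    comm = simulate_community(config, seed=3)
    load_a = comm.total_load[comm.design.samples_in_group("A")].mean()
    load_b = comm.total_load[comm.design.samples_in_group("B")].mean()
    assert load_b > 5 * load_a  # bloom dominates total load

    # a non-bloomer taxon: unchanged absolute level, depressed percent in B
    abs_a = comm.absolute.loc["g002", comm.design.samples_in_group("A")].mean()
    abs_b = comm.absolute.loc["g002", comm.design.samples_in_group("B")].mean()
    assert abs_b == pytest.approx(abs_a, rel=1.0)  # same order: no planted effect
    pct = comm.percent_table.data
    pct_a = pct.loc["g002", comm.design.samples_in_group("A")].mean()
    pct_b = pct.loc["g002", comm.design.samples_in_group("B")].mean()
    assert pct_b < 0.5 * pct_a

    assert comm.truth_differential("A", "B") == {"g001"}


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError, match="taxa"):
        _plain_config(n_taxa=1)
    with pytest.raises(ConfigurationError, match="depth"):
        _plain_config(depth=0)
    with pytest.raises(ConfigurationError, match="fold"):
        _plain_config(differential=(TaxonEffect(2, "A", 0.0),))
    with pytest.raises(ConfigurationError, match="IRM level"):
        _plain_config(irm_levels={"A": 1.0})  # target group B lacks a level


def test_scenario_from_dict_builtin_and_explicit():
    cfg = scenario_from_dict({"builtin": "planted_signal", "n_taxa": 20})
    assert cfg.n_taxa == 20 and cfg.label == "planted_signal"
    cfg = scenario_from_dict(
        {
            "n_taxa": 5,
            "groups": [
                {"name": "A", "site": "s", "role": "target", "n_samples": 3},
                {"name": "B", "site": "t", "role": "target", "n_samples": 3},
            ],
            "irm_taxon": 0,
            "irm_levels": {"A": 1.0, "B": 1.0},
        }
    )
    assert cfg.taxon_name(0) == "g000"
    with pytest.raises(ConfigurationError, match="unknown builtin"):
        scenario_from_dict({"builtin": "nope"})


def test_benchmark_tiny_alpha_rejects_nothing():
    config = _plain_config(differential=(TaxonEffect(2, "A", 4.0),))
    result = run_benchmark(config, seed=5, n_reps=1, alpha=1e-12)
    assert (result.summary["fpr"] == 0).all()
    assert (result.summary["tpr"] == 0).all()


def test_benchmark_recovers_planted_signal():
    config = planted_signal(n_taxa=20, n_planted=3)
    result = run_benchmark(config, seed=6, n_reps=2)
    assert (result.summary["tpr"] > 0).all()
    assert result.per_rep.shape[0] == 4  # 2 reps x 2 methods
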