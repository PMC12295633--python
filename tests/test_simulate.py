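"""Synthetic generators: determinism and plant/recover fidelity."""
import numpy as np
import pandas as pd
import pytest

from herbnet.adme import filter_ingredients
from herbnet.config import PipelineConfig
from herbnet.rescue import analyse_study
from herbnet.simulate import (
    SyntheticTruth,
    gen_behavior_trials,
    gen_compound_target_map,
    gen_expression_matrix,
    gen_herb_ingredient_table,
    gen_ppi_edges,
    plant_expression_truth,
)


def test_truth_invariants_enforced():
    with pytest.raises(ValueError, match="subset"):
        SyntheticTruth(planted_altered={"g1": "up"},
                       planted_rescued=frozenset({"g2"}))
    with pytest.raises(ValueError, match="noise_sd"):
        SyntheticTruth(noise_sd=-0.1)


def test_herb_table_paper_scale_structure(config):
    overlap = [(f"s{i}", ("EH", "GR") if i < 10 else ("EH", "AS"))
               for i in range(11)]
    records, truth = gen_herb_ingredient_table(
        {"EH": 24, "AS": 20, "GR": 102}, overlap, 1.0, seed=2)
    assert len(records) == 146
    assert len({r.ingredient for r in records}) == 135
    result = filter_ingredients(records, config)
    assert len(result.unique_ingredients) == 135
    assert len(result.overlap) == 11


def test_herb_table_trivial_and_pass_plant(config):
    records, _ = gen_herb_ingredient_table({"A": 2}, [], 1.0, seed=0)
    assert len(records) == 2 and len({r.ingredient for r in records}) == 2
    records, _ = gen_herb_ingredient_table({"A": 100}, [], 0.5, seed=1)
    result = filter_ingredients(records, config)
    assert len(result.passing["A"]) == 50


def test_shared_ingredient_has_identical_adme_values():
    records, _ = gen_herb_ingredient_table(
        {"A": 5, "B": 5}, [("sh", ("A", "B"))], 1.0, seed=3)
    rows = [r for r in records if r.ingredient == "sh"]
    assert len(rows) == 2
    assert (rows[0].ob, rows[0].dl, rows[0].caco2) == \
        (rows[1].ob, rows[1].dl, rows[1].caco2)


def test_overlap_referencing_unknown_herb_rejected():
    with pytest.raises(ValueError, match="unknown herb"):
        gen_herb_ingredient_table({"A": 3}, [("x", ("A", "Z"))], 1.0, seed=0)


def test_generators_are_deterministic():
    args = ({"EH": 10, "AS": 8}, [("s", ("EH", "AS"))], 0.8)
    a, _ = gen_herb_ingredient_table(*args, seed=42)
    b, _ = gen_herb_ingredient_table(*args, seed=42)
    assert a == b
    e1 = gen_ppi_edges(["A", "B", "C", "D"], {"A": 3}, 0.5, seed=42)
    e2 = gen_ppi_edges(["A", "B", "C", "D"], {"A": 3}, 0.5, seed=42)
    pd.testing.assert_frame_equal(e1, e2)
    t = plant_expression_truth(20, 3, 3, 0.5, seed=42)
    pd.testing.assert_frame_equal(
        gen_expression_matrix(20, 3, t).values,
        gen_expression_matrix(20, 3, t).values,
    )


def test_compound_map_pair_count():
    ctmap = gen_compound_target_map(
        ["a", "b", "c"], 10, {"a": 5, "b": 3, "c": 1}, seed=0)
    assert len(ctmap.pairs) == 9
    assert len(ctmap.targets) <= 10


def test_noiseless_plant_recovered_exactly(config):
    truth = plant_expression_truth(40, 6, 4, 0.5, noise_sd=0.0, seed=17)
    report = analyse_study(gen_expression_matrix(40, 2, truth), config)
    directions = report.per_gene["direction"]
    for gene in report.per_gene.index:
        assert directions[gene] == truth.planted_altered.get(gene, "unchanged")
    rescued = set(report.per_gene.index[report.per_gene["rescued"] == True])  # noqa: E712
    assert rescued == set(truth.planted_rescued)
    assert report.summary()["overall_rescue_pct"] == 50


def test_empty_plant_reports_zero_altered(config):
    truth = plant_expression_truth(15, 0, 0, 0.0, seed=1)
    report = analyse_study(gen_expression_matrix(15, 3, truth), config)
    assert report.n_altered == 0


def test_expression_values_positive_with_noise():
    truth = plant_expression_truth(30, 5, 5, 0.5, noise_sd=0.5, seed=9)
    study = gen_expression_matrix(30, 4, truth)
    assert (study.values.to_numpy() > 0).all()


def test_expression_rejects_bad_sizes():
    truth = plant_expression_truth(10, 2, 2, 0.5, seed=0)
    with pytest.raises(ValueError, match="n_per_group"):
        gen_expression_matrix(10, 0, truth)
    with pytest.raises(ValueError, match="universe"):
        gen_expression_matrix(3, 2, truth)


def test_behavior_trivial_plants():
    trials = gen_behavior_trials(
        5, {"g": (1.0, 100.0, 0.0)}, seed=6)
    g = trials["g"]
    from herbnet.behavior import discrimination_ratio, spontaneous_alternation

    assert all(spontaneous_alternation(t) == 100.0 for t in g.maze)
    assert all(discrimination_ratio(t) == 100.0 for t in g.objects)
    assert all(t.closed_entries == 0 for t in g.epm)


def test_discrimination_ratio_law_of_large_numbers():
    trials = gen_behavior_trials(1000, {"g": (0.5, 50.0, 5.0)}, seed=8)
    from herbnet.behavior import discrimination_ratio

    drs = [discrimination_ratio(t) for t in trials["g"].objects]
    assert np.mean(drs) == pytest.approx(50.0, abs=1.5)


def test_behavior_rejects_bad_probability():
    with pytest.raises(ValueError, match="alternation_p"):
        gen_behavior_trials(3, {"g": (1.5, 50.0, 5.0)}, seed=0)
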