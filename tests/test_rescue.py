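"""Fold-ratio computation, alteration/rescue classification, clustering."""
import itertools

import numpy as np
import pandas as pd
import pytest

from herbnet.config import PipelineConfig
from herbnet.rescue import (
    ExpressionStudy,
    analyse_study,
    classify_altered,
    classify_rescue,
    cluster_heatmap_export,
    compute_ratios,
)
from herbnet.simulate import gen_expression_matrix, plant_expression_truth


def make_study(baseline, model, treated, n_rep=2):
    """Build a study with exact group means and zero within-group spread."""
    genes = [f"g{i}" for i in range(len(baseline))]
    data, cols, groups = [], [], {}
    for role, means in (("baseline", baseline), ("model", model),
                        ("treated", treated)):
        for j in range(n_rep):
            cols.append(f"{role}_{j}")
            groups[f"{role}_{j}"] = role
        data.append(np.tile(np.asarray(means, float)[:, None], (1, n_rep)))
    return ExpressionStudy(
        values=pd.DataFrame(np.hstack(data), index=genes, columns=cols),
        groups=groups,
    )


def test_identical_groups_give_unit_ratio(config):
    study = make_study([10, 100], [10, 100], [10, 100])
    ratios = compute_ratios(study, config)
    assert np.allclose(ratios["model_ratio"], 1.0)
    assert np.allclose(ratios["treated_ratio"], 1.0)


def test_fourfold_ratio_without_pseudocount():
    cfg = PipelineConfig(pseudocount=0.0)
    ratios = compute_ratios(make_study([10], [40], [10]), cfg)
    assert ratios["model_ratio"].iloc[0] == pytest.approx(4.0)


def test_zero_baseline_without_pseudocount_errors():
    cfg = PipelineConfig(pseudocount=0.0)
    with pytest.raises(ValueError, match="pseudocount"):
        compute_ratios(make_study([0.0], [5.0], [5.0]), cfg)


def test_noiseless_ratios_equal_planted_fold():
    cfg = PipelineConfig(pseudocount=0.0)
    truth = plant_expression_truth(30, 5, 5, 0.5, effect_fold=8.0,
                                   noise_sd=0.0, seed=13)
    study = gen_expression_matrix(30, 3, truth)
    ratios = compute_ratios(study, cfg)
    for gene, direction in truth.planted_altered.items():
        expected = 8.0 if direction == "up" else 0.125
        assert ratios.loc[gene, "model_ratio"] == pytest.approx(expected)


@pytest.mark.parametrize(
    "ratio,direction",
    [
        (4.0, "up"),         # inclusive up bound
        (4.0001, "up"),
        (3.9999, "unchanged"),
        (0.25, "unchanged"),  # strict down bound
        (0.2499, "down"),
        (1.0, "unchanged"),
    ],
)
def test_alteration_boundary_semantics(config, ratio, direction):
    calls = classify_altered(pd.Series([ratio], index=["g"]), config)
    assert calls["g"] == direction


def test_classification_matches_bruteforce(config, rng):
    ratios = pd.Series(
        10.0 ** rng.uniform(-2, 2, size=1000),
        index=[f"g{i}" for i in range(1000)],
    )
    calls = classify_altered(ratios, config)
    for gene, r in ratios.items():
        expected = "up" if r >= 4.0 else ("down" if r < 0.25 else "unchanged")
        assert calls[gene] == expected


def test_nonpositive_ratio_rejected(config):
    with pytest.raises(ValueError):
        classify_altered(pd.Series([0.0]), config)


def test_treated_at_baseline_rescues_everything(config):
    study = make_study([10, 10, 10], [80, 1.0, 10], [10, 10, 10])
    report = analyse_study(study, config)
    assert report.n_altered == 2
    assert report.n_rescued == 2


def test_treated_at_model_rescues_nothing(config):
    study = make_study([10, 10], [80, 1.0], [80, 1.0])
    report = analyse_study(study, config)
    assert report.n_altered == 2 and report.n_rescued == 0


def test_treated_ratio_exactly_four_is_not_rescued(config):
    cfg = PipelineConfig(pseudocount=0.0)
    ratios = pd.DataFrame(
        {"model_ratio": [4.0], "treated_ratio": [4.0]}, index=["g"]
    )
    report = classify_rescue(ratios, cfg)
    assert report.n_up == 1 and report.n_rescued == 0


def test_zero_altered_genes_reports_undefined(config):
    report = analyse_study(make_study([10], [11], [10]), config)
    assert report.n_altered == 0
    assert report.overall_rescue_pct is None
    assert report.summary()["overall_rescue_pct"] is None


def test_rescued_subset_of_altered(config, rng):
    ratios = pd.DataFrame(
        {
            "model_ratio": 10.0 ** rng.uniform(-2, 2, size=300),
            "treated_ratio": 10.0 ** rng.uniform(-2, 2, size=300),
        },
        index=[f"g{i}" for i in range(300)],
    )
    report = classify_rescue(ratios, config)
    rescued = set(report.per_gene.index[report.per_gene["rescued"] == True])  # noqa: E712
    altered = set(
        report.per_gene.index[report.per_gene["direction"] != "unchanged"]
    )
    assert rescued <= altered
    for pct in (report.up_rescue_pct, report.down_rescue_pct,
                report.overall_rescue_pct):
        assert pct is None or 0 <= pct <= 100


def test_scale_invariance_of_all_calls(rng):
    cfg = PipelineConfig(pseudocount=0.0)
    truth = plant_expression_truth(50, 8, 8, 0.5, noise_sd=0.2, seed=21)
    study = gen_expression_matrix(50, 4, truth)
    scaled = ExpressionStudy(values=study.values * 1234.5,
                             groups=dict(study.groups))
    a = analyse_study(study, cfg).per_gene
    b = analyse_study(scaled, cfg).per_gene
    assert (a["direction"] == b["direction"]).all()
    assert a["rescued"].equals(b["rescued"])
    assert np.allclose(a["model_ratio"], b["model_ratio"])


def test_widening_rescue_window_never_loses_rescues(config, rng):
    ratios = pd.DataFrame(
        {
            "model_ratio": 10.0 ** rng.uniform(-2, 2, size=400),
            "treated_ratio": 10.0 ** rng.uniform(-2, 2, size=400),
        },
        index=[f"g{i}" for i in range(400)],
    )
    narrow = PipelineConfig(rescue_lower=0.2, rescue_upper=2.0)
    wide = PipelineConfig(rescue_lower=0.05, rescue_upper=4.0)
    assert classify_rescue(ratios, narrow).n_rescued <= \
        classify_rescue(ratios, wide).n_rescued


# --------------------------------------------------------------------------
# Hierarchical clustering export


def naive_average_linkage(points):
    """Greedy agglomerative average linkage, independent of scipy.

    Returns the merge history as a list of leaf-index frozensets and the
    cophenetic distance for every leaf pair.
    """
    points = np.asarray(points, float)
    clusters = {i: frozenset([i]) for i in range(len(points))}
    coph = {}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            ])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        for i in clusters[a]:
            for j in clusters[b]:
                coph[frozenset((i, j))] = d
        del clusters[a], clusters[b]
        clusters[len(points) + len(merges)] = merged
        merges.append(merged)
    return merges, coph


def test_identical_profiles_adjacent(config):
    study = make_study(
        [10, 10, 10, 10], [80, 20, 80, 1.0], [10, 40, 10, 10])
    report = analyse_study(study, config)
    ordered = cluster_heatmap_export(study, report)
    order = list(ordered.index)
    assert abs(order.index("g0") - order.index("g2")) == 1


def test_log2_of_unit_ratio_is_zero():
    cfg = PipelineConfig(pseudocount=0.0)
    study = make_study([10, 10], [80, 80], [10, 10])
    report = analyse_study(study, cfg)
    ordered = cluster_heatmap_export(study, report)
    assert np.allclose(ordered["log2_treated_ratio"], 0.0)
    assert np.allclose(ordered["log2_model_ratio"], 3.0)


def test_fewer_than_two_altered_passthrough(config):
    study = make_study([10, 10], [80, 11], [10, 10])
    report = analyse_study(study, config)
    ordered = cluster_heatmap_export(study, report)
    assert list(ordered.index) == ["g0"]


def test_cluster_order_agrees_with_naive_linkage(config, rng):
    """Every merged cluster is contiguous in the exported leaf order, and
    scipy's cophenetic structure matches the naive implementation."""
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import pdist, squareform

    base = [10.0] * 10
    model = list(10.0 ** rng.uniform(0.7, 1.5, size=10) * 10)  # all >=4x up
    treated = list(10.0 ** rng.uniform(-0.5, 0.5, size=10) * 10)
    cfg = PipelineConfig(pseudocount=0.0)
    study = make_study(base, model, treated)
    report = analyse_study(study, cfg)
    assert report.n_altered == 10
    ordered = cluster_heatmap_export(study, report)

    altered = report.per_gene[report.per_gene["direction"] != "unchanged"]
    log2 = np.log2(altered[["model_ratio", "treated_ratio"]].to_numpy())
    merges, naive_coph = naive_average_linkage(log2)

    gene_pos = {g: i for i, g in enumerate(ordered.index)}
    altered_genes = list(altered.index)
    for cluster in merges:
        positions = sorted(gene_pos[altered_genes[i]] for i in cluster)
        assert positions == list(range(positions[0], positions[-1] + 1))

    scipy_coph = squareform(cophenet(average(pdist(log2))))
    for i in range(10):
        for j in range(i + 1, 10):
            assert scipy_coph[i, j] == pytest.approx(
                naive_coph[frozenset((i, j))])
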