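"""Module PCA, gene ranking scores, filtering and panel assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from panelign import prioritization as pr
from panelign import synthetic_data as sd
from panelign.errors import ContractError, InsufficientDataError
from panelign.io_model import CoexpressionModule, OrthologyTable

from conftest import make_expression


def _module(genes, module_id="m1"):
    return CoexpressionModule(module_id=module_id, cohort="Mayo",
                              brain_region="TCX", consensus_cluster="A",
                              members=frozenset(genes))


def _orth(mapping, dn=0.1, ds=1.0):
    return OrthologyTable(pd.DataFrame(
        {"human_gene": list(mapping), "mouse_gene": list(mapping.values()),
         "dn": dn, "ds": ds}))


def test_rank_one_module_puts_all_variance_on_pc1():
    base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 0.0, 2.5])
    X = np.vstack([base, base, base, base])
    expr = make_expression(X, [f"g{i}" for i in range(4)],
                           [f"s{i}" for i in range(8)])
    mod = _module([f"g{i}" for i in range(4)])
    pca = pr.module_pca(expr, mod)
    assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(pca.variance_fractions[1:], 0.0, atol=1e-12)
    scores = pr.gene_ranking_scores(expr, pca, mod)
    assert all(s.score == pytest.approx(1.0, abs=1e-10) for s in scores)


def test_variance_fractions_match_svd_oracle():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(6, 8))
    expr = make_expression(X, [f"g{i}" for i in range(6)],
                           [f"s{i}" for i in range(8)])
    mod = _module([f"g{i}" for i in range(6)])
    pca = pr.module_pca(expr, mod)
    # oracle: full SVD of the standardized samples x genes submatrix
    Z = (X.T - X.T.mean(axis=0)) / X.T.std(axis=0, ddof=1)
    s = np.linalg.svd(Z, compute_uv=False)
    ve_oracle = (s**2 / (Z.shape[0] - 1)) / Z.shape[1]
    assert np.allclose(pca.variance_fractions, ve_oracle[:5], atol=1e-8)


def test_gene_scores_match_brute_force_oracle():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(6, 8))
    genes = [f"g{i}" for i in range(6)]
    expr = make_expression(X, genes, [f"s{i}" for i in range(8)])
    mod = _module(genes)
    pca = pr.module_pca(expr, mod)
    scores = {gs.gene: gs.score
              for gs in pr.gene_ranking_scores(expr, pca, mod)}
    for gi, g in enumerate(genes):
        r = [np.corrcoef(X[gi], pca.component_scores[:, k])[0, 1]
             for k in range(5)]
        expected = abs(sum(rk * vk for rk, vk
                           in zip(r, pca.variance_fractions)))
        assert scores[g] == pytest.approx(expected, abs=1e-8)


def test_sum_of_abs_variant_bounds_abs_of_sum():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(6, 10))
    genes = [f"g{i}" for i in range(6)]
    expr = make_expression(X, genes, [f"s{i}" for i in range(10)])
    mod = _module(genes)
    pca = pr.module_pca(expr, mod)
    a = {s.gene: s.score for s in pr.gene_ranking_scores(expr, pca, mod)}
    b = {s.gene: s.score for s in pr.gene_ranking_scores(
        expr, pca, mod, variant="sum-of-abs")}
    for g in genes:
        assert b[g] >= a[g] - 1e-12


def test_constant_gene_scores_zero():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(4, 8))
    X[2] = 3.0
    genes = [f"g{i}" for i in range(4)]
    expr = make_expression(X, genes, [f"s{i}" for i in range(8)])
    mod = _module(genes)
    pca = pr.module_pca(expr, mod)
    scores = {s.gene: s.score for s in pr.gene_ranking_scores(expr, pca, mod)}
    assert scores["g2"] == 0.0


def test_score_bound_and_scale_invariance():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 12))
    genes = [f"g{i}" for i in range(8)]
    expr = make_expression(X, genes, [f"s{i}" for i in range(12)])
    mod = _module(genes)
    pca = pr.module_pca(expr, mod)
    scores = pr.gene_ranking_scores(expr, pca, mod)
    bound = pca.variance_fractions.sum()
    assert all(0 <= s.score <= bound + 1e-12 for s in scores)
    # positive rescaling of the module leaves scores unchanged
    expr2 = make_expression(X * 17.0, genes, [f"s{i}" for i in range(12)])
    pca2 = pr.module_pca(expr2, mod)
    scores2 = pr.gene_ranking_scores(expr2, pca2, mod)
    assert np.allclose([s.score for s in scores],
                       [s.score for s in scores2], atol=1e-9)


def test_module_pca_error_cases():
    expr = make_expression(np.random.default_rng(0).normal(size=(1, 8)),
                           ["g0"], [f"s{i}" for i in range(8)])
    with pytest.raises(InsufficientDataError):
        pr.module_pca(expr, _module(["g0"]))
    X = np.ones((3, 8))
    expr = make_expression(X, ["g0", "g1", "g2"],
                           [f"s{i}" for i in range(8)])
    from panelign.errors import DegenerateInputError
    with pytest.raises(DegenerateInputError):
        pr.module_pca(expr, _module(["g0", "g1", "g2"]))


def test_mismatched_module_ids_rejected():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(3, 8))
    genes = ["g0", "g1", "g2"]
    expr = make_expression(X, genes, [f"s{i}" for i in range(8)])
    pca = pr.module_pca(expr, _module(genes, "m1"))
    with pytest.raises(ContractError):
        pr.gene_ranking_scores(expr, pca, _module(genes, "other"))


def test_filter_candidates_by_orthology_and_expression():
    scores = [pr.GeneScore(f"h{i}", "m1", 1.0 - i / 10) for i in range(10)]
    orth = _orth({f"h{i}": f"Mg{i}" for i in range(7)})  # h7..h9 no ortholog
    tpm = np.array([[5.0], [5.0], [0.2], [5.0], [0.2], [5.0], [5.0]])
    mouse = make_expression(np.tile(tpm, (1, 3)),
                            [f"Mg{i}" for i in range(7)],
                            ["b1", "b2", "b3"], unit="tpm")
    kept = pr.filter_candidates(scores, orth, mouse, tpm_threshold=1.0)
    assert [g.gene for g in kept] == ["h0", "h1", "h3", "h5", "h6"]


@pytest.mark.parametrize("n,frac,expected", [
    (200, 0.05, 10),   # the 5% selection rule
    (10, 0.05, 1),     # ceiling rule keeps small modules represented
    (0, 0.05, 0),
    (7, 1.0, 7),
])
def test_select_top_fraction_counts(n, frac, expected):
    scores = [pr.GeneScore(f"g{i:03d}", "m1", 1.0 - i / (n + 1))
              for i in range(n)]
    sel = pr.select_top_fraction(scores, frac)
    assert len(sel) == expected
    assert sel == [f"g{i:03d}" for i in range(expected)]


def test_select_top_fraction_rejects_bad_fraction():
    with pytest.raises(ContractError):
        pr.select_top_fraction([], 0.0)
    with pytest.raises(ContractError):
        pr.select_top_fraction([], 1.5)


def test_assemble_panel_merges_multi_module_genes():
    orth = _orth({"h1": "Mg1", "h2": "Mg2"})
    panel, report = pr.assemble_panel(
        {"m1": ["h1"], "m2": ["h1"], "m3": ["h1", "h2"]}, orth,
        housekeeping=["Hk1"], drug_targets=[], capacity=100)
    entry = panel.entry_for("Mg1")
    assert entry.annotated_modules == {"m1", "m2", "m3"}
    assert len(panel.entries) == 3  # Mg1, Mg2, Hk1


def test_assemble_panel_housekeeping_only():
    orth = _orth({})
    hk = [f"Hk{i}" for i in range(10)]
    panel, _ = pr.assemble_panel({}, orth, hk, [], capacity=770)
    assert len(panel.entries) == 10
    assert all(e.category == "housekeeping" for e in panel.entries)


def test_assemble_panel_truncates_lowest_score_first():
    n = 900
    orth = _orth({f"h{i:04d}": f"Mg{i:04d}" for i in range(n)})
    selections = {"m1": [f"h{i:04d}" for i in range(n)]}
    scores = {("m1", f"h{i:04d}"): 1.0 - i / n for i in range(n)}
    hk = [f"Hk{i}" for i in range(10)]
    panel, report = pr.assemble_panel(selections, orth, hk, [], capacity=770,
                                      scores=scores)
    assert len(panel.entries) == 770
    assert any("truncated" in line for line in report)
    kept_keys = {e.mouse_gene for e in panel.entries if e.category == "key"}
    # highest-scoring 760 key genes survive
    assert kept_keys == {f"Mg{i:04d}" for i in range(760)}


def test_assemble_panel_collision_keeps_housekeeping():
    orth = _orth({"h1": "Hk1"})
    panel, report = pr.assemble_panel({"m1": ["h1"]}, orth, ["Hk1"], [],
                                      capacity=10)
    assert panel.entry_for("Hk1").category == "housekeeping"
    assert any("collision" in line for line in report)


def test_assemble_panel_capacity_contract():
    orth = _orth({})
    with pytest.raises(ContractError):
        pr.assemble_panel({}, orth, [f"Hk{i}" for i in range(10)],
                          [f"D{i}" for i in range(5)], capacity=12)


def test_module_probe_coverage_matches_membership_tally(small_sim):
    modules = small_sim["modules"][:5]
    orth = small_sim["orthology"]
    entries = []
    rng = np.random.default_rng(5)
    for mod in modules:
        for hg in sorted(mod.members)[:8]:
            mg = orth.mouse_for(hg)
            if mg is None or any(e.mouse_gene == mg for e in entries):
                continue
            entries.append(
                __import__("panelign.io_model", fromlist=["PanelEntry"])
                .PanelEntry(mg, "key", frozenset({mod.module_id})))
    panel = __import__("panelign.io_model", fromlist=["PanelDefinition"]) \
        .PanelDefinition(entries=entries, capacity=770)
    cov = pr.module_probe_coverage(panel, modules, orth)
    for mod in modules:
        expected = sum(1 for e in entries
                       if mod.module_id in e.annotated_modules)
        row = cov[cov.module_id == mod.module_id].iloc[0]
        assert row.probe_count == expected
        assert row.coverage_fraction == pytest.approx(expected / mod.size)


def test_planted_high_loading_genes_recovered_over_seeds():
    """Top-fraction selection recovers >= 90% of planted high-loading genes."""
    recovered = total = 0
    for seed in range(20):
        cfg = sd.SimulationConfig(
            seed=seed, n_modules=2, module_sizes=[100, 100],
            strong_fraction=0.05, loading_high=0.95, loading_low=0.0,
            noise_sd=0.4, n_case=40, n_control=40)
        modules, _ = sd.simulate_modules(cfg)
        expr, _ = sd.simulate_human_cohort(modules, cfg)
        planted = sd.strong_genes(modules, cfg)
        for mod in modules:
            pca = pr.module_pca(expr, mod)
            scores = pr.gene_ranking_scores(expr, pca, mod)
            sel = set(pr.select_top_fraction(scores, 0.05))
            recovered += len(sel & set(planted[mod.module_id]))
            total += len(planted[mod.module_id])
    assert recovered / total >= 0.9
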