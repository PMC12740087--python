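"""Generators: distributional correctness, planted structure, determinism,
and writer/reader round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from climbmet import io, synthetic as syn


def _single_fraction_spec(alpha, beta, n, entry=0.0, seed=0, censor=0.0):
    return syn.CohortSpec(
        n_flies=n, fraction_probs=(0, 0, 1, 0, 0),
        alpha_by_fraction=(1, 1, alpha, 1, 1),
        beta_by_fraction=(0, 0, beta, 0, 0),
        entry_age_days=entry, censor_prob=censor, seed=seed)


def test_exponential_limit_mean():
    rec = syn.simulate_lifespans(_single_fraction_spec(0.02, 0.0, 100_000, seed=1))
    assert abs(rec["exit_age"].mean() - 50.0) / 50.0 < 0.02


def test_gompertz_survivorship_matches_closed_form():
    alpha, beta = 1e-3, 0.1
    rec = syn.simulate_lifespans(_single_fraction_spec(alpha, beta, 100_000, seed=2))
    t = rec["exit_age"].to_numpy()
    for x in (20.0, 40.0, 60.0):
        s_emp = (t > x).mean()
        s_true = np.exp(-(alpha / beta) * (np.exp(beta * x) - 1.0))
        assert abs(s_emp - s_true) < 0.01


def test_gompertz_sampler_ks_distance():
    alpha, beta = 1e-3, 0.1
    rec = syn.simulate_lifespans(_single_fraction_spec(alpha, beta, 100_000, seed=3))

    def cdf(x):
        return 1.0 - np.exp(-(alpha / beta) * (np.exp(beta * np.asarray(x)) - 1.0))

    d, _ = stats.kstest(rec["exit_age"], cdf)
    assert d < 0.01


def test_entry_age_conditioning():
    rec = syn.simulate_lifespans(_single_fraction_spec(1e-3, 0.1, 5000, entry=29.0, seed=4))
    assert (rec["exit_age"] > 29.0).all()
    assert (rec["entry_age"] == 29.0).all()


def test_lifespan_determinism_and_censoring():
    spec = syn.CohortSpec(n_flies=500, censor_prob=0.05, seed=11)
    a = syn.simulate_lifespans(spec)
    b = syn.simulate_lifespans(spec)
    pd.testing.assert_frame_equal(a, b)
    assert (a["event"] == 0).any()
    assert (a.loc[a["event"] == 0, "exit_age"] <= a["exit_age"].max()).all()


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        syn.CohortSpec(fraction_probs=(0.3, 0.3, 0.3, 0.05, 0.06))
    with pytest.raises(ValueError):
        syn.CohortSpec(alpha_by_fraction=(0, 1, 1, 1, 1))
    with pytest.raises(ValueError):
        syn.CohortSpec(beta_by_fraction=(-0.1, 0, 0, 0, 0))


# --- metabolome -----------------------------------------------------------


def test_null_planted_pairs_uncorrelated():
    pairs = [(0, 1, (0.0,) * 5), (2, 3, (0.0,) * 5)]
    spec = syn.MetabolomeSpec(n_samples=10_000, n_metabolites=6, n_batches=1,
                              planted_pairs=pairs, seed=5)
    mat, meta = syn.simulate_metabolome(spec)
    for i, k, _ in pairs:
        r = np.corrcoef(mat.iloc[:, i], mat.iloc[:, k])[0, 1]
        assert abs(r) < 0.05


def test_planted_fraction_dependent_correlation():
    rho = (0.8, 0.8, 0.8, 0.0, 0.0)
    spec = syn.MetabolomeSpec(n_samples=2500, n_metabolites=4, n_batches=1,
                              planted_pairs=[(0, 1, rho)], seed=6)
    mat, meta = syn.simulate_metabolome(spec)
    frac = meta["fraction"].to_numpy()
    for f, target in ((0, 0.8), (4, 0.0)):
        sub = mat.loc[frac == f]
        r = np.corrcoef(sub.iloc[:, 0], sub.iloc[:, 1])[0, 1]
        assert abs(r - target) < 0.05, (f, r)


def test_planted_batch_shifts_recovered():
    spec = syn.MetabolomeSpec(n_samples=60, n_metabolites=30, n_batches=3,
                              batch_shifts=(0.0, 2.0, -2.0), noise_sd=1.0, seed=7)
    mat, meta = syn.simulate_metabolome(spec)
    means = mat.mean(axis=1).groupby(meta["batch"]).mean()
    n_per = meta["batch"].value_counts()
    for b, shift in enumerate([0.0, 2.0, -2.0]):
        se = 3.0 / np.sqrt(n_per[b] * 30)  # generous pooled-SE bound
        assert abs((means[b] - means[0]) - (shift - 0.0)) < 3 * se + 0.2


def test_duplicate_planted_pair_rejected():
    with pytest.raises(ValueError, match="twice"):
        syn.MetabolomeSpec(planted_pairs=[(1, 2, (0,) * 5), (2, 1, (0,) * 5)])


def test_metabolome_metadata_structure():
    mat, meta = syn.simulate_metabolome(syn.default_metabolome_spec(seed=8))
    assert len(mat) == 71
    assert set(meta["age_week"]) == {4, 6}
    assert set(meta["fraction"]) == set(range(5))
    assert meta.groupby("batch")["run_order"].apply(
        lambda s: s.is_unique).all()


# --- graph ----------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_graph_no_metabolite_edges_and_counts(seed):
    spec = syn.GraphSpec(seed=seed)
    g = syn.simulate_hetero_graph(spec)
    counts = g.class_counts()
    assert counts == {"metabolite": 40, "reaction": 60, "enzyme": 15,
                      "pathway": 8, "module": 5}
    for u, v in g.g.edges:
        assert not (g.klass(u) == "metabolite" and g.klass(v) == "metabolite")


def test_graph_connectivity_invariant():
    import networkx as nx

    g = syn.simulate_hetero_graph(syn.GraphSpec(seed=3))
    comp = max(nx.connected_components(g.g), key=len)
    frac_in = sum(1 for m in g.metabolites if m in comp) / len(g.metabolites)
    assert frac_in >= 0.9


def test_graph_determinism():
    a = syn.simulate_hetero_graph(syn.GraphSpec(seed=4))
    b = syn.simulate_hetero_graph(syn.GraphSpec(seed=4))
    assert set(a.g.edges) == set(b.g.edges)


def test_graph_spec_rejects_unwirable_densities():
    with pytest.raises(ValueError):
        syn.GraphSpec(reaction_metabolites=1.0)


# --- bang assay -----------------------------------------------------------


def test_bang_assay_degenerate_and_mean():
    hi = syn.simulate_bang_assay(p_by_fraction=(0.999999,) * 5, n_vials=3, seed=1)
    v = hi[hi["treatment"] == "vortex"]
    assert (v["n_alive_24h"] == v["n_flies"]).all()

    big = syn.simulate_bang_assay(p_by_fraction=(0.69,) * 5, n_vials=1000,
                                  flies_per_vial=25, seed=2)
    v = big[big["treatment"] == "vortex"]
    pooled = v["n_alive_24h"].sum() / v["n_flies"].sum()
    assert abs(pooled - 0.69) < 0.01


def test_bang_assay_seed_sensitivity():
    a = syn.simulate_bang_assay(seed=1)
    b = syn.simulate_bang_assay(seed=2)
    assert not a["n_alive_24h"].equals(b["n_alive_24h"])


# --- writers round-trip ----------------------------------------------------


def test_io_round_trips(tmp_path):
    rec = syn.simulate_lifespans(syn.CohortSpec(n_flies=50, seed=1))
    io.write_survival_tsv(rec, tmp_path / "s.tsv")
    back = io.read_survival_tsv(tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(rec.reset_index(drop=True), back,
                                  check_dtype=False)

    mat, meta = syn.simulate_metabolome(
        syn.MetabolomeSpec(n_samples=20, n_metabolites=5, n_batches=2, seed=2))
    io.write_metabolome_tsv(mat, meta, tmp_path / "m.tsv", tmp_path / "meta.tsv")
    m2, md2 = io.read_metabolome_tsv(tmp_path / "m.tsv", tmp_path / "meta.tsv")
    np.testing.assert_allclose(mat.to_numpy(), m2.to_numpy())
    assert list(md2["replicate"]) == list(meta["replicate"])

    bang = syn.simulate_bang_assay(seed=3)
    io.write_bang_tsv(bang, tmp_path / "b.tsv")
    pd.testing.assert_frame_equal(bang.reset_index(drop=True),
                                  io.read_bang_tsv(tmp_path / "b.tsv"),
                                  check_dtype=False)

    from climbmet import keggnet as kn

    g = syn.simulate_hetero_graph(syn.GraphSpec(seed=4))
    io.write_graph_tsv(g, tmp_path / "n.tsv", tmp_path / "e.tsv")
    g2 = kn.load_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")
    assert set(g.g.nodes) == set(g2.g.nodes)
    assert {frozenset(e) for e in g.g.edges} == {frozenset(e) for e in g2.g.edges}
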