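"""Simulator unit and oracle tests: parameter sampling, rate matrices,
event-level evolution, and dataset assembly."""

import numpy as np
import pytest
from scipy import linalg, stats

from selcnn import codons
from selcnn.phylo import build_symmetric_tree
from selcnn.simulate import (
    GENE_CLASSES,
    IndelModel,
    SimulationConfig,
    _Kernel,
    _ColumnRegistry,
    _evolve_branch,
    EventCounts,
    allocate_classes,
    build_codon_model,
    plan_dataset,
    sample_gene_profile,
    simulate_dataset,
    simulate_gene,
)

from conftest import make_profile


# ---------------------------------------------------------------------------
# parameter sampling


@pytest.mark.parametrize("gene_class", GENE_CLASSES)
def test_profile_invariants(gene_class):
    cfg = SimulationConfig()
    rng = np.random.default_rng(5)
    for _ in range(200):
        p = sample_gene_profile(cfg, gene_class, rng)
        assert p.p0 + p.p1 + p.p2 == pytest.approx(1.0)
        assert 0.5 <= p.p0 <= 0.8 and 0.01 <= p.p2 <= 0.1 and p.p1 >= 0
        assert 0.1 <= p.omega0 <= 0.5
        assert 0.5 <= p.omega1 <= 0.9
        assert 2.0 <= p.kappa <= 3.0
        assert 100 <= p.root_length <= 600
        if gene_class == "purifying":
            assert 0.9 <= p.omega2 <= 1.0
        elif gene_class == "neutral":
            assert p.omega2 == 1.0
        else:
            assert 1.5 <= p.omega2 <= 5.0
        assert p.label == (1 if gene_class == "positive" else 0)


def test_neutral_class_omega2_is_exactly_one():
    rng = np.random.default_rng(0)
    p = sample_gene_profile(SimulationConfig(), "neutral", rng)
    assert p.omega2 == 1.0


def test_degenerate_root_length_bounds():
    cfg = SimulationConfig(root_length_min=300, root_length_max=300)
    rng = np.random.default_rng(1)
    p = sample_gene_profile(cfg, "purifying", rng)
    assert p.root_length == 300


def test_root_length_matches_truncated_gamma_mean():
    """Empirical mean of sampled root lengths vs. the discretized truncated
    gamma expectation computed by numeric integration (independent oracle)."""
    cfg = SimulationConfig()
    dist = stats.gamma(cfg.root_length_shape, scale=cfg.root_length_scale)
    ks = np.arange(cfg.root_length_min, cfg.root_length_max + 1)
    probs = dist.cdf(ks + 0.5) - dist.cdf(ks - 0.5)
    expected_mean = float(np.sum(ks * probs) / probs.sum())
    expected_var = float(np.sum(ks**2 * probs) / probs.sum() - expected_mean**2)

    rng = np.random.default_rng(42)
    n = 10_000
    draws = [
        sample_gene_profile(cfg, "positive", rng).root_length for _ in range(n)
    ]
    se = np.sqrt(expected_var / n)
    assert abs(np.mean(draws) - expected_mean) < 3 * se


# ---------------------------------------------------------------------------
# codon model construction


def test_neutral_parameters_make_all_rates_equal():
    profile = make_profile(kappa=1.0, omegas=(1.0, 1.0, 1.0))
    model = build_codon_model(profile)
    for q in model.rate_matrices:
        off = q[codons.SINGLE_CHANGE]
        assert np.allclose(off, off[0])
        assert np.all(q[~codons.SINGLE_CHANGE & ~np.eye(61, dtype=bool)] == 0)


def test_mixture_normalization_is_unit():
    rng = np.random.default_rng(3)
    for _ in range(5):
        profile = sample_gene_profile(SimulationConfig(), "positive", rng)
        model = build_codon_model(profile)
        rate = sum(
            p * np.sum(model.frequencies * -np.diag(q))
            for p, q in zip(profile.proportions, model.rate_matrices)
        )
        assert rate == pytest.approx(1.0)
        for q in model.rate_matrices:
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)


def test_transition_transversion_and_selection_ratio():
    """With kappa=2, omega=0.5: rate(synonymous transition) /
    rate(nonsynonymous transversion) = 4, verified by brute-force
    classification of all single-change codon pairs."""
    profile = make_profile(kappa=2.0, omegas=(0.5, 0.5, 0.5))
    model = build_codon_model(profile)
    q = model.rate_matrices[0]

    syn_ts, nonsyn_tv = [], []
    for i in range(61):
        for j in range(61):
            if i == j or not codons.SINGLE_CHANGE[i, j]:
                assert i == j or q[i, j] == 0
                continue
            ci, cj = codons.SENSE_CODONS[i], codons.SENSE_CODONS[j]
            (a, b) = next((a, b) for a, b in zip(ci, cj) if a != b)
            ts = {a, b} in ({"A", "G"}, {"C", "T"})
            syn = codons.CODON_AA[i] == codons.CODON_AA[j]
            if syn and ts:
                syn_ts.append(q[i, j])
            elif not syn and not ts:
                nonsyn_tv.append(q[i, j])
    assert np.mean(syn_ts) / np.mean(nonsyn_tv) == pytest.approx(4.0)


def test_frequency_validation():
    profile = make_profile()
    with pytest.raises(ValueError):
        build_codon_model(profile, np.ones(60) / 60)
    bad = np.full(61, 1 / 61)
    bad[0] += 1e-6
    with pytest.raises(ValueError):
        build_codon_model(profile, bad)


# ---------------------------------------------------------------------------
# gene-level simulation


def test_no_indels_means_gapless_alignment():
    profile = make_profile(root_length=100)
    tree = build_symmetric_tree(8, 0.2)
    model = build_codon_model(profile)
    rec = simulate_gene(profile, tree, model, IndelModel(rate=0.0),
                        np.random.default_rng(2))
    assert rec.events.indels == 0
    for name, row in rec.alignment_rows:
        assert "-" not in row
        assert row == rec.leaf_sequences[name]
    assert rec.alignment_length == 300


def test_alignment_invariants(small_gene_records):
    """Equal row lengths, frame preserved, ungapping identity, no stops,
    annotation aligned with columns."""
    for rec in small_gene_records:
        lengths = {len(row) for _, row in rec.alignment_rows}
        assert len(lengths) == 1
        (L,) = lengths
        assert L % 3 == 0
        assert len(rec.column_classes) == L // 3
        assert len(rec.column_inserted) == L // 3
        for name, row in rec.alignment_rows:
            assert row.replace("-", "") == rec.leaf_sequences[name]
            seq = rec.leaf_sequences[name]
            assert len(seq) % 3 == 0
            for k in range(0, len(seq), 3):
                assert seq[k : k + 3] not in codons.STOP_CODONS


def test_substitution_rate_calibration():
    """Mean substitution events per codon site per branch ~ divergence."""
    cfg = SimulationConfig(
        indel_rate=0.0, root_length_min=100, root_length_max=150
    )
    per_gene = []
    for rec in simulate_dataset(cfg, 100, seed=9):
        per_gene.append(rec.events.substitutions / rec.branch_codon_sites)
    per_gene = np.array(per_gene)
    se = per_gene.std(ddof=1) / np.sqrt(len(per_gene))
    assert abs(per_gene.mean() - cfg.divergence) < 3 * se


def test_gillespie_matches_matrix_exponential():
    """Single-site end-state distribution vs. expm of the scaled generator
    (total variation < 0.01 over 50,000 runs)."""
    profile = make_profile(omegas=(0.3, 0.7, 3.0))
    model = build_codon_model(profile)
    kernel = _Kernel(model)
    cls, start, t = 2, 17, 0.2
    indel = IndelModel(rate=0.0)
    cum_class = np.cumsum(np.asarray(profile.proportions))

    n_runs = 50_000
    rng = np.random.default_rng(123)
    counts = np.zeros(61)
    for _ in range(n_runs):
        registry = _ColumnRegistry()
        registry.new_root_columns(np.array([cls]))
        states, _, _ = _evolve_branch(
            np.array([start]), np.array([0]), np.array([cls]), t,
            kernel, indel, cum_class, registry, rng, EventCounts(),
        )
        counts[states[0]] += 1
    empirical = counts / n_runs
    expected = linalg.expm(model.rate_matrices[cls] * t)[start]
    tv = 0.5 * np.abs(empirical - expected).sum()
    assert tv < 0.01


def test_leaf_frequencies_stay_stationary():
    """With the root drawn from pi and no indels, leaf codon frequencies
    pass a chi-square goodness-of-fit test at alpha = 0.001.

    Only one leaf per gene is pooled: without indels the per-site chains are
    independent within a single sequence, whereas codons pooled across taxa
    share ancestry and would overdisperse the chi-square statistic.
    """
    cfg = SimulationConfig(
        n_taxa=2, indel_rate=0.0, root_length_min=300, root_length_max=600
    )
    counts = np.zeros(61)
    for rec in simulate_dataset(cfg, 250, seed=21):
        seq = rec.leaf_sequences["t1"]
        for k in range(0, len(seq), 3):
            counts[codons.CODON_INDEX[seq[k : k + 3]]] += 1
    assert counts.sum() >= 1e5
    expected = counts.sum() * np.full(61, 1 / 61)
    p = stats.chisquare(counts, expected).pvalue
    assert p > 0.001


def test_indel_lengths_are_geometric():
    """Mean drawn indel length ~ 1/q within 3 SE (pre-truncation draws)."""
    cfg = SimulationConfig(
        indel_rate=0.2, root_length_min=100, root_length_max=150
    )
    drawn = []
    for rec in simulate_dataset(cfg, 150, seed=33):
        drawn.extend(rec.events.insertion_lengths)
        drawn.extend(rec.events.deletion_drawn_lengths)
    drawn = np.array(drawn, dtype=float)
    assert len(drawn) >= 5_000
    q = cfg.indel_length_q
    se = np.sqrt((1 - q) / q**2 / len(drawn))
    assert abs(drawn.mean() - 1 / q) < 3 * se


def test_simulation_is_deterministic(baseline_config):
    a = list(simulate_dataset(baseline_config, 3, seed=77))
    b = list(simulate_dataset(baseline_config, 3, seed=77))
    for ra, rb in zip(a, b):
        assert ra.alignment_rows == rb.alignment_rows
        assert ra.leaf_sequences == rb.leaf_sequences
        assert ra.profile == rb.profile
        assert np.array_equal(ra.column_classes, rb.column_classes)


# ---------------------------------------------------------------------------
# dataset assembly


def test_class_allocation_is_exact_and_interleaved():
    mix = {"purifying": 0.4, "neutral": 0.1, "positive": 0.5}
    classes = allocate_classes(mix, 1000)
    assert classes.count("positive") == 500
    assert classes.count("purifying") == 400
    assert classes.count("neutral") == 100
    # interleaving: every window of 20 holds every class
    for start in range(0, 1000, 20):
        window = classes[start : start + 20]
        assert set(window) == set(mix)


def test_single_class_mix():
    classes = allocate_classes({"positive": 1.0}, 10)
    assert classes == ["positive"] * 10


def test_bad_proportions_rejected():
    with pytest.raises(ValueError):
        allocate_classes({"positive": 0.6, "purifying": 0.3}, 10)


def test_plan_labels_match_classes():
    rows = plan_dataset(SimulationConfig(), 40, seed=5)
    assert sum(r.label for r in rows) == 20
    for r in rows:
        assert r.label == (1 if r.gene_class == "positive" else 0)
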