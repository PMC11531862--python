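import json

import numpy as np
import pytest

from mtloc.synthetic_data import (SimConfig, SLRule, default_motif_catalogue,
                                  default_sl_rules, generate_backbone,
                                  generate_corpus, generate_dataset,
                                  generate_protein, _term_direction)


def test_backbone_step_length_and_self_avoidance():
    cfg = SimConfig()
    coords = generate_backbone(40, cfg, seed=3)
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    np.testing.assert_allclose(steps, cfg.bond_length, atol=1e-9)
    # non-consecutive residues respect the excluded radius
    d = np.linalg.norm(coords[None] - coords[:, None], axis=-1)
    n = coords.shape[0]
    mask = np.abs(np.arange(n)[None] - np.arange(n)[:, None]) > 1
    assert d[mask].min() >= cfg.excluded_radius - 1e-9


def test_backbone_deterministic_per_seed():
    np.testing.assert_array_equal(generate_backbone(20, seed=5),
                                  generate_backbone(20, seed=5))
    assert not np.allclose(generate_backbone(20, seed=5),
                           generate_backbone(20, seed=6))


def test_backbone_single_residue():
    coords = generate_backbone(1, seed=0)
    np.testing.assert_array_equal(coords, np.zeros((1, 3)))


def test_default_catalogue_counts():
    motifs = default_motif_catalogue()
    by = {"bp": 0, "cc": 0, "mf": 0}
    for m in motifs:
        by[m.ontology] += 1
    assert by == {"bp": 8, "cc": 5, "mf": 5}
    assert len({m.term for m in motifs}) == len(motifs)


def test_sl_rule_semantics():
    rule = SLRule("x", (("a",), ("b", "c")))
    assert rule.holds({"a"})
    assert rule.holds({"b", "c", "z"})
    assert not rule.holds({"b"})
    assert not rule.holds(set())


def test_term_direction_is_unit_and_fixed():
    cfg = SimConfig()
    v1 = _term_direction("bp00", cfg)
    v2 = _term_direction("bp00", cfg)
    np.testing.assert_array_equal(v1, v2)
    assert np.linalg.norm(v1) == pytest.approx(1.0)
    assert abs(np.dot(v1, _term_direction("bp01", cfg))) < 0.9


def test_protein_motif_windows_shift_embeddings():
    cfg = SimConfig(label_noise=0.0)
    protein = None
    for seed in range(100):
        p = generate_protein(cfg, seed)
        if p.motif_windows:
            protein = p
            break
    assert protein is not None
    term, (start, end) = next(iter(protein.motif_windows.items()))
    direction = _term_direction(term, cfg)
    inside = protein.embedding[start:end] @ direction
    # mean projection inside the window carries the +shift offset
    spec = next(m for m in cfg.motifs if m.term == term)
    assert inside.mean() > spec.shift - 1.5  # N(shift, 1/sqrt(len)) margin


def test_labels_follow_rules_without_noise():
    cfg = SimConfig(label_noise=0.0)
    for seed in range(30):
        p = generate_protein(cfg, seed)
        expected = np.array([1 if r.holds(p.go_terms) else 0
                             for r in cfg.sl_rules], dtype=np.int8)
        np.testing.assert_array_equal(p.record.sl, expected)
        # GO vectors encode exactly the present terms
        for ontology in ("bp", "cc", "mf"):
            terms = cfg.terms(ontology)
            vec = getattr(p.record, f"go_{ontology}")
            got = {t for t, v in zip(terms, vec) if v}
            assert got == {t for t in p.go_terms
                           if any(m.term == t and m.ontology == ontology
                                  for m in cfg.motifs)}


def test_label_noise_flip_rate_matches_epsilon():
    cfg_clean = SimConfig(label_noise=0.0, n_proteins=400)
    cfg_noisy = SimConfig(label_noise=0.05, n_proteins=400)
    clean = generate_corpus(cfg_clean)
    noisy = generate_corpus(cfg_noisy)
    # same seeds => same proteins up to the SL flips
    flips = total = 0
    for a, b in zip(clean, noisy):
        np.testing.assert_array_equal(a.record.go_bp, b.record.go_bp)
        flips += int((a.record.sl != b.record.sl).sum())
        total += a.record.sl.size
    rate = flips / total
    assert 0.02 < rate < 0.09  # 1600 draws at eps = 0.05


def test_term_prevalence_near_configured():
    cfg = SimConfig(n_proteins=400)
    corpus = generate_corpus(cfg)
    count = sum("bp00" in p.go_terms for p in corpus)
    assert 0.2 < count / len(corpus) < 0.4  # configured prevalence 0.3


def test_corpus_deterministic_and_ids_unique():
    cfg = SimConfig(n_proteins=12, length_range=(10, 15), seed=2)
    c1, c2 = generate_corpus(cfg), generate_corpus(cfg)
    assert [p.record.id for p in c1] == [p.record.id for p in c2]
    assert len({p.record.id for p in c1}) == 12
    np.testing.assert_array_equal(c1[3].embedding, c2[3].embedding)
    np.testing.assert_array_equal(c1[3].record.coords, c2[3].record.coords)


def test_sim_config_validation():
    with pytest.raises(ValueError, match="bond length"):
        SimConfig(bond_length=5.0, contact_threshold=4.5)
    with pytest.raises(ValueError, match="label_noise"):
        SimConfig(label_noise=0.7)


def test_generate_dataset_layout_and_round_trip(tmp_path):
    cfg = SimConfig(n_proteins=6, length_range=(10, 14), seed=4)
    out = generate_dataset(cfg, tmp_path / "data")
    assert (out / "sequences.fasta").exists()
    assert (out / "labels_sl.tsv").exists()
    assert len(list((out / "coords").glob("*.xyz"))) == 6
    assert len(list((out / "embeddings").glob("*.tsv"))) == 6
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["seed"] == 4 and manifest["n_proteins"] == 6
    assert manifest["sl_classes"] == [r.name for r in default_sl_rules()]

    from mtloc.pipeline import load_dataset_dir
    samples, vocabs = load_dataset_dir(out)
    assert len(samples) == 6
    assert set(vocabs) == {"bp", "cc", "mf", "sl"}
    assert list(vocabs["bp"].terms) == manifest["terms"]["bp"]
    sample = samples[0]
    assert sample.graph.node_feats.shape[1] == cfg.embedding_dim
    assert sample.sl.shape == (len(cfg.sl_rules),)
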