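"""Exact p-value machinery and the promoter scanner."""

from itertools import product

import numpy as np
import pytest

from florinet.io_formats import MotifModel
from florinet.motif_scan import (
    UNIFORM_BG,
    build_scoring_model,
    estimate_background,
    scan_sequences,
)
from florinet.seqcodes import ALPHABET, revcomp


def enumerate_tail(model, w):
    """Brute-force null tail over all 4**w words (the independent oracle)."""
    words = np.array(list(product(range(4), repeat=w)))
    scores = model.int_scores[np.arange(w), words].sum(axis=1)
    return scores


class TestScoringModel:
    def test_uniform_motif_all_zero_logodds(self):
        m = MotifModel("u", np.full((3, 4), 0.25))
        sm = build_scoring_model(m, pseudocount=0.0)
        assert np.allclose(sm.log_odds, 0.0)
        assert sm.pvalue(0) == 1.0

    def test_two_column_max_score_probability(self):
        # both columns favour A (0.7); only "AA" attains the maximum score,
        # so P(score >= max) under uniform background is 1/16
        m = MotifModel("a", np.array([[0.7, 0.1, 0.1, 0.1]] * 2))
        sm = build_scoring_model(m, pseudocount=0.0)
        assert sm.pvalue(sm.int_scores.max(axis=1).sum()) == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_tail_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(2, 5))
        m = MotifModel(f"m{seed}", rng.dirichlet(np.ones(4), size=w))
        sm = build_scoring_model(m)
        scores = enumerate_tail(sm, w)
        for s in np.unique(scores):
            exact = (scores >= s).sum() / 4**w
            assert sm.pvalue(int(s)) == pytest.approx(exact, abs=1e-12)

    def test_tail_nonincreasing_and_one_at_minimum(self):
        rng = np.random.default_rng(7)
        m = MotifModel("m", rng.dirichlet(np.ones(4), size=6))
        sm = build_scoring_model(m)
        assert sm.tail[0] == pytest.approx(1.0)
        assert (np.diff(sm.tail) <= 1e-15).all()

    def test_zero_pseudocount_with_zero_prob_rejected(self):
        m = MotifModel("z", np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            build_scoring_model(m, pseudocount=0.0)


def _random_seq(rng, n):
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, n))


def _sharp_motif(consensus: str, pmax=0.97) -> MotifModel:
    mat = np.full((len(consensus), 4), (1 - pmax) / 3)
    for i, c in enumerate(consensus):
        mat[i, ALPHABET.index(c)] = pmax
    return MotifModel("sharp", mat)


class TestScan:
    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(5)
        motif = _sharp_motif("ACGTACGTTG")
        seq = _random_seq(rng, 600)
        seq = seq[:37] + motif.consensus + seq[47:]
        hits = scan_sequences({"g": seq}, [build_scoring_model(motif)], p_threshold=1e-5)
        fwd = hits[hits.strand == "+"]
        assert list(fwd.offset) == [37]
        assert (fwd.p_value <= 1e-5).all()

    def test_short_promoter_yields_no_hits(self):
        motif = _sharp_motif("ACGTACGTTG")
        hits = scan_sequences({"g": "ACGT"}, [build_scoring_model(motif)])
        assert len(hits) == 0

    def test_zero_threshold_yields_no_hits(self):
        motif = _sharp_motif("ACGTACGTTG")
        seq = "AAAA" + motif.consensus + "TTTT"
        assert len(scan_sequences({"g": seq}, [build_scoring_model(motif)], p_threshold=0.0)) == 0

    def test_n_windows_are_skipped(self):
        motif = _sharp_motif("ACGTACGTTG")
        cons = motif.consensus
        seq = cons[:5] + "N" + cons[6:]  # the only strong window now contains N
        hits = scan_sequences({"g": seq}, [build_scoring_model(motif)], p_threshold=0.5)
        assert len(hits) == 0

    def test_lowering_threshold_never_adds_hits(self):
        rng = np.random.default_rng(11)
        motif = MotifModel("m", rng.dirichlet(np.ones(4) * 2, size=8))
        sm = build_scoring_model(motif)
        seqs = {f"g{i}": _random_seq(rng, 600) for i in range(20)}
        loose = scan_sequences(seqs, [sm], p_threshold=1e-2)
        tight = scan_sequences(seqs, [sm], p_threshold=1e-3)
        loose_keys = set(map(tuple, loose[["gene", "offset", "strand"]].itertuples(index=False)))
        tight_keys = set(map(tuple, tight[["gene", "offset", "strand"]].itertuples(index=False)))
        assert tight_keys <= loose_keys

    def test_strand_symmetry(self):
        """Hits on a sequence equal mirrored hits on its reverse complement."""
        rng = np.random.default_rng(3)
        motif = _sharp_motif("ACGTACGTTG")
        sm = build_scoring_model(motif)
        seq = _random_seq(rng, 300)
        seq = seq[:50] + motif.consensus + seq[60:120] + revcomp(motif.consensus) + seq[130:]
        fwd = scan_sequences({"g": seq}, [sm], p_threshold=1e-4)
        rev = scan_sequences({"g": revcomp(seq)}, [sm], p_threshold=1e-4)
        w, L = motif.width, len(seq)
        mirrored = {
            (L - w - int(r.offset), {"+": "-", "-": "+"}[r.strand]) for r in rev.itertuples()
        }
        assert {(int(r.offset), r.strand) for r in fwd.itertuples()} == mirrored

    def test_planted_sites_recovered_in_default_dataset(self, dataset, hits):
        """>=95% of planted consensus sites are found at exact offset+strand."""
        found = {(r.gene, r.motif, int(r.offset), r.strand) for r in hits.itertuples(index=False)}
        planted = {(g, m, o, s) for g, o, s, m in dataset.truth.planted_sites}
        recovered = len(planted & found) / len(planted)
        assert recovered >= 0.95


def test_background_estimation_ignores_n():
    bg = estimate_background(["AACN", "GGTT"])
    assert bg == pytest.approx([2 / 7, 1 / 7, 2 / 7, 2 / 7])
    assert np.allclose(UNIFORM_BG.sum(), 1.0)
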