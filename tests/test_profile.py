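"""Seed curation, PSSM construction and the six-frame scan."""

from functools import lru_cache

import numpy as np
import pytest

from tcme.cluster import Alignment
from tcme.genetics import encode_aa, revcomp, six_frame_translate, translate
from tcme.profile import (CurationThresholds, build_profile, calibrate_threshold,
                          curate_seed, dinucleotide_shuffle, gap_filter,
                          scan_genome, score_local)
from tcme.synth import Genome

from .conftest import random_dna, random_protein


def test_curate_seed_length_boundaries():
    rng = np.random.default_rng(0)
    seqs = {f"l{n}": random_protein(rng, n) for n in (150, 199, 200, 250, 600, 601)}
    kept = curate_seed(seqs)
    assert sorted(kept) == ["l200", "l250", "l600"]
    # all in range -> identity operation
    ok = {k: v for k, v in seqs.items() if k in ("l200", "l250")}
    assert curate_seed(ok) == ok
    with pytest.warns(UserWarning):
        curate_seed({"x": random_protein(rng, 100)})


def test_gap_filter_boundary_is_strictly_greater_than():
    rows = {
        "nogap": "ACDEFGHIKLMNPQRSTVWY",
        "gap20": "ACDEFGHIKLMNPQRS----",      # exactly 20% -> retained
        "gap25": "ACDEFGHIKLMNPQR-----",      # 25% -> discarded
    }
    aln = Alignment(list(rows), list(rows.values()))
    kept = gap_filter(aln, (0, 20), 0.20)
    assert kept == ["nogap", "gap20"]
    with pytest.raises(ValueError):
        gap_filter(aln, (10, 25), 0.20)


def test_build_profile_closed_form_and_counts():
    # single column of four identical residues, pseudocount -> 0
    aln = Alignment(["a", "b", "c", "d"], ["A", "A", "A", "A"])
    prof = build_profile(aln, pseudocount=1e-9)
    a_idx = 0
    assert prof.scores[0, a_idx] == pytest.approx(np.log2(20), abs=1e-6)
    # random alignment vs independently coded count formula
    rng = np.random.default_rng(1)
    rows = [random_protein(rng, 30) for _ in range(5)]
    aln = Alignment([f"r{i}" for i in range(5)], rows)
    prof = build_profile(aln, pseudocount=1.0)
    bg = np.full(20, 1 / 20)
    from tcme.genetics import AA_ALPHABET
    for c in range(30):
        counts = np.zeros(20)
        for r in rows:
            counts[AA_ALPHABET.index(r[c])] += 1
        expected = np.log2(((counts + bg) / (5 + 1.0)) / bg)
        assert np.allclose(prof.scores[c, :20], expected, atol=1e-9)
    with pytest.raises(ValueError):
        build_profile(Alignment(["a", "b"], ["--", "--"]))


def brute_force_local(S, x, go, ge):
    """Exhaustive best local profile alignment on tiny instances."""
    m, n = S.shape[0], len(x)

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # best score of a path ENDING at (i, j) in the given state
        best = -1e18
        if state == 0:
            prev = max(rec(i - 1, j - 1, s) for s in (0, 1, 2)) \
                if i > 1 and j > 1 else 0.0
            prev = max(prev, 0.0)
            best = prev + S[i - 1, x[j - 1]]
        elif state == 1 and i > 1:
            best = max(rec(i - 1, j, 0) - go, rec(i - 1, j, 1) - ge)
        elif state == 2 and j > 1:
            best = max(rec(i, j - 1, 0) - go, rec(i, j - 1, 2) - ge)
        return best

    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = max(best, rec(i, j, 0))
    return best


@pytest.mark.parametrize("seed", range(10))
def test_local_profile_score_equals_enumeration(seed):
    rng = np.random.default_rng(seed)
    ncols = int(rng.integers(3, 9))
    S = np.round(rng.normal(0, 2, size=(ncols, 22)), 3)
    prot = random_protein(rng, int(rng.integers(4, 13)))
    x = encode_aa(prot)
    from tcme._align import profile_local
    got, *_ = profile_local(S.astype(float), x, 3.0, 1.0)
    exp = brute_force_local(S, list(x), 3.0, 1.0)
    assert got == pytest.approx(exp)


def test_score_monotone_under_flanking(profile):
    rng = np.random.default_rng(5)
    core = random_protein(rng, 80)
    base, *_ = score_local(profile, core)
    for _ in range(5):
        flanked = random_protein(rng, 20) + core + random_protein(rng, 20)
        flank_score, *_ = score_local(profile, flanked)
        assert flank_score >= base - 1e-9
        core = flanked
        base = flank_score


def test_six_frame_stops_rendered():
    frames = six_frame_translate("ATGAAATAAGGG")
    assert frames[1] == "MK*G"


def test_dinucleotide_shuffle_preserves_counts():
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 300)
    shuf = dinucleotide_shuffle(seq, rng)
    def dinucs(s):
        out = {}
        for a, b in zip(s, s[1:]):
            out[a + b] = out.get(a + b, 0) + 1
        return out
    assert dinucs(shuf) == dinucs(seq)
    assert shuf != seq


def test_scan_finds_planted_domain_and_ignores_shuffle(profile, templates):
    rng = np.random.default_rng(8)
    tnpb = templates[0].tnpb_protein
    # embed the unmutated TnpB CDS in a random genome
    from tcme.genetics import reverse_translate
    cds = reverse_translate(tnpb, np.random.default_rng(1))
    bg = random_dna(rng, 30_000)
    contig = bg[:12_000] + cds + bg[12_000:]
    g = Genome("t1", "Synthetica alpha", {"c1": contig})
    thr = calibrate_threshold(profile, [g], seed=9, n_decoys=200)
    hits = scan_genome(profile, g, thr)
    assert len(hits) == 1
    h = hits[0]
    assert h.genomic_start >= 12_000 and h.genomic_end <= 12_000 + len(cds)
    assert h.matched_len >= 50

    shuffled = dinucleotide_shuffle(contig, rng)
    assert scan_genome(profile, Genome("t2", "x", {"c1": shuffled}), thr) == []


def test_short_hits_discarded_by_min_length(profile, templates):
    """A 40-aa domain fragment scores above threshold but fails the 50-aa
    hit-length rule."""
    rng = np.random.default_rng(3)
    _sc, cols, span = score_local(profile, templates[0].tnpb_protein)
    frag = templates[0].tnpb_protein[span[0]: span[0] + 40]
    from tcme.genetics import reverse_translate
    cds = "ATG" + reverse_translate("M" + frag, np.random.default_rng(2))[3:]
    bg = random_dna(rng, 20_000)
    contig = bg[:9_000] + cds + bg[9_000:]
    g = Genome("t3", "x", {"c1": contig})
    thr = calibrate_threshold(profile, [g], seed=4, n_decoys=200)
    frag_score, *_ = score_local(profile, frag)
    assert frag_score >= thr            # the filter, not the score, rejects it
    assert scan_genome(profile, g, thr, min_hit_len=50) == []


def test_hit_round_trips_through_reverse_frames(profile, small_dataset,
                                                scan_threshold):
    _cfg, genomes, _ledger = small_dataset
    found_minus = False
    for g in genomes:
        for h in scan_genome(profile, g, scan_threshold):
            contig = g.contigs[h.contig_id]
            sub = contig[h.genomic_start:h.genomic_end]
            if h.strand == "-":
                sub = revcomp(sub)
                found_minus = True
            pep = translate(sub)
            frames = six_frame_translate(contig)
            assert pep == frames[h.frame][h.protein_start:h.protein_end]
    assert found_minus


def test_calibration_false_hit_rate(profile, small_dataset):
    _cfg, genomes, _ledger = small_dataset
    thr = calibrate_threshold(profile, genomes, seed=10, n_decoys=1000)
    # recompute decoy scores with a different seed; the threshold must keep
    # the empirical false-hit rate under 1%
    rng = np.random.default_rng(11)
    from tcme._align import profile_local
    from tcme.genetics import encode_nt, translate_codes
    S2 = profile.halfbit_matrix()
    contig = genomes[0].contigs["c1"]
    n_false = 0
    n = 1000
    for _ in range(n):
        p = int(rng.integers(0, len(contig) - 600))
        dec = dinucleotide_shuffle(contig[p:p + 600], rng)
        x = translate_codes(encode_nt(dec))
        sc, *_ = profile_local(S2, x, profile.gap_open, profile.gap_extend)
        if sc / 2.0 >= thr:
            n_false += 1
    assert n_false / n < 1e-2
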