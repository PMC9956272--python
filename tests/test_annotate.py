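"""Locus annotation: ORFs, roles, boundaries, subgroups, decay, families."""

import numpy as np
import pytest

from tcme.annotate import (AnnotationParams, Element, Orf, annotate_locus,
                           assign_family, assign_role, call_completeness,
                           classify_subgroup, detect_boundaries, extract_locus,
                           find_orfs, group_hits_to_loci, has_flank_remnant)
from tcme.genetics import revcomp, reverse_translate, translate
from tcme.profile import ProteinHit, calibrate_threshold, scan_genome, score_local
from tcme.synth import Genome

from .conftest import random_dna, random_protein

PARAMS = AnnotationParams()


def _hit(gid, cid, s, e, strand="+"):
    return ProteinHit(gid, cid, 1 if strand == "+" else -1, 0, (e - s) // 3,
                      s, e, strand, 100.0, (e - s) // 3)


def test_extract_locus_flank_arithmetic():
    g = Genome("g", "sp", {"c1": "A" * 100_000})
    loc = extract_locus(_hit("g", "c1", 5000, 6200), g, flank=1700)
    assert (loc.start, loc.end) == (3300, 7900)
    assert loc.sequence == g.contigs["c1"][3300:7900]
    # clipping at the contig edge
    loc = extract_locus(_hit("g", "c1", 100, 400), g, flank=1700)
    assert loc.start == 0 and loc.end == 2100


def test_nearby_hits_make_separate_loci():
    g = Genome("g", "sp", {"c1": "A" * 50_000})
    hits = [_hit("g", "c1", 10_000, 10_300), _hit("g", "c1", 10_800, 11_100)]
    loci = group_hits_to_loci(hits, g)
    assert len(loci) == 2              # loci overlap but stay distinct
    assert loci[0].end > loci[1].start
    # overlapping hits (same element, two frames) collapse into one locus
    hits = [_hit("g", "c1", 10_000, 10_300),
            ProteinHit("g", "c1", 2, 0, 100, 10_050, 10_350, "+", 90.0, 100)]
    assert len(group_hits_to_loci(hits, g)) == 1


def brute_force_orfs(seq, min_codons):
    """Independent six-frame scanner."""
    out = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        n = len(s)
        for off in range(3):
            codons = [s[p:p + 3] for p in range(off, n - 2, 3)]
            stops = [i for i, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
            prev = -1
            for si in stops:
                starts = [i for i in range(prev + 1, si)
                          if codons[i] in ("ATG", "GTG", "TTG")]
                if starts and si - starts[0] >= min_codons:
                    a = off + 3 * starts[0]
                    b = off + 3 * si + 3
                    if strand == "-":
                        a, b = n - b, n - a
                    out.add((a, b, strand))
                prev = si
    return out


@pytest.mark.parametrize("seed", range(8))
def test_find_orfs_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 3000)
    got = {(o.start, o.end, o.strand) for o in find_orfs(seq, 50)}
    assert got == brute_force_orfs(seq, 50)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_planted_orf_recovered(strand):
    rng = np.random.default_rng(1)
    prot = "M" + random_protein(rng, 59)
    cds = reverse_translate(prot, rng) + "TAA"
    # stop guard upstream prevents accidental 5' extension
    seq = random_dna(rng, 500)[:-3] + "TAA" + cds + random_dna(rng, 500)
    if strand == "-":
        seq = revcomp(seq)
    orfs = find_orfs(seq, 50)
    match = [o for o in orfs if o.strand == strand and o.protein == prot]
    assert len(match) == 1


def test_assign_role_on_template_proteins(templates_by_subgroup, profile,
                                          scan_threshold):
    y1 = templates_by_subgroup["IS605a"].orfa_protein
    sr = templates_by_subgroup["IS607b"].orfa_protein
    tnpb = templates_by_subgroup["IS1341"].tnpb_protein
    o = assign_role(Orf(0, 3 * len(y1) + 3, "+", y1), profile, scan_threshold)
    assert o.role == "Y1" and o.motif_evidence[0][0] == "HuH"
    o = assign_role(Orf(0, 3 * len(sr) + 3, "+", sr), profile, scan_threshold)
    assert o.role == "SR"
    o = assign_role(Orf(0, 3 * len(tnpb) + 3, "+", tnpb), profile, scan_threshold)
    assert o.role == "TnpB" and o.score >= scan_threshold


def test_shuffled_y1_loses_role(templates_by_subgroup, profile, scan_threshold):
    rng = np.random.default_rng(0)
    y1 = list(templates_by_subgroup["IS605a"].orfa_protein)
    rng.shuffle(y1)
    shuffled = "".join(y1)
    from tcme.motifs import find_y1_motif
    assert find_y1_motif(shuffled) is None  # motifs destroyed at this seed
    o = assign_role(Orf(0, 3 * len(shuffled) + 3, "+", shuffled), profile,
                    scan_threshold)
    assert o.role == "unknown"


def test_detect_boundaries_planted_palindromes(templates_by_subgroup):
    t = templates_by_subgroup["IS605b"]
    rng = np.random.default_rng(3)
    ctx = random_dna(rng, 1000)
    seq = ctx[:500] + t.sequence + ctx[500:]
    orf_lo = 500 + min(t.orfa_cds[0], t.tnpb_cds[0])
    orf_hi = 500 + max(t.orfa_cds[1], t.tnpb_cds[1])
    le, re_ = detect_boundaries(seq, orf_lo, orf_hi)
    assert le is not None and re_ is not None
    assert le.repeat_kind == "inverted" and re_.repeat_kind == "inverted"
    assert le.cleavage_tetramer == t.le.tetramer
    assert re_.cleavage_tetramer == t.re.tetramer
    assert le.tetramer_start == 500            # element start
    assert re_.tetramer_start + 4 == 500 + t.length


def test_is607_ends_are_direct_not_inverted(templates_by_subgroup):
    t = templates_by_subgroup["IS607b"]
    rng = np.random.default_rng(4)
    ctx = random_dna(rng, 1000)
    seq = ctx[:500] + t.sequence + ctx[500:]
    orf_lo = 500 + min(t.orfa_cds[0], t.tnpb_cds[0])
    orf_hi = 500 + max(t.orfa_cds[1], t.tnpb_cds[1])
    le, re_ = detect_boundaries(seq, orf_lo, orf_hi)
    assert le.repeat_kind == "direct" and re_.repeat_kind == "direct"
    assert le.tetramer_start == 500
    assert re_.tetramer_start + 4 == 500 + t.length


def test_boundary_absent_when_window_clipped():
    rng = np.random.default_rng(5)
    # ORF starts at position 1: no room for any repeat (or tetramer) left
    seq = random_dna(rng, 400)
    le, _re = detect_boundaries(seq, 1, 380)
    assert le is None


def test_call_completeness_table():
    b = object.__new__(type("B", (), {}))
    from tcme.annotate import BoundaryCall
    le = BoundaryCall("LE", "inverted", 10, 40, 12, 5, "TTAT", 6)
    re_ = BoundaryCall("RE", "inverted", 900, 930, 12, 5, "TCAA", 930)
    assert call_completeness(le, re_) == "full"
    assert call_completeness(le, None) == "truncated_RE"
    assert call_completeness(None, re_) == "truncated_LE"
    assert call_completeness(None, None) == "truncated_both"


def _orf(start, end, strand, role):
    return Orf(start, end, strand, "M" * 100, role)


def test_classify_subgroup_rules():
    tnpb = Orf(1000, 2200, "+", "M" * 399, "TnpB", score=100.0)
    y1_overlap = _orf(600, 1014, "+", "Y1")       # 14 nt overlap
    assert classify_subgroup([tnpb, y1_overlap]) == "IS605a"
    y1_gap = _orf(560, 980, "+", "Y1")            # 20 nt gap
    assert classify_subgroup([tnpb, y1_gap]) == "IS605b"
    y1_rev = _orf(560, 980, "-", "Y1")
    assert classify_subgroup([tnpb, y1_rev]) == "IS605c"
    sr_overlap = Orf(400, 1004, "+", "M" * 200, "SR")
    assert classify_subgroup([tnpb, sr_overlap]) == "IS607a"
    sr_gap = Orf(370, 975, "+", "M" * 200, "SR")  # 25 nt gap
    assert classify_subgroup([tnpb, sr_gap]) == "IS607b"
    assert classify_subgroup([tnpb]) == "IS1341"
    tnpb2 = Orf(2500, 3700, "+", "M" * 399, "TnpB", score=90.0)
    assert classify_subgroup([tnpb, tnpb2]) == "unclassified"
    with pytest.raises(ValueError):
        classify_subgroup([y1_gap])


def _embed_remnant(bg, ref, a, b):
    """Plant ref[a:b] into bg with mismatching 10-nt shoulders so the
    local alignment cannot pick up chance matches adjacent to the
    remnant (isolating the >20-matches rule)."""
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    left = "".join(flip[c] for c in ref[a - 10:a])
    right = "".join(flip[c] for c in ref[b:b + 10])
    ins = left + ref[a:b] + right
    return bg[:80] + ins + bg[80 + len(ins):]


def test_decay_rule_boundary_at_20_matches():
    rng = np.random.default_rng(6)
    ref = random_dna(rng, 420)
    bg_up = random_dna(rng, 200)
    bg_dn = random_dna(rng, 200)
    # exactly 20 identical nt -> not flagged (rule is strictly > 20)
    up20 = _embed_remnant(bg_up, ref, 100, 120)
    assert not has_flank_remnant(up20, bg_dn, [ref])
    # 25 identical nt -> flagged
    up25 = _embed_remnant(bg_up, ref, 100, 125)
    assert has_flank_remnant(up25, bg_dn, [ref])
    # reverse-complement remnants count too
    up_rc = bg_up[:80] + revcomp(ref[100:125]) + bg_up[105:]
    assert has_flank_remnant(up_rc, bg_dn, [ref])
    # exact-substring reading
    assert has_flank_remnant(up25, bg_dn, [ref], exact=True)
    assert not has_flank_remnant(up20, bg_dn, [ref], exact=True)


@pytest.mark.parametrize("seed", range(10))
def test_decay_soundness_on_random_flanks(seed):
    """No flag without a >=21-nt shared stretch (brute-force corroborated)."""
    rng = np.random.default_rng(100 + seed)
    ref = random_dna(rng, 400)
    up = random_dna(rng, 220)
    down = random_dna(rng, 220)

    def brute(region):
        k = 21
        for target in (ref, revcomp(ref)):
            kmers = {target[i:i + k] for i in range(len(target) - k + 1)}
            if any(region[i:i + k] in kmers
                   for i in range(len(region) - k + 1)):
                return True
        return False

    flagged = has_flank_remnant(up, down, [ref], exact=True)
    assert flagged == (brute(up) or brute(down))
    assert not flagged


def _element(subgroup, species, le_tet="TTAT", re_tet="TCAA", full=True):
    from tcme.annotate import BoundaryCall
    le = BoundaryCall("LE", "inverted", 4, 40, 12, 5, le_tet, 0) if full else None
    re_ = BoundaryCall("RE", "inverted", 900, 936, 12, 5, re_tet, 936) if full else None
    return Element("g", species, "c1", 0, 940, "+", subgroup, [],
                   le, re_, "full" if full else "truncated_both")


def test_assign_family_known_and_new(references):
    ref = references[0]
    rep = _element(ref.subgroup, "Synthetica alpha",
                   le_tet=ref.le_tetramer, re_tet=ref.re_tetramer)
    fams = [("fam0", ref.sequence, rep)]
    names = assign_family(fams, references, "Synthetica alpha")
    assert names["fam0"] == ref.name

    # >90% identical but mismatching RE tetramer -> new name
    rep_bad = _element(ref.subgroup, "Synthetica alpha",
                       le_tet=ref.le_tetramer, re_tet="GGGG")
    names = assign_family([("fam0", ref.sequence, rep_bad)], references,
                          "Synthetica alpha")
    assert names["fam0"] == "ISSal1"

    # two novel families in one species -> increments in family-id order
    rng = np.random.default_rng(9)
    novel1 = random_dna(rng, 900)
    novel2 = random_dna(rng, 900)
    e1 = _element("IS1341", "Escherichia coli")
    e2 = _element("IS1341", "Escherichia coli")
    names = assign_family([("famA", novel1, e1), ("famB", novel2, e2)],
                          references, "Escherichia coli")
    assert names == {"famA": "ISEco1", "famB": "ISEco2"}

    # no reference library -> everything new
    names = assign_family([("famA", novel1, e1)], [], "Escherichia coli")
    assert names["famA"] == "ISEco1"


def test_annotate_locus_recovers_planted_element(templates_by_subgroup, profile,
                                                 scan_threshold, references):
    t = templates_by_subgroup["IS605a"]
    rng = np.random.default_rng(13)
    ctx = random_dna(rng, 4400)
    contig = ctx[:2200] + t.sequence + ctx[2200:]
    g = Genome("gx", "Synthetica alpha", {"c1": contig})
    hits = scan_genome(profile, g, scan_threshold)
    assert len(hits) == 1
    loci = group_hits_to_loci(hits, g)
    decay_refs = [r.orfa_cds for r in references if r.orfa_cds]
    orfbs = [r.tnpb_protein for r in references]
    e = annotate_locus(loci[0], g.species, profile, scan_threshold,
                       decay_refs, orfbs)
    assert e is not None
    assert e.subgroup == "IS605a"
    assert e.completeness == "full"
    assert (e.start, e.end) == (2200, 2200 + t.length)
    assert not e.decay_flag
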