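"""From TnpB hits to classified elements.

Each profile hit seeds a locus (hit extended 1.7 kb both sides).  Within a
locus the pipeline predicts ORFs, assigns them roles (TnpB by profile
score; Y1 by the HuH triad with downstream catalytic Y and Q; SR by the
central catalytic serine), classifies the structural subgroup from the
ORF arrangement, locates the LE/RE subterminal repeats and their cleavage
tetramers, calls completeness, applies the IS1341 decay rule, and finally
names families as known or new against a reference library.

All boundary logic runs in element orientation (TnpB on the forward
strand); a locus seeded by a minus-strand hit is reverse-complemented
first and results are mapped back to contig coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align
from .genetics import encode_nt, revcomp, six_frame_translate, translate
from .motifs import find_sr_motif, find_y1_motif
from .profile import ProteinHit, RuvCProfile, score_local
from .repeats import best_direct_repeat, best_inverted_repeat
from .synth import Genome, ReferenceEntry, species_abbrev

GROUPS = ("IS605", "IS607", "IS1341")


@dataclass(frozen=True)
class AnnotationParams:
    """Tunables of the locus-annotation stage.

    The boundary search scans up to ``boundary_window`` nt outside the
    outermost ORF ends.  Inverted repeats need an arm of at least
    ``ir_min_arm`` nt (at most one mismatch); direct repeats a unit of
    ``dr_unit_min``..``dr_unit_max`` nt occurring at least twice within
    ``dr_span`` nt.  The arm/unit minima are set where a random 250-nt
    window has only a few-percent chance of a spurious structure, keeping
    truncated ends from being called full.
    """

    flank: int = 1700
    min_orf_codons: int = 50
    boundary_window: int = 250
    ir_min_arm: int = 11
    ir_max_arm: int = 40
    ir_loop_min: int = 3
    ir_loop_max: int = 15
    ir_max_mismatch: int = 1
    dr_unit_min: int = 9
    dr_unit_max: int = 12
    dr_span: int = 60
    dr_min_occ: int = 2
    max_partner_gap: int = 150
    max_partner_overlap_frac: float = 0.6   # of the partner ORF's length
    role_len_tolerance: int = 15
    tnpb_len_range: tuple[int, int] = (340, 489)
    tnpb_len_tolerance: int = 30
    y1_len_range: tuple[int, int] = (102, 164)
    sr_len_range: tuple[int, int] = (150, 217)
    decay_min_match: int = 20          # strictly more than this many matches
    decay_min_identity: float = 0.80
    decay_exact: bool = False          # exact-substring reading of the rule
    family_identity: float = 0.90
    min_orfb_identity: float = 0.30    # homology rescue for boundary-less loci


@dataclass
class Locus:
    genome_id: str
    contig_id: str
    start: int                  # contig coords, half-open
    end: int
    strand: str                 # strand of the seeding hit
    sequence: str
    hit_score: float = 0.0


@dataclass
class Orf:
    start: int                  # locus-relative, half-open, incl. stop codon
    end: int
    strand: str
    protein: str                # without the stop
    role: str = "unknown"
    motif_evidence: list = field(default_factory=list)
    score: float = 0.0          # profile bits when role == TnpB


@dataclass
class BoundaryCall:
    side: str                   # "LE" | "RE"
    repeat_kind: str            # "inverted" | "direct"
    repeat_start: int           # oriented-locus coords
    repeat_end: int
    stem_len: int               # arm length (inverted) or unit length
    loop_len: int
    cleavage_tetramer: str
    tetramer_start: int         # oriented-locus coords


@dataclass
class Element:
    genome_id: str
    species: str
    contig_id: str
    start: int                  # contig coords, half-open
    end: int
    strand: str                 # element orientation = TnpB strand
    subgroup: str               # IS605a..IS1341 or "unclassified"
    orfs: list[Orf] = field(default_factory=list)
    le: BoundaryCall | None = None
    re: BoundaryCall | None = None
    completeness: str = "truncated_both"
    decay_flag: bool = False
    family: str = ""
    tnpb_protein: str = ""
    orfa_protein: str = ""
    orfa_cds_seq: str = ""      # partner CDS, coding orientation
    sequence: str = ""          # element orientation
    locus_start: int = 0        # contig offset of the seeding locus

    @property
    def group(self) -> str:
        if self.decay_flag:
            return "decay"
        if self.subgroup == "IS1341":
            return "IS1341"
        if self.subgroup == "unclassified":
            return "unclassified"
        return self.subgroup[:5]

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------

def extract_locus(hit: ProteinHit, genome: Genome, flank: int = 1700) -> Locus:
    """Hit interval extended by flank nt each side, clipped to the contig."""
    contig = genome.contigs[hit.contig_id]
    s = max(0, hit.genomic_start - flank)
    e = min(len(contig), hit.genomic_end + flank)
    return Locus(genome.genome_id, hit.contig_id, s, e, hit.strand,
                 contig[s:e], hit.score)


def group_hits_to_loci(hits: list[ProteinHit], genome: Genome,
                       flank: int = 1700) -> list[Locus]:
    """One locus per group of overlapping hits (any frame), seeded by the
    best-scoring hit of the group.  Hits of one element found in several
    frames collapse here; distinct nearby elements stay separate because
    their hit intervals do not overlap."""
    by_contig: dict[str, list[ProteinHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    loci = []
    for cid in sorted(by_contig):
        hs = sorted(by_contig[cid], key=lambda h: (h.genomic_start, h.genomic_end))
        group: list[ProteinHit] = []
        group_end = -1
        for h in hs + [None]:
            if h is not None and (not group or h.genomic_start < group_end):
                group.append(h)
                group_end = max(group_end, h.genomic_end)
                continue
            if group:
                best = max(group, key=lambda g: g.score)
                loci.append(extract_locus(best, genome, flank))
            if h is not None:
                group = [h]
                group_end = h.genomic_end
        # (final group flushed by the None sentinel)
    return loci


def find_orfs(sequence: str, min_codons: int = 50) -> list[Orf]:
    """Maximal ORFs on both strands: start codon ATG/GTG/TTG, in-frame
    stop, protein length >= min_codons.  Within one stop-to-stop frame
    segment only the longest start-to-stop ORF is reported.

    Coordinates are forward-strand, half-open, and include the stop codon.
    """
    n = len(sequence)
    out = []
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else revcomp(sequence)
        for off in range(3):
            seg_start_codon = None
            for p in range(off, n - 2, 3):
                codon = seq[p:p + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    if seg_start_codon is not None:
                        aa_len = (p - seg_start_codon) // 3
                        if aa_len >= min_codons:
                            s, e = seg_start_codon, p + 3
                            if strand == "-":
                                s, e = n - e, n - s
                            prot = translate(seq[seg_start_codon:p])
                            out.append(Orf(s, e, strand, prot))
                    seg_start_codon = None
                elif seg_start_codon is None and codon in ("ATG", "GTG", "TTG"):
                    seg_start_codon = p
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def assign_role(orf: Orf, profile: RuvCProfile, score_threshold: float,
                params: AnnotationParams = AnnotationParams()) -> Orf:
    """Assign TnpB/Y1/SR/unknown in place (precedence TnpB > Y1 > SR)."""
    n = len(orf.protein)
    tol = params.role_len_tolerance
    evidence: list = []

    sc, cols, span = score_local(profile, orf.protein)
    b_lo = params.tnpb_len_range[0] - params.tnpb_len_tolerance
    b_hi = params.tnpb_len_range[1] + params.tnpb_len_tolerance
    if sc >= score_threshold and b_lo <= n <= b_hi:
        orf.role = "TnpB"
        orf.score = sc
        orf.motif_evidence = [("RuvC_profile", span[0])]
        return orf

    y_lo, y_hi = params.y1_len_range[0] - tol, params.y1_len_range[1] + tol
    if y_lo <= n <= y_hi:
        m = find_y1_motif(orf.protein)
        if m is not None:
            i, j, k = m
            orf.role = "Y1"
            orf.motif_evidence = [("HuH", i), ("Y", j), ("Q", k)]
            return orf

    s_lo, s_hi = params.sr_len_range[0] - tol, params.sr_len_range[1] + tol
    if s_lo <= n <= s_hi:
        pos = find_sr_motif(orf.protein)
        if pos is not None:
            orf.role = "SR"
            orf.motif_evidence = [("catalytic_S", pos)]
            return orf

    orf.role = "unknown"
    return orf


def _pick_tnpb_and_partner(orfs: list[Orf],
                           params: AnnotationParams) -> tuple[Orf | None, Orf | None, int]:
    """The element's TnpB ORF and its adjacent ORFA partner (Y1/SR).

    The partner must sit on the LE side of TnpB (upstream in TnpB
    orientation) within max_partner_gap nt; the nearest qualifying ORF
    wins.  Returns (tnpb, partner, n_tnpb)."""
    tnpbs = [o for o in orfs if o.role == "TnpB"]
    if not tnpbs:
        return None, None, 0
    tnpb = max(tnpbs, key=lambda o: o.score)
    cands = []
    for o in orfs:
        if o.role not in ("Y1", "SR"):
            continue
        if tnpb.strand == "+":
            gap = tnpb.start - o.end
            upstream = o.start < tnpb.start
        else:
            gap = o.start - tnpb.end
            upstream = o.end > tnpb.end
        # A genuine same-strand ORFA abuts or partially overlaps the TnpB
        # start (the predicted TnpB start can slide upstream through
        # ORFA's tail); an opposite-strand ORFA never overlaps.  ORFs
        # reaching deep into the TnpB CDS are antisense/frame noise.
        if o.strand == tnpb.strand:
            max_ov = min(160.0,
                         params.max_partner_overlap_frac * (o.end - o.start))
        else:
            max_ov = 0.0
        if upstream and -max_ov <= gap <= params.max_partner_gap:
            cands.append((max(gap, 0), o.start, o))
    partner = min(cands, key=lambda t: (t[0], t[1]))[2] if cands else None
    return tnpb, partner, len(tnpbs)


def classify_subgroup(orfs: list[Orf],
                      params: AnnotationParams = AnnotationParams()) -> str:
    """Structural subgroup from role-assigned ORFs.

    (Y1, TnpB) same strand overlapping -> IS605a; separated -> IS605b;
    opposite strands -> IS605c.  (SR, TnpB) same strand overlapping ->
    IS607a; separated -> IS607b.  TnpB alone -> IS1341.  Anything else is
    unclassified.  Raises if no TnpB ORF is present.
    """
    tnpb, partner, n_tnpb = _pick_tnpb_and_partner(orfs, params)
    if tnpb is None:
        raise ValueError("a TCME requires a TnpB ORF")
    if n_tnpb > 1:
        return "unclassified"
    if partner is None:
        return "IS1341"
    overlap = min(tnpb.end, partner.end) - max(tnpb.start, partner.start)
    same = partner.strand == tnpb.strand
    if partner.role == "Y1":
        if not same:
            return "IS605c"
        return "IS605a" if overlap >= 1 else "IS605b"
    if same:
        return "IS607a" if overlap >= 1 else "IS607b"
    return "unclassified"


def detect_boundaries(oriented_seq: str, orf_lo: int, orf_hi: int,
                      params: AnnotationParams = AnnotationParams()
                      ) -> tuple[BoundaryCall | None, BoundaryCall | None]:
    """LE/RE subterminal repeats in element orientation.

    Searches up to boundary_window nt outside [orf_lo, orf_hi): first for
    an inverted repeat (longest stem, ties closest to the ORFs), then for
    a direct-repeat array.  The cleavage tetramer is the 4 nt immediately
    external to the accepted repeat; a side with no structure, or whose
    tetramer falls off the sequence, is reported absent.
    """
    n = len(oriented_seq)
    ir_kw = dict(min_arm=params.ir_min_arm, max_arm=params.ir_max_arm,
                 loop_min=params.ir_loop_min, loop_max=params.ir_loop_max,
                 max_mismatch=params.ir_max_mismatch)
    dr_kw = dict(unit_min=params.dr_unit_min, unit_max=params.dr_unit_max,
                 span=params.dr_span, min_occurrences=params.dr_min_occ)

    inv: dict[str, BoundaryCall | None] = {}
    dirc: dict[str, BoundaryCall | None] = {}
    for side in ("LE", "RE"):
        if side == "LE":
            ws, we = max(0, orf_lo - params.boundary_window), orf_lo
            prefer_right = True
        else:
            ws, we = orf_hi, min(n, orf_hi + params.boundary_window)
            prefer_right = False
        window = oriented_seq[ws:we]
        inv[side] = dirc[side] = None
        if window:
            ir = best_inverted_repeat(window, prefer_right, **ir_kw)
            if ir is not None:
                inv[side] = _tetramer_call(oriented_seq, side, "inverted",
                                           ws + ir.arm1_start, ws + ir.end,
                                           ir.arm_len, ir.loop_len)
            dr = best_direct_repeat(window, prefer_right, **dr_kw)
            if dr is not None:
                dirc[side] = _tetramer_call(oriented_seq, side, "direct",
                                            ws + dr.unit_start, ws + dr.end,
                                            dr.unit_len, 0)
    # One repeat mode per element: palindromic ends (IS605/IS1341) or
    # direct-repeat ends (IS607).  The mode explaining more sides wins;
    # ties go to inverted.  Per-side mixing would let a chance hairpin in
    # flanking DNA displace one end of a direct-repeat element.
    n_inv = sum(c is not None for c in inv.values())
    n_dir = sum(c is not None for c in dirc.values())
    calls = inv if n_inv >= n_dir else dirc
    return calls["LE"], calls["RE"]


def _tetramer_call(seq: str, side: str, kind: str, rs: int, re_: int,
                   stem: int, loop: int) -> BoundaryCall | None:
    if side == "LE":
        ts = rs - 4
        if ts < 0:
            return None
        tet = seq[ts:rs]
    else:
        ts = re_
        if ts + 4 > len(seq):
            return None
        tet = seq[ts:ts + 4]
    return BoundaryCall(side, kind, rs, re_, stem, loop, tet, ts)


def call_completeness(le: BoundaryCall | None, re: BoundaryCall | None) -> str:
    """Full means both ends present with identifiable cleavage sites."""
    if le is not None and re is not None:
        return "full"
    if le is None and re is None:
        return "truncated_both"
    return "truncated_RE" if re is None else "truncated_LE"


# ---------------------------------------------------------------------------
# decay rule

def _local_nt(a: str, b: str) -> tuple[float, int, int]:
    """Best local nucleotide alignment (match +1, mismatch -1, gap open 4
    extend 2); returns (score, matches, cols).  Gaps are priced stiffly:
    a decayed ORFA remnant is a contiguous stretch, and cheap gaps would
    let a short seed chain with distant chance matches across the flank."""
    sc, matches, cols, *_ = _align.local_affine(
        encode_nt(a.upper()), encode_nt(b.upper()), 1.0, -1.0, 4.0, 2.0)
    return sc, matches, cols


def has_flank_remnant(up: str, down: str, references: list[str],
                      min_match: int = 20, min_identity: float = 0.80,
                      exact: bool = False) -> bool:
    """True when either flank region carries a local alignment to any
    reference CDS (either orientation) with strictly more than min_match
    identical positions at >= min_identity."""
    for region in (up, down):
        if len(region) <= min_match:
            continue
        for ref in references:
            for r in (ref, revcomp(ref)):
                if exact:
                    if _longest_shared_substring_at_least(region, r, min_match + 1):
                        return True
                    continue
                _sc, matches, cols = _local_nt(region, r)
                if matches > min_match and cols > 0 and matches / cols >= min_identity:
                    return True
    return False


def _longest_shared_substring_at_least(a: str, b: str, k: int) -> bool:
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def decay_filter(element: Element, tnpb: Orf, oriented_seq: str,
                 references: list[str],
                 params: AnnotationParams = AnnotationParams()) -> bool:
    """IS1341 decay rule: flag the element when the regions between its
    boundaries and the TnpB CDS carry a Y1/SR-derived remnant."""
    if element.subgroup != "IS1341":
        return False
    if not references:
        return False
    up_start = element.le.tetramer_start if element.le else max(0, tnpb.start - params.boundary_window)
    down_end = (element.re.tetramer_start + 4) if element.re else min(
        len(oriented_seq), tnpb.end + params.boundary_window)
    up = oriented_seq[up_start:tnpb.start]
    down = oriented_seq[tnpb.end:down_end]
    return has_flank_remnant(up, down, references,
                             params.decay_min_match, params.decay_min_identity,
                             params.decay_exact)


# ---------------------------------------------------------------------------
# locus -> element driver

def annotate_locus(locus: Locus, species: str, profile: RuvCProfile,
                   score_threshold: float, decay_references: list[str],
                   reference_orfbs: list[str] | None = None,
                   params: AnnotationParams = AnnotationParams()) -> Element | None:
    """Classify one locus; returns None for loci that fail every retention
    rule (no TnpB ORF, or no boundaries and no ORFB homology)."""
    orfs = find_orfs(locus.sequence, params.min_orf_codons)
    for o in orfs:
        assign_role(o, profile, score_threshold, params)

    n = len(locus.sequence)

    def interpret(cand_orfs):
        tnpb, partner, _nt = _pick_tnpb_and_partner(cand_orfs, params)
        if tnpb is None:
            return None
        subgroup = classify_subgroup(cand_orfs, params)
        strand = tnpb.strand
        if strand == "+":
            oriented = locus.sequence
            o_tnpb = tnpb
            o_partner = partner
        else:
            oriented = revcomp(locus.sequence)
            o_tnpb = Orf(n - tnpb.end, n - tnpb.start, "+", tnpb.protein,
                         tnpb.role, tnpb.motif_evidence, tnpb.score)
            o_partner = None
            if partner is not None:
                o_partner = Orf(n - partner.end, n - partner.start,
                                "-" if partner.strand == "+" else "+",
                                partner.protein, partner.role,
                                partner.motif_evidence, partner.score)
        core = [o_tnpb] + ([o_partner] if o_partner else [])
        orf_lo = min(o.start for o in core)
        orf_hi = max(o.end for o in core)
        le, re = detect_boundaries(oriented, orf_lo, orf_hi, params)
        o_start = le.tetramer_start if le else orf_lo
        o_end = (re.tetramer_start + 4) if re else orf_hi
        outside = (o_partner is not None and le is not None and re is not None
                   and (o_partner.start < o_start - 10
                        or o_partner.end > o_end + 10))
        return dict(tnpb=tnpb, partner=partner, subgroup=subgroup,
                    strand=strand, oriented=oriented, o_tnpb=o_tnpb,
                    le=le, re=re, o_start=o_start, o_end=o_end,
                    n_bounds=(le is not None) + (re is not None),
                    outside=outside)

    A = interpret(orfs)
    if A is None:
        return None
    # Best-supported interpretation: a "partner" that sits outside the
    # detected element, or whose inclusion costs a boundary, is flank
    # context rather than the element's ORFA.
    if A["partner"] is not None and (A["outside"] or A["n_bounds"] < 2):
        B = interpret([o for o in orfs if o is not A["partner"]])
        if B is not None and (B["n_bounds"] > A["n_bounds"]
                              or (A["outside"] and B["n_bounds"] >= A["n_bounds"])):
            A = B
    tnpb = A["tnpb"]
    partner = A["partner"]
    subgroup = A["subgroup"]
    strand = A["strand"]
    oriented = A["oriented"]
    o_tnpb = A["o_tnpb"]
    le, re = A["le"], A["re"]
    o_start, o_end = A["o_start"], A["o_end"]
    completeness = call_completeness(le, re)
    if strand == "+":
        c_start, c_end = locus.start + o_start, locus.start + o_end
    else:
        c_start, c_end = locus.end - o_end, locus.end - o_start

    elem = Element(
        genome_id=locus.genome_id, species=species, contig_id=locus.contig_id,
        start=c_start, end=c_end, strand=strand, subgroup=subgroup,
        orfs=orfs, le=le, re=re, completeness=completeness,
        tnpb_protein=tnpb.protein,
        orfa_protein=partner.protein if partner else "",
        sequence=oriented[o_start:o_end], locus_start=locus.start)
    if partner is not None:
        cds = locus.sequence[partner.start:partner.end]
        elem.orfa_cds_seq = cds if partner.strand == "+" else revcomp(cds)

    if subgroup == "IS1341":
        elem.decay_flag = decay_filter(elem, o_tnpb, oriented,
                                       decay_references, params)

    if completeness == "truncated_both":
        # retained only with homology to the reference ORFB set
        if reference_orfbs:
            from .cluster import pairwise_identity
            best = max((pairwise_identity(tnpb.protein, r)
                        for r in reference_orfbs), default=0.0)
            if best < params.min_orfb_identity:
                return None
    return elem


# ---------------------------------------------------------------------------
# family naming

def assign_family(families: list[tuple[str, str, Element]],
                  references: list[ReferenceEntry], species: str,
                  start_index: int = 1,
                  params: AnnotationParams = AnnotationParams()) -> dict[str, str]:
    """Known/new family names for one species' consensus families.

    ``families`` holds (family_id, consensus_sequence, representative
    element).  A family keeps a library name when its consensus is > 90%
    identical to that reference, both boundary repeats were detected on
    the representative, and both cleavage tetramers match the reference.
    Otherwise it becomes IS<Abbrev><n> with n counting per species in
    family-id order.
    """
    from .cluster import pairwise_identity

    ab = species_abbrev(species)
    names: dict[str, str] = {}
    counter = start_index
    for fid, cons, rep in sorted(families, key=lambda t: t[0]):
        named = ""
        if references and rep.le is not None and rep.re is not None:
            for ref in references:
                if pairwise_identity(cons, ref.sequence) > params.family_identity \
                        and rep.le.cleavage_tetramer == ref.le_tetramer \
                        and rep.re.cleavage_tetramer == ref.re_tetramer:
                    named = ref.name
                    break
        if not named:
            named = f"IS{ab}{counter}"
            counter += 1
        names[fid] = named
    return names
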