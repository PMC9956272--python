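"""Synthetic bacterial genomes with planted TnpB-containing mobile elements.

The generator builds element templates for the six structural subgroups
(IS605a/b/c, IS607a/b, IS1341), plants diverged copies of them into random
multi-contig genomes across a panel of pseudo-species, and records every
copy in a machine-readable truth ledger.  It also emits the ancillary
inputs the mining pipeline needs: a set of TnpB-like seed proteins sharing
a common RuvC core (for profile building), distant outgroup proteins, and
a reference element library.

Element anatomy (canonical orientation, TnpB on the forward strand)::

    [tet][LE repeat]--spacer--[ORFA][TnpB]--spacer--[RE repeat][tet]

IS605/IS1341 ends are palindromic (inverted-repeat stems); IS607 ends are
short direct-repeat arrays with no inverted repeat.  The 4-nt cleavage
sites sit immediately external to each subterminal repeat.  IS605a/IS607a
have ORFA and TnpB overlapping by 4 nt (the classical ATGA junction where
the ORFA stop overlaps the TnpB start), the b-types are separated on the
same strand, IS605c carries ORFA on the opposite strand, and IS1341
encodes TnpB alone.

Divergence is applied as substitutions at a configured expected rate.
Substitutions are resampled away from a small protected set — start/stop
codons, catalytic-motif codons, subterminal repeat arms and cleavage
tetramers — and never introduce an in-frame stop: planted copies emulate
functional element families under purifying selection, not neutrally
decaying pseudogenes (decayed copies are planted explicitly instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (AA_ALPHABET, STOP_CODONS, decode_nt, encode_nt,
                       revcomp, reverse_translate, translate)
from .motifs import find_y1_motif
from .repeats import (best_direct_repeat, best_inverted_repeat,
                      find_inverted_repeats)

SUBGROUPS = ("IS605a", "IS605b", "IS605c", "IS607a", "IS607b", "IS1341")

DEFAULT_SPECIES = (
    "Synthetica alpha", "Synthetica bravo", "Synthetica charlie",
    "Synthetica delta", "Synthetica echo", "Synthetica foxtrot",
)

#: shared seed for the ancestral RuvC core, so independently generated
#: templates and profile seed proteins describe the same domain family
DEFAULT_ANCESTOR_SEED = 523

RUVC_CORE_LEN = 120
RUVC_CATALYTIC = (12, 60, 102)  # D, E, D — RuvC I/II/III order


@dataclass(frozen=True)
class GroupPriors:
    """Published length ranges of the element groups and their proteins
    (nt for elements, aa for proteins; inclusive)."""

    is605_length_range: tuple[int, int] = (1740, 1950)
    is607_length_range: tuple[int, int] = (1620, 2400)
    is1341_short_range: tuple[int, int] = (1252, 1393)
    is1341_long_range: tuple[int, int] = (1512, 2382)
    y1_len_range: tuple[int, int] = (102, 164)
    sr_len_range: tuple[int, int] = (150, 217)
    tnpb_len_range: tuple[int, int] = (340, 489)
    is1341_tnpb_len_range: tuple[int, int] = (362, 489)

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class BoundarySpec:
    """A planted subterminal repeat (element-relative coordinates)."""

    kind: str                      # "inverted" | "direct"
    start: int                     # first nt of the repeat structure
    end: int                       # one past the last nt
    arm_len: int                   # stem length (inverted) or unit length
    loop_len: int                  # loop (inverted) / 0 for direct
    tetramer: str                  # 4-nt cleavage site external to the repeat


@dataclass
class ElementTemplate:
    template_id: str
    subgroup: str
    sequence: str                  # canonical orientation: TnpB on +
    tnpb_cds: tuple[int, int]      # incl. stop codon, forward strand
    orfa_cds: tuple[int, int] | None
    orfa_strand: str               # "+", "-" or "" when absent
    orfa_role: str                 # "Y1", "SR" or ""
    tnpb_protein: str
    orfa_protein: str
    le: BoundarySpec
    re: BoundarySpec
    cds_list: tuple[tuple[int, int, str], ...]   # for stop-safe mutation
    protected: frozenset[int]      # element positions never substituted
    orfa_separate: bool            # ORFA replaceable (decay surgery possible)

    @property
    def group(self) -> str:
        return self.subgroup[:5] if self.subgroup != "IS1341" else "IS1341"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulate→mine experiments."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    n_genomes_per_species: int = 20
    genome_length: int = 500_000
    n_contigs: int = 2
    gc_content: float = 0.5
    copy_number_distribution: dict[str, float] = field(
        default_factory=lambda: {sg: 1.0 for sg in SUBGROUPS})
    divergence: float = 0.04
    truncation_fraction: float = 0.10
    decay_fraction: float = 0.10
    decay_remnant_len: int = 25
    min_separation: int = 3500     # nt between planted elements
    poisson_copy_numbers: bool = True   # False: means are exact counts
    seed: int = 0

    def __post_init__(self):
        for f in ("gc_content", "divergence", "truncation_fraction", "decay_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.n_genomes_per_species < 1 or self.genome_length < 1 or self.n_contigs < 1:
            raise ValueError("counts and lengths must be positive")
        if any(v < 0 for v in self.copy_number_distribution.values()):
            raise ValueError("copy numbers must be nonnegative")


@dataclass
class Genome:
    genome_id: str
    species: str
    contigs: dict[str, str]


@dataclass
class TruthRecord:
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    subgroup: str
    completeness: str   # full | truncated_LE | truncated_RE | truncated_both | decay
    template_id: str
    planted_seq: str = ""          # forward-strand sequence as planted


@dataclass
class TruthLedger:
    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_rows(self):
        return [(r.genome_id, r.contig_id, r.start, r.end, r.strand,
                 r.subgroup, r.completeness, r.template_id) for r in self.records]


@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    subgroup: str
    sequence: str
    le_tetramer: str
    re_tetramer: str
    tnpb_protein: str
    orfa_protein: str
    orfa_role: str
    orfa_cds: str = ""          # nucleotide CDS (coding orientation)


# ---------------------------------------------------------------------------
# proteins

def _rand_protein(rng: np.random.Generator, n: int) -> list[str]:
    return [AA_ALPHABET[i] for i in rng.integers(0, 20, n)]


def ruvc_ancestor(seed: int = DEFAULT_ANCESTOR_SEED) -> str:
    """The ancestral RuvC-domain core shared by all synthetic TnpBs."""
    rng = np.random.default_rng(seed)
    core = _rand_protein(rng, RUVC_CORE_LEN)
    d1, e2, d3 = RUVC_CATALYTIC
    core[d1] = "D"
    core[e2] = "E"
    core[d3] = "D"
    return "".join(core)


def mutate_protein(p: str, rate: float, rng: np.random.Generator,
                   protected: frozenset[int] = frozenset()) -> str:
    out = list(p)
    free = [i for i in range(len(p)) if i not in protected]
    n = rng.binomial(len(p), rate)
    n = min(n, len(free))
    for i in rng.choice(len(free), size=n, replace=False):
        pos = free[i]
        alts = [a for a in AA_ALPHABET if a != out[pos]]
        out[pos] = alts[rng.integers(len(alts))]
    return "".join(out)


def _make_y1(rng: np.random.Generator, n: int) -> tuple[str, frozenset[int]]:
    """Y1 transposase: HuH triad plus downstream catalytic Y then Q."""
    p = _rand_protein(rng, n)
    p[0] = "M"
    i0 = max(20, n // 3)
    p[i0] = "H"
    p[i0 + 1] = "LIVF"[rng.integers(4)]
    p[i0 + 2] = "H"
    y, q = n - 20, n - 8
    p[y] = "Y"
    p[q] = "Q"
    return "".join(p), frozenset({0, i0, i0 + 1, i0 + 2, y, q})


def _make_sr(rng: np.random.Generator, n: int) -> tuple[str, frozenset[int]]:
    """Serine recombinase: catalytic S in the central domain.  Resampled
    until free of a chance HuH-Y-Q pattern, which would let the Y1 rule
    (which outranks SR) claim the protein."""
    for _ in range(200):
        p = _rand_protein(rng, n)
        p[0] = "M"
        s = n // 2
        p[s] = "S"
        cand = "".join(p)
        if find_y1_motif(cand) is None:
            return cand, frozenset({0, s})
    raise ValueError("could not sample an SR protein free of the Y1 motif")


def _make_tnpb(rng: np.random.Generator, n: int, ancestor: str,
               family_divergence: float) -> tuple[str, frozenset[int]]:
    """TnpB: family-diverged RuvC core embedded between random flanks."""
    core_len = len(ancestor)
    if n < core_len + 50:
        raise ValueError("TnpB length prior too small for the RuvC core")
    cat = frozenset(RUVC_CATALYTIC)
    core = mutate_protein(ancestor, family_divergence, rng, cat)
    off_max = n - core_len - 20
    off = int(rng.integers(25, off_max + 1)) if off_max > 25 else 25
    p = _rand_protein(rng, n)
    p[0] = "M"
    p[off:off + core_len] = list(core)
    prot = {0} | {off + i for i in RUVC_CATALYTIC}
    return "".join(p), frozenset(prot)


_START_CODONS = ("ATG", "GTG", "TTG")


def _upstream_extension(seq: str, s: int) -> int:
    """Codons by which a forward-frame ORF starting at s could extend
    upstream before an in-frame stop (the ORF caller reports the earliest
    start codon in the stop-to-stop segment)."""
    p = s - 3
    while p >= 0 and seq[p:p + 3] not in STOP_CODONS:
        p -= 3
    q = p + 3
    while q < s:
        if seq[q:q + 3] in _START_CODONS:
            return (s - q) // 3
        q += 3
    return 0


def _upstream_extension_rev(seq: str, e: int) -> int:
    """Same for a reverse-strand ORF whose CDS ends (element coords) at e."""
    n = len(seq)
    p = e
    while p + 3 <= n and revcomp(seq[p:p + 3]) not in STOP_CODONS:
        p += 3
    q = p - 3
    while q >= e:
        if revcomp(seq[q:q + 3]) in _START_CODONS:
            return (q + 3 - e) // 3
        q -= 3
    return 0


def _codon_positions(aa_positions: frozenset[int], cds_start: int) -> set[int]:
    out = set()
    for a in aa_positions:
        base = cds_start + 3 * a
        out.update((base, base + 1, base + 2))
    return out


# ---------------------------------------------------------------------------
# template assembly

def _rand_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return decode_nt(rng.choice(4, size=n, p=p).astype(np.int8))


def _ir_block(rng: np.random.Generator) -> tuple[str, int, int]:
    """A perfect palindromic stem-loop; returns (seq, arm_len, loop_len)."""
    arm_len = int(rng.integers(14, 19))
    loop_len = int(rng.integers(4, 9))
    arm = _rand_nt(rng, arm_len)
    loop = _rand_nt(rng, loop_len)
    return arm + loop + revcomp(arm), arm_len, loop_len


def _dr_block(rng: np.random.Generator) -> tuple[str, int]:
    """A direct-repeat array: three copies of a 12-nt unit with short
    random joints; returns (seq, unit_len).  The unit sits at the top of
    the detector's unit range so chance repeats cannot outrank it."""
    u = 12
    unit = _rand_nt(rng, u)
    g1 = _rand_nt(rng, int(rng.integers(3, 7)))
    g2 = _rand_nt(rng, int(rng.integers(3, 7)))
    return unit + g1 + unit + g2 + unit, u


def _has_detectable_ir(seq: str) -> bool:
    return bool(find_inverted_repeats(seq))


_GROUP_RANGE = {
    "IS605a": "is605_length_range", "IS605b": "is605_length_range",
    "IS605c": "is605_length_range",
    "IS607a": "is607_length_range", "IS607b": "is607_length_range",
    "IS1341": "is1341_short_range",
}


def _sample_tetramer(rng: np.random.Generator) -> str:
    return _rand_nt(rng, 4)


def make_template(subgroup: str, priors: GroupPriors, rng: np.random.Generator,
                  template_id: str, ancestor: str | None = None,
                  family_divergence: float = 0.12,
                  max_tries: int = 400) -> ElementTemplate:
    """Build one element template of the requested subgroup.

    Raises ValueError when the length priors cannot accommodate the ORFs,
    repeats and minimum spacers, naming the violated constraint.
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    if ancestor is None:
        ancestor = ruvc_ancestor()
    lo, hi = getattr(priors, _GROUP_RANGE[subgroup])
    is607 = subgroup.startswith("IS607")
    is1341 = subgroup == "IS1341"
    overlap_type = subgroup in ("IS605a", "IS607a")
    reverse_orfa = subgroup == "IS605c"

    last_err = "no attempt made"
    for _try in range(max_tries):
        total = int(rng.integers(lo, hi + 1))
        # ends
        if is607:
            le_seq, le_arm = _dr_block(rng)
            re_seq, re_arm = _dr_block(rng)
            le_loop = re_loop = 0
        else:
            le_seq, le_arm, le_loop = _ir_block(rng)
            re_seq, re_arm, re_loop = _ir_block(rng)
        le_tet = _sample_tetramer(rng)
        re_tet = _sample_tetramer(rng)
        ends_len = 8 + len(le_seq) + len(re_seq)

        # proteins
        if is1341:
            nb = int(rng.integers(*_incl(priors.is1341_tnpb_len_range)))
            na = 0
        elif is607:
            nb = int(rng.integers(*_incl((361, 447))))
            na = int(rng.integers(*_incl(priors.sr_len_range)))
        else:
            nb = int(rng.integers(*_incl(priors.tnpb_len_range)))
            na = int(rng.integers(*_incl(priors.y1_len_range)))
        cds_b = 3 * nb + 3
        cds_a = 3 * na + 3 if na else 0
        gap_ab = 0 if (overlap_type or is1341) else int(rng.integers(10, 41))
        coding_len = cds_a + gap_ab + cds_b - (4 if overlap_type else 0)

        budget = total - ends_len - coding_len
        if budget < 16:
            last_err = (f"{subgroup}: length range ({lo},{hi}) too small for "
                        f"ORFs+repeats (needed {ends_len + coding_len + 16})")
            continue
        # each end structure (tetramer + repeat + spacer) must fit inside
        # the 250-nt boundary search window anchored at the ORF edge
        s1_cap = 250 - (4 + len(le_seq)) - 4
        s2_cap = 250 - (4 + len(re_seq)) - 4
        s1_lo, s1_hi = max(8, budget - s2_cap), min(s1_cap, budget - 8)
        if s1_lo > s1_hi:
            last_err = f"{subgroup}: spacer budget {budget} not splittable"
            continue
        s1 = int(rng.integers(s1_lo, s1_hi + 1))
        s2 = budget - s1

        # build proteins / CDS
        if is1341:
            pa, prot_a = "", frozenset()
        elif is607:
            pa, prot_a = _make_sr(rng, na)
        else:
            pa, prot_a = _make_y1(rng, na)
        pb, prot_b = _make_tnpb(rng, nb, ancestor, family_divergence)
        if overlap_type:
            pa = pa[:-1] + "E"          # forced codon GAA: ORFA CDS ends ...A
            pb = pb[0] + "T" + pb[2:]   # Thr codons ACx: TnpB codon 2 starts A
        cdsA = reverse_translate(pa, rng) if pa else ""
        if overlap_type:
            cdsA = cdsA[:-3] + "GAA"
        cdsB = reverse_translate(pb, rng)
        stopA = STOP_CODONS[rng.integers(3)] if pa else ""
        stopB = STOP_CODONS[rng.integers(3)]

        # Guard stop codons immediately 5' of each ORF start (in that ORF's
        # frame) pin the predicted start to the annotated one: without them
        # a chance upstream in-frame start codon would extend the ORF,
        # blurring the overlapping/separated distinction and the protein
        # length windows.
        spacer1 = _rand_nt(rng, s1)
        spacer2 = _rand_nt(rng, s2)
        gap_seq = _rand_nt(rng, gap_ab)
        if is1341:
            spacer1 = spacer1[:-3] + "TAA"          # TnpB guard
        else:
            spacer1 = spacer1[:-3] + "TAA"          # ORFA guard (a/b/c)
        if gap_ab:
            if reverse_orfa:
                # ORFA reads right-to-left: its guard sits at the gap start
                gap_seq = "TTA" + gap_seq[3:]
            gap_seq = gap_seq[:-3] + "TAA"          # TnpB guard

        # assemble coding block + element-relative coordinates
        pos = 0
        seq_parts = [le_tet, le_seq, spacer1]
        pos = 4 + len(le_seq) + s1
        if is1341:
            orfa_iv = None
            orfa_strand = ""
            tnpb_iv = (pos, pos + cds_b)
            seq_parts.append(cdsB + stopB)
            pos += cds_b
            orfa_sep = False
        elif overlap_type:
            # classical ATGA junction: ORFA's stop TGA overlaps the TnpB ATG
            # shifted one frame — cdsA ends ...A, then "TG", then TnpB codon 2
            # (which starts with A, completing both TGA and ATG).
            orfa_iv = (pos, pos + cds_a)
            orfa_strand = "+"
            tb = pos + cds_a - 4
            coding = cdsA + "TG" + cdsB[3:] + stopB
            tnpb_iv = (tb, tb + cds_b)
            seq_parts.append(coding)
            pos += len(coding)
            orfa_sep = False
        else:
            a_region = cdsA + stopA
            if reverse_orfa:
                a_region = revcomp(a_region)
                orfa_strand = "-"
            else:
                orfa_strand = "+"
            orfa_iv = (pos, pos + cds_a)
            seq_parts.append(a_region)
            pos += cds_a
            seq_parts.append(gap_seq)
            pos += gap_ab
            tnpb_iv = (pos, pos + cds_b)
            seq_parts.append(cdsB + stopB)
            pos += cds_b
            orfa_sep = True
        seq_parts += [spacer2, re_seq, re_tet]
        seq = "".join(seq_parts)
        if len(seq) != total:
            last_err = f"{subgroup}: assembly arithmetic off ({len(seq)} != {total})"
            continue

        # verify the reading frames
        tnpb_nt = seq[tnpb_iv[0]:tnpb_iv[1]]
        if translate(tnpb_nt) != pb + "*":
            last_err = f"{subgroup}: TnpB frame corrupted in assembly"
            continue
        if orfa_iv is not None:
            a_nt = seq[orfa_iv[0]:orfa_iv[1]]
            if orfa_strand == "-":
                a_nt = revcomp(a_nt)
            if translate(a_nt) != pa + "*":
                last_err = f"{subgroup}: ORFA frame corrupted in assembly"
                continue

        # predicted ORF starts must coincide with the annotated ones
        ext_b = _upstream_extension(seq, tnpb_iv[0])
        if overlap_type:
            # no guard is possible inside ORFA's coding sequence, so the
            # predicted TnpB start may slide upstream to a chance start
            # codon; the nearest in-frame stop bounds that slide.  Keep it
            # short enough that the ORFA/TnpB overlap stays a minor
            # fraction of ORFA and the TnpB stays inside its length window,
            # and protect the bounding stop against substitutions.
            p = tnpb_iv[0] - 3
            while p >= 0 and seq[p:p + 3] not in STOP_CODONS:
                p -= 3
            slide = tnpb_iv[0] - (p + 3)
            if p < 0 or slide > 150:
                last_err = f"{subgroup}: TnpB start slide too long ({slide})"
                continue
            if nb + slide // 3 > 505:
                last_err = f"{subgroup}: TnpB extension exceeds length window"
                continue
            bound_stop = (p, p + 3)
        elif ext_b != 0:
            last_err = f"{subgroup}: TnpB guard failed"
            continue
        else:
            bound_stop = None
        if orfa_iv is not None:
            if orfa_strand == "+":
                ext_a = _upstream_extension(seq, orfa_iv[0])
            else:
                ext_a = _upstream_extension_rev(seq, orfa_iv[1])
            if ext_a != 0:
                last_err = f"{subgroup}: ORFA guard failed"
                continue

        le_spec = BoundarySpec("direct" if is607 else "inverted",
                               4, 4 + len(le_seq), le_arm, le_loop, le_tet)
        re_start = len(seq) - 4 - len(re_seq)
        re_spec = BoundarySpec("direct" if is607 else "inverted",
                               re_start, re_start + len(re_seq),
                               re_arm, re_loop, re_tet)

        # The end regions (outside the outermost ORFs) must be recovered
        # exactly by the boundary detector: the planted repeat has to be the
        # unique best structure, with no chance extension or competitor.
        orf_lo = min(tnpb_iv[0], orfa_iv[0] if orfa_iv else tnpb_iv[0])
        orf_hi = max(tnpb_iv[1], orfa_iv[1] if orfa_iv else tnpb_iv[1])
        left_region = seq[:orf_lo]
        right_region = seq[orf_hi:]
        if is607:
            if _has_detectable_ir(left_region) or _has_detectable_ir(right_region):
                last_err = f"{subgroup}: stray inverted repeat in end region"
                continue
            rstart = len(right_region) - 4 - len(re_seq)
            bl = best_direct_repeat(left_region, prefer_right=True)
            br = best_direct_repeat(right_region, prefer_right=False)
            if bl is None or bl.unit_start != 4 or bl.unit_len != le_arm \
                    or len(bl.occurrence_starts) != 3 \
                    or bl.end != 4 + len(le_seq):
                last_err = f"{subgroup}: LE direct repeats not uniquely recoverable"
                continue
            if br is None or br.unit_start != rstart or br.unit_len != re_arm \
                    or len(br.occurrence_starts) != 3 \
                    or br.end != rstart + len(re_seq):
                last_err = f"{subgroup}: RE direct repeats not uniquely recoverable"
                continue
        else:
            # the boundary detector may resolve the same hairpin with a
            # longer stem and shorter loop (loop bases that happen to
            # pair); what must be invariant is the repeat's external edge,
            # which fixes the cleavage-tetramer position
            rstart = len(right_region) - 4 - len(re_seq)
            bl = best_inverted_repeat(left_region, prefer_right=True)
            br = best_inverted_repeat(right_region, prefer_right=False)
            if bl is None or bl.arm1_start != 4:
                last_err = f"{subgroup}: LE repeat edge not uniquely recoverable"
                continue
            if br is None or br.end != rstart + len(re_seq):
                last_err = f"{subgroup}: RE repeat edge not uniquely recoverable"
                continue

        # protected positions: tetramers, repeat arms/units, motif codons,
        # start and stop codons of both ORFs
        protected = set(range(0, 4 + len(le_seq)))
        protected.update(range(re_start - 0, len(seq)))
        # guard stop codons stay intact under divergence
        g1 = 4 + len(le_seq) + s1
        protected.update(range(g1 - 3, g1))
        if gap_ab:
            protected.update(range(tnpb_iv[0] - 3, tnpb_iv[0]))
            if reverse_orfa:
                protected.update(range(orfa_iv[1], orfa_iv[1] + 3))
        if bound_stop is not None:
            protected.update(range(*bound_stop))
        cds_list: list[tuple[int, int, str]] = [(tnpb_iv[0], tnpb_iv[1], "+")]
        protected.update(_codon_positions(prot_b, tnpb_iv[0]))
        protected.update(range(tnpb_iv[1] - 3, tnpb_iv[1]))  # stop
        if orfa_iv is not None:
            if orfa_strand == "+":
                protected.update(_codon_positions(prot_a, orfa_iv[0]))
                protected.update(range(orfa_iv[1] - 3, orfa_iv[1]))
            else:
                # ORFA runs right-to-left: aa position a occupies element
                # positions [end-3(a+1), end-3a)
                for a in prot_a:
                    b0 = orfa_iv[1] - 3 * (a + 1)
                    protected.update((b0, b0 + 1, b0 + 2))
                protected.update(range(orfa_iv[0], orfa_iv[0] + 3))
            cds_list.append((orfa_iv[0], orfa_iv[1], orfa_strand))

        role = "" if is1341 else ("SR" if is607 else "Y1")
        return ElementTemplate(
            template_id=template_id, subgroup=subgroup, sequence=seq,
            tnpb_cds=tnpb_iv, orfa_cds=orfa_iv, orfa_strand=orfa_strand,
            orfa_role=role, tnpb_protein=pb, orfa_protein=pa,
            le=le_spec, re=re_spec, cds_list=tuple(cds_list),
            protected=frozenset(protected), orfa_separate=orfa_sep)
    raise ValueError(f"could not build template after {max_tries} tries: {last_err}")


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def make_templates(priors: GroupPriors, seed: int,
                   n_per_subgroup: int = 1,
                   subgroups: tuple[str, ...] = SUBGROUPS,
                   ancestor: str | None = None) -> list[ElementTemplate]:
    """One or more templates per subgroup, deterministically from seed."""
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = ruvc_ancestor()
    out = []
    for sg in subgroups:
        for k in range(n_per_subgroup):
            out.append(make_template(sg, priors, rng, f"{sg}_t{k}", ancestor))
    return out


# ---------------------------------------------------------------------------
# copy-level surgery (truncation, decay) and mutation

@dataclass
class _Variant:
    seq: str
    cds_list: list[tuple[int, int, str]]
    protected: set[int]
    completeness: str


def _truncate(tpl: ElementTemplate, mode: str) -> _Variant:
    seq = tpl.sequence
    cds = list(tpl.cds_list)
    prot = set(tpl.protected)
    le_cut = tpl.le.end            # removes tetramer + LE repeat
    re_cut = len(seq) - tpl.re.start      # RE repeat + tetramer
    start, end = 0, len(seq)
    if mode in ("truncated_LE", "truncated_both"):
        start = le_cut
    if mode in ("truncated_RE", "truncated_both"):
        end = len(seq) - re_cut
    seq2 = seq[start:end]
    cds2 = [(s - start, e - start, st) for s, e, st in cds]
    prot2 = {p - start for p in prot if start <= p < end}
    return _Variant(seq2, cds2, prot2, mode)


def _decay(tpl: ElementTemplate, remnant_len: int) -> _Variant:
    """An IS605/IS607 copy whose ORFA has eroded to a short remnant."""
    if not tpl.orfa_separate or tpl.orfa_cds is None:
        raise ValueError("decay surgery needs a template with a separate ORFA")
    s, e = tpl.orfa_cds
    remnant = tpl.sequence[s:s + remnant_len]
    delta = remnant_len - (e - s)
    seq2 = tpl.sequence[:s] + remnant + tpl.sequence[e:]
    cds2 = []
    for cs, ce, st in tpl.cds_list:
        if (cs, ce) == (s, e):
            continue
        if cs >= e:
            cs, ce = cs + delta, ce + delta
        cds2.append((cs, ce, st))
    prot2 = set()
    for p in tpl.protected:
        if s <= p < e:
            continue
        prot2.add(p + delta if p >= e else p)
    # the remnant itself is the decay copy's defining feature: it must
    # still satisfy the >20 bp flank-match rule after divergence is applied
    prot2.update(range(s, s + remnant_len))
    return _Variant(seq2, cds2, prot2, "decay")


_ALTS = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def mutate_sequence(seq: str, n_sub: int, rng: np.random.Generator,
                    protected: set[int],
                    cds_list: list[tuple[int, int, str]]) -> str:
    """Place n_sub substitutions outside the protected set, never creating
    an in-frame stop codon within any listed CDS."""
    out = list(seq)
    free = [i for i in range(len(seq)) if i not in protected]
    if not free:
        return seq
    n_sub = min(n_sub, len(free))
    chosen = rng.choice(len(free), size=n_sub, replace=False)
    for ci in chosen:
        pos = free[ci]
        alts = list(_ALTS.get(out[pos], []))
        if not alts:
            continue
        rng.shuffle(alts)
        for alt in alts:
            ok = True
            for cs, ce, st in cds_list:
                if not cs <= pos < ce:
                    continue
                if st == "+":
                    ci0 = cs + 3 * ((pos - cs) // 3)
                    codon = "".join(out[ci0:ci0 + 3])
                    codon = codon[:pos - ci0] + alt + codon[pos - ci0 + 1:]
                else:
                    off = (ce - 1 - pos) // 3
                    ci0 = ce - 3 * (off + 1)
                    codon = "".join(out[ci0:ci0 + 3])
                    codon = codon[:pos - ci0] + alt + codon[pos - ci0 + 1:]
                    codon = revcomp(codon)
                if codon in STOP_CODONS:
                    ok = False
                    break
            if ok:
                out[pos] = alt
                break
    return "".join(out)


# ---------------------------------------------------------------------------
# dataset simulation

def species_abbrev(species: str) -> str:
    """ISfinder-style species abbreviation: genus initial + first two
    epithet letters (e.g. 'Escherichia coli' -> 'Eco')."""
    parts = species.split()
    if len(parts) < 2:
        return (species[:3] or "Xxx").capitalize()
    return (parts[0][0] + parts[1][:2]).capitalize()


def simulate_dataset(cfg: SimulationConfig,
                     templates: list[ElementTemplate]) -> tuple[list[Genome], TruthLedger]:
    """Plant diverged template copies into random genomes; every planted
    copy is recorded in the returned truth ledger."""
    if not templates:
        raise ValueError("no templates supplied")
    by_sg: dict[str, list[ElementTemplate]] = {}
    for t in templates:
        by_sg.setdefault(t.subgroup, []).append(t)
    decay_donors = [t for t in templates if t.orfa_separate]

    root = np.random.SeedSequence(cfg.seed)
    genomes: list[Genome] = []
    ledger = TruthLedger()
    contig_len = cfg.genome_length // cfg.n_contigs
    if contig_len < cfg.min_separation:
        raise ValueError("contigs shorter than the minimum element separation")

    species_seeds = root.spawn(len(cfg.species))
    for sp, sp_seed in zip(cfg.species, species_seeds):
        ab = species_abbrev(sp)
        genome_seeds = sp_seed.spawn(cfg.n_genomes_per_species)
        for g_idx, g_seed in enumerate(genome_seeds):
            rng = np.random.default_rng(g_seed)
            gid = f"{ab}_g{g_idx:03d}"
            gc = cfg.gc_content
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            contigs = {}
            occupied: dict[str, list[tuple[int, int]]] = {}
            arrays = {}
            for c in range(cfg.n_contigs):
                cid = f"c{c + 1}"
                arrays[cid] = rng.choice(4, size=contig_len, p=p).astype(np.int8)
                occupied[cid] = []

            plants = []
            for sg in SUBGROUPS:
                mean = cfg.copy_number_distribution.get(sg, 0.0)
                if mean <= 0 or sg not in by_sg:
                    continue
                if cfg.poisson_copy_numbers:
                    k = int(rng.poisson(mean))
                else:
                    k = int(round(mean))
                for _ in range(k):
                    plants.append(sg)
            for sg in plants:
                tpl = by_sg[sg][rng.integers(len(by_sg[sg]))]
                if sg == "IS1341" and decay_donors and rng.random() < cfg.decay_fraction:
                    # a decayed IS605/IS607 copy occupying an IS1341-like slot
                    tpl = decay_donors[rng.integers(len(decay_donors))]
                    var = _decay(tpl, cfg.decay_remnant_len)
                elif rng.random() < cfg.truncation_fraction:
                    mode = ("truncated_LE", "truncated_RE",
                            "truncated_both")[rng.integers(3)]
                    var = _truncate(tpl, mode)
                else:
                    var = _Variant(tpl.sequence, list(tpl.cds_list),
                                   set(tpl.protected), "full")
                n_sub = int(rng.binomial(len(var.seq), cfg.divergence))
                seq = mutate_sequence(var.seq, n_sub, rng, var.protected, var.cds_list)
                strand = "+" if rng.random() < 0.5 else "-"
                planted = seq if strand == "+" else revcomp(seq)

                L = len(planted)
                order = list(rng.permutation(cfg.n_contigs))
                placed = False
                for c_idx in order:
                    cid = f"c{c_idx + 1}"
                    arr = arrays[cid]
                    if len(arr) < L:
                        continue
                    for _t in range(200):
                        pos = int(rng.integers(0, len(arr) - L + 1))
                        clash = any(pos < e + cfg.min_separation and
                                    s - cfg.min_separation < pos + L
                                    for s, e in occupied[cid])
                        if not clash:
                            placed = True
                            break
                    if placed:
                        break
                if not placed:
                    raise ValueError(
                        f"genome {gid} too short/crowded for requested "
                        f"copies (contigs of {contig_len} nt)")
                arr[pos:pos + L] = encode_nt(planted)
                occupied[cid].append((pos, pos + L))
                ledger.records.append(TruthRecord(
                    gid, cid, pos, pos + L, strand, tpl.subgroup,
                    var.completeness, tpl.template_id, planted))
            for cid, arr in arrays.items():
                contigs[cid] = decode_nt(arr)
            genomes.append(Genome(gid, sp, contigs))
    ledger.records.sort(key=lambda r: (r.genome_id, r.contig_id, r.start))
    return genomes, ledger


# ---------------------------------------------------------------------------
# profile seed proteins, outgroup, reference library

def make_seed_proteins(seed: int, n_families: int = 18,
                       ancestor: str | None = None,
                       family_divergence: float = 0.20,
                       within_family_divergence: float = 0.02,
                       n_short: int = 2, n_long: int = 2,
                       n_truncated_core: int = 3) -> dict[str, str]:
    """TnpB-like proteins sharing the RuvC core, for profile building.

    The set has family structure: each of n_families base proteins appears
    as 1-4 near-identical variants, so the 80% redundancy clustering has
    real work to do.  Alongside them the set carries deliberate rejects for
    the curation filters: too-short (150 aa) and too-long (650 aa) entries,
    and proteins whose RuvC core is half-deleted (they survive the length
    filter but exceed the 20% gap threshold once aligned to the domain
    region).
    """
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = ruvc_ancestor()
    core_len = len(ancestor)
    out: dict[str, str] = {}
    k = 0
    for fam in range(n_families):
        total = int(rng.integers(320, 481))
        core = mutate_protein(ancestor, family_divergence, rng,
                              frozenset(RUVC_CATALYTIC))
        n_flank = total - core_len
        nf = int(rng.integers(60, max(61, n_flank - 40)))
        p = _rand_protein(rng, total)
        p[0] = "M"
        p[nf:nf + core_len] = list(core)
        base = "".join(p)
        for _copy in range(int(rng.integers(1, 5))):
            out[f"seed{k:03d}"] = mutate_protein(
                base, within_family_divergence, rng, frozenset({0}))
            k += 1
    for i in range(n_short):
        out[f"short{i}"] = "M" + "".join(_rand_protein(rng, 149))
    for i in range(n_long):
        out[f"long{i}"] = "M" + "".join(_rand_protein(rng, 649))
    for i in range(n_truncated_core):
        total = int(rng.integers(320, 481))
        core = mutate_protein(ancestor, family_divergence, rng,
                              frozenset(RUVC_CATALYTIC))[: core_len // 2]
        p = _rand_protein(rng, total)
        p[0] = "M"
        p[80:80 + len(core)] = list(core)
        out[f"trunc{i}"] = "".join(p)
    return out


def make_outgroup_proteins(seed: int, n: int = 3,
                           ancestor: str | None = None) -> dict[str, str]:
    """Distant outgroup proteins (IscB-like): the same catalytic geometry
    but a heavily diverged core and unrelated flanks."""
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = ruvc_ancestor()
    out = {}
    for i in range(n):
        core = mutate_protein(ancestor, 0.45, rng, frozenset(RUVC_CATALYTIC))
        total = int(rng.integers(380, 521))
        p = _rand_protein(rng, total)
        p[0] = "M"
        p[60:60 + len(core)] = list(core)
        out[f"outgroup{i}"] = "".join(p)
    return out


def reference_library(templates: list[ElementTemplate],
                      include: tuple[str, ...] | None = None) -> list[ReferenceEntry]:
    """Reference element library entries built from templates.

    ``include`` names the subgroups present in the library (None = all);
    withholding subgroups lets a run exercise the new-element naming path.
    """
    out = []
    k = 0
    for t in templates:
        if include is not None and t.subgroup not in include:
            continue
        k += 1
        a_cds = ""
        if t.orfa_cds is not None:
            a_cds = t.sequence[t.orfa_cds[0]:t.orfa_cds[1]]
            if t.orfa_strand == "-":
                a_cds = revcomp(a_cds)
        out.append(ReferenceEntry(
            name=f"ISRef{k}", subgroup=t.subgroup, sequence=t.sequence,
            le_tetramer=t.le.tetramer, re_tetramer=t.re.tetramer,
            tnpb_protein=t.tnpb_protein, orfa_protein=t.orfa_protein,
            orfa_role=t.orfa_role, orfa_cds=a_cds))
    return out
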