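"""Identity computation, greedy clustering, center-star MSA and consensus.

These are the desk-scale counterparts of the cd-hit / USEARCH / MAFFT steps
of the element-mining procedure: greedy incremental clustering against the
cluster representative at 80% (profile seeds), 70% (loci) and 90% (family)
identity, and a center-star multiple alignment feeding consensus calling.

Identity is computed on a fitting alignment: the shorter sequence is aligned
end to end, terminal gaps are free only along the longer sequence, and
identity = identical columns / aligned columns excluding terminal gaps.
Equal-length pairs reduce to a plain global alignment.  This matches the
fragment-versus-full-length comparisons the locus clustering has to make
while keeping unrelated full-length pairs at background identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align
from .genetics import encode_aa, encode_nt

NT_CHARS = set("ACGTN")


@dataclass(frozen=True)
class IdentityParams:
    """Scoring for the identity alignment (match/mismatch, affine gaps).

    Penalties are held as the (non-positive) values used in the score sum;
    the first gap column of a run costs ``gap_open``, later ones
    ``gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


DEFAULT_PARAMS = IdentityParams()


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str]
    threshold: float
    identities: dict[str, float] = field(default_factory=dict)


@dataclass
class Alignment:
    """A padded multiple alignment (rows of equal length, gap '-')."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must all have the same length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class Consensus:
    sequence: str
    majority_fraction: list[float]


def _looks_nt(seq: str) -> bool:
    return set(seq.upper()) <= NT_CHARS


def _encode_pair(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    a_nt, b_nt = _looks_nt(a), _looks_nt(b)
    if a_nt != b_nt:
        raise ValueError("mixed alphabets: one sequence looks like DNA, the other like protein")
    enc = encode_nt if a_nt else encode_aa
    return enc(a.upper()), enc(b.upper())


def pairwise_identity(a: str, b: str, params: IdentityParams = DEFAULT_PARAMS,
                      band_slack: int | None = None) -> float:
    """Fraction of identical columns in the fitting alignment of a and b.

    ``band_slack`` restricts the search to diagonals within that distance of
    the length-difference corridor (None = exact, full matrix).  The band is
    a speed device for long, collinear sequences; on dissimilar pairs it can
    only underestimate identity.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    ea, eb = _encode_pair(a, b)
    if len(ea) > len(eb):
        ea, eb = eb, ea
    m, n = len(ea), len(eb)
    if band_slack is None:
        lo, hi = -m, n
    else:
        lo, hi = -band_slack, (n - m) + band_slack
    fit = m != n
    _score, matches, cols = _align.banded_affine(
        ea, eb, lo, hi, params.match, params.mismatch,
        -params.gap_open, -params.gap_extend, fit)
    if cols == 0:
        return 0.0
    return matches / cols


def greedy_cluster(seqs: dict[str, str], threshold: float,
                   params: IdentityParams = DEFAULT_PARAMS,
                   band_slack: int | None = None) -> list[Cluster]:
    """Greedy incremental clustering in decreasing length order.

    Sequences are visited longest first (ties by identifier); each joins the
    first existing cluster whose *representative* it matches at >= threshold,
    otherwise it founds a new cluster.  Because of the ordering, every
    representative is the longest member of its cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[Cluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            ident = pairwise_identity(seqs[sid], seqs[cl.representative_id],
                                      params, band_slack)
            if ident >= threshold:
                cl.member_ids.append(sid)
                cl.identities[sid] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sid, [sid], threshold, {sid: 1.0}))
    return clusters


def _pairwise_path(center: np.ndarray, other: np.ndarray,
                   params: IdentityParams, free_ends: bool = True) -> np.ndarray:
    _score, moves = _align.global_affine_path(
        center, other, params.match, params.mismatch,
        -params.gap_open, -params.gap_extend, free_ends)
    return moves


def center_star_msa(seqs: dict[str, str],
                    params: IdentityParams = DEFAULT_PARAMS,
                    center_by: str = "identity",
                    free_ends: bool = True,
                    center: str | None = None) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence maximising its summed pairwise identity to
    all others (ties by identifier); every other sequence is aligned to the
    center pairwise (end-gap-free global) and the pairwise gaps are merged
    under "once a gap, always a gap".  Degapping any output row reproduces
    the corresponding input exactly.

    center_by="score" picks the center by summed alignment score instead —
    preferable when sequences share only a short domain, where identity
    fractions are dominated by unalignable flanks.
    """
    ids = sorted(seqs)
    if not ids:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return Alignment(ids, [seqs[ids[0]]])
    # choose center (or honour an explicit one, e.g. for guide comparisons)
    if center is not None:
        if center not in seqs:
            raise ValueError(f"center {center!r} not among the sequences")
        center_id = center
    else:
        nt0 = _looks_nt(seqs[ids[0]])
        enc0 = encode_nt if nt0 else encode_aa
        sums = {}
        for i in ids:
            if center_by == "score":
                sums[i] = sum(_align.global_affine_path(
                    enc0(seqs[i].upper()), enc0(seqs[j].upper()),
                    params.match, params.mismatch,
                    -params.gap_open, -params.gap_extend, True)[0]
                    for j in ids if j != i)
            else:
                sums[i] = sum(pairwise_identity(seqs[i], seqs[j], params)
                              for j in ids if j != i)
        center_id = max(ids, key=lambda i: (sums[i], i))
    others = [i for i in ids if i != center_id]

    nt = _looks_nt(seqs[center_id])
    enc = encode_nt if nt else encode_aa
    c_seq = seqs[center_id].upper()
    c_enc = enc(c_seq)
    m = len(c_seq)

    # Each pairwise alignment is re-expressed against ungapped center
    # coordinates: ins_runs[p] holds residues inserted before center
    # position p (p = m meaning after the last residue) and core[p] the
    # symbol aligned to center residue p.  "Once a gap, always a gap":
    # the merged alignment reserves max_ins[p] insert columns at each slot.
    per_other: list[tuple[list[list[str]], list[str]]] = []
    max_ins = [0] * (m + 1)
    for oid in others:
        o_seq = seqs[oid].upper()
        moves = _pairwise_path(c_enc, enc(o_seq), params, free_ends)
        ins_runs: list[list[str]] = [[] for _ in range(m + 1)]
        core: list[str] = ["-"] * m
        ci = oi = 0
        for mv in moves:
            if mv == 1:
                core[ci] = o_seq[oi]
                ci += 1
                oi += 1
            elif mv == 2:  # gap in the other sequence
                ci += 1
            else:  # insertion relative to the center
                ins_runs[ci].append(o_seq[oi])
                oi += 1
        per_other.append((ins_runs, core))
        for p in range(m + 1):
            if len(ins_runs[p]) > max_ins[p]:
                max_ins[p] = len(ins_runs[p])

    parts = []
    for p in range(m + 1):
        parts.append("-" * max_ins[p])
        if p < m:
            parts.append(c_seq[p])
    final_rows = ["".join(parts)]
    for ins_runs, core in per_other:
        row_parts = []
        for p in range(m + 1):
            run = "".join(ins_runs[p])
            row_parts.append(run + "-" * (max_ins[p] - len(run)))
            if p < m:
                row_parts.append(core[p])
        final_rows.append("".join(row_parts))

    all_ids = [center_id] + others
    # restore deterministic id order
    order = sorted(range(len(all_ids)), key=lambda k: all_ids[k])
    return Alignment([all_ids[k] for k in order], [final_rows[k] for k in order])


def consensus(aln: Alignment, max_gap_fraction: float = 0.5) -> Consensus:
    """Majority-rule consensus over columns with gap fraction < 0.5.

    Ties go to the alphabetically first symbol; the winning symbol's
    fraction of non-gap residues is recorded per retained column.
    """
    if aln.n_rows == 0:
        raise ValueError("empty alignment")
    out = []
    fracs = []
    n = aln.n_rows
    for c in range(aln.n_cols):
        col = [r[c] for r in aln.rows]
        gaps = col.count("-")
        if gaps / n >= max_gap_fraction:
            continue
        counts: dict[str, int] = {}
        for ch in col:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        out.append(best)
        fracs.append(counts[best] / (n - gaps))
    return Consensus("".join(out), fracs)
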