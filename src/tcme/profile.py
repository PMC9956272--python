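"""RuvC-domain profile: curation, PSSM construction, six-frame genome scan.

The mining procedure starts from a curated set of TnpB-like proteins, keeps
those of 200-600 aa, clusters them at 80% identity, aligns the cluster
representatives, drops rows whose RuvC region is more than 20% gaps, and
builds a position-specific scoring model from the remaining alignment.
Genomes are then scanned in all six reading frames with an affine-gap
local alignment of the model; hits shorter than 50 aa are discarded.

The scoring model is a log-odds PSSM (profile HMM internals are out of
scope): score(column, residue) = log2(((count + pc*bg) / (n + pc)) / bg)
with pseudocount pc and background bg.  Alignment scores are accumulated
in half-bits with gap penalties 11 (open) / 1 (extend); reported scores
are in bits.

Because hit thresholds for a PSSM have no hmmsearch-default equivalent,
the default threshold is calibrated empirically as the 99.9th percentile
of local-alignment scores over dinucleotide-preserving shuffles of the
scanned genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .cluster import Alignment
from .genetics import (AA_ALPHABET, AA_STOP, AA_X, aa_to_nt_interval,
                       encode_nt, six_frame_codes)
from .synth import Genome

N_SYMBOLS = 22  # 20 aa + X + stop


@dataclass(frozen=True)
class CurationThresholds:
    """Published curation constants of the mining procedure."""

    min_protein_len: int = 200
    max_protein_len: int = 600
    build_cluster_identity: float = 0.80
    max_gap_fraction: float = 0.20
    min_hit_len: int = 50

    def __post_init__(self):
        if not 0 < self.build_cluster_identity <= 1:
            raise ValueError("cluster identity must be in (0, 1]")
        if self.min_protein_len >= self.max_protein_len:
            raise ValueError("min_protein_len must be < max_protein_len")


@dataclass
class RuvCProfile:
    """Per-column log-odds scores (bits) over the 22 residue codes."""

    scores: np.ndarray                  # (n_columns, 22) float64, bits
    gap_open: float = 11.0              # half-bits
    gap_extend: float = 1.0             # half-bits
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1 / 20))

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def halfbit_matrix(self) -> np.ndarray:
        return (2.0 * self.scores).astype(np.float64)


@dataclass(frozen=True)
class ProteinHit:
    genome_id: str
    contig_id: str
    frame: int                          # +1..+3, -1..-3
    protein_start: int                  # aa, within the frame's translation
    protein_end: int
    genomic_start: int                  # nt, forward strand, half-open
    genomic_end: int
    strand: str
    score: float                        # bits
    matched_len: int                    # aa consumed by the local alignment


def curate_seed(seqs: dict[str, str],
                thresholds: CurationThresholds = CurationThresholds()) -> dict[str, str]:
    """Length filter: keep sequences with min <= len <= max (the published
    rule discards strictly <200 aa and >600 aa)."""
    if not seqs:
        raise ValueError("empty seed set")
    out = {k: v for k, v in seqs.items()
           if thresholds.min_protein_len <= len(v) <= thresholds.max_protein_len}
    if not out:
        warnings.warn("length curation removed every seed sequence")
    return out


def gap_filter(aln: Alignment, region: tuple[int, int],
               max_gap_fraction: float = 0.20) -> list[str]:
    """Ids of rows whose gap fraction within the column interval
    [region[0], region[1]) is <= max_gap_fraction (rows with strictly more
    are discarded)."""
    s, e = region
    if not (0 <= s < e <= aln.n_cols):
        raise ValueError(f"region ({s}, {e}) outside alignment width {aln.n_cols}")
    width = e - s
    kept = []
    for rid, row in zip(aln.ids, aln.rows):
        gaps = row[s:e].count("-")
        if gaps / width <= max_gap_fraction:
            kept.append(rid)
    return kept


def match_column_region(aln: Alignment, max_gap: float = 0.5) -> tuple[int, int]:
    """Contiguous column interval spanning the first to last match column
    (gap fraction < max_gap)."""
    cols = [c for c in range(aln.n_cols)
            if sum(r[c] == "-" for r in aln.rows) / aln.n_rows < max_gap]
    if not cols:
        raise ValueError("alignment has no match columns")
    return cols[0], cols[-1] + 1


def conserved_region(aln: Alignment, background: np.ndarray | None = None,
                     smooth: int = 15) -> tuple[int, int]:
    """The conserved domain block of an alignment, as a column interval.

    Per-column relative entropy (bits against the background, scaled by the
    column's non-gap fraction) is smoothed with a moving average; the
    region is the longest contiguous run above an adaptive cutoff halfway
    between the median (the finite-sample noise floor of unconserved
    columns) and the maximum of the smoothed signal.  On an alignment of
    proteins that share only one domain this recovers that domain's
    columns, standing in for extracting the aligned region of a curated
    domain model.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    n = aln.n_rows
    info = np.zeros(aln.n_cols)
    for c in range(aln.n_cols):
        counts = np.zeros(20)
        for r in aln.rows:
            i = AA_ALPHABET.find(r[c])
            if i >= 0:
                counts[i] += 1
        n_c = counts.sum()
        if n_c == 0:
            continue
        p = counts / n_c
        nz = p > 0
        info[c] = float(np.sum(p[nz] * np.log2(p[nz] / background[nz]))) * (n_c / n)
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(info, kernel, mode="same")
    # the median tracks the unconserved-column noise floor, the max the
    # domain plateau; the cutoff sits just above the floor so the whole
    # plateau (not only its peak) is kept.  When the alignment is domain
    # columns throughout (median ~ max) the floor estimate is meaningless
    # and the cutoff falls back to a fraction of the plateau.
    med, mx = float(np.median(sm)), float(sm.max())
    cutoff = max(0.25 * mx, min(2.0 * med, 0.6 * mx))
    above = sm >= cutoff
    best = (0, 0)
    run_start = None
    for c in range(len(above) + 1):
        if c < len(above) and above[c]:
            if run_start is None:
                run_start = c
        elif run_start is not None:
            if c - run_start > best[1] - best[0]:
                best = (run_start, c)
            run_start = None
    if best == (0, 0):
        raise ValueError("no conserved region found in the seed alignment")
    return best


def slice_alignment(aln: Alignment, region: tuple[int, int],
                    ids: list[str] | None = None) -> Alignment:
    """Restrict an alignment to a column interval (and optionally rows)."""
    s, e = region
    keep = set(ids) if ids is not None else None
    out_ids, out_rows = [], []
    for rid, row in zip(aln.ids, aln.rows):
        if keep is None or rid in keep:
            out_ids.append(rid)
            out_rows.append(row[s:e])
    return Alignment(out_ids, out_rows)


def build_profile(aln: Alignment, pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  gap_open: float = 11.0, gap_extend: float = 1.0) -> RuvCProfile:
    """Log-odds PSSM over the alignment's match columns.

    Match columns are those with gap fraction < 0.5.  Unknown residues (X)
    and stop symbols get fixed penalties (-2 and -4 bits) so that genomic
    reading-frame noise is discouraged without dominating the score.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be 20 frequencies summing to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    n_rows = aln.n_rows
    cols = []
    for c in range(aln.n_cols):
        col = [r[c] for r in aln.rows]
        gaps = col.count("-")
        if gaps / n_rows >= 0.5:
            continue
        counts = np.zeros(20)
        for ch in col:
            i = AA_ALPHABET.find(ch)
            if i >= 0:
                counts[i] += 1
        n_c = counts.sum()
        probs = (counts + pseudocount * background) / (n_c + pseudocount)
        cols.append(np.log2(probs / background))
    if not cols:
        raise ValueError("alignment has no match columns")
    scores = np.zeros((len(cols), N_SYMBOLS))
    scores[:, :20] = np.vstack(cols)
    scores[:, AA_X] = -2.0
    scores[:, AA_STOP] = -4.0
    return RuvCProfile(scores, gap_open, gap_extend, background)


def score_local(profile: RuvCProfile, protein) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Best local alignment of the profile to a protein.

    Returns (score_bits, (col_start, col_end), (aa_start, aa_end)).
    Accepts a string or an encoded int8 array.
    """
    if isinstance(protein, str):
        from .genetics import encode_aa
        protein = encode_aa(protein)
    s, qs, qe, ts, te = _align.profile_local(
        profile.halfbit_matrix(), protein, profile.gap_open, profile.gap_extend)
    return s / 2.0, (qs, qe), (ts, te)


# ---------------------------------------------------------------------------
# scanning

def _prescan_candidates(S2: np.ndarray, x: np.ndarray, cand_cut: float,
                        pad: int = 25) -> list[tuple[int, int]]:
    """Candidate aa windows from an exhaustive ungapped profile sweep.

    The sweep scores every frame offset as sum_c S2[c, x[p+c]] over the
    profile's *informative* columns (best residue score >= 1 bit); weak
    columns are left out because their background-level contributions
    would dilute a true hit's window sum without adding discrimination.
    Under the substitution-only divergence model a true hit's optimal
    local path is ungapped, so its offset scores far exceed cand_cut
    (set well below the reporting threshold); windows are padded and
    merged.
    """
    ncols = S2.shape[0]
    L = x.shape[0]
    windows: list[tuple[int, int]] = []
    if L <= ncols + 2 * pad:
        return [(0, L)] if L else []
    colmax = S2[:, :20].max(axis=1)
    info_cols = np.flatnonzero(colmax >= max(2.0, 0.5 * float(colmax.max())))
    if len(info_cols) < 20:
        info_cols = np.arange(ncols)
    n_off = L - ncols + 1
    acc = np.zeros(n_off)
    xi = x.astype(np.intp)
    for c in info_cols:
        acc += S2[c][xi[c:c + n_off]]
    cand = np.flatnonzero(acc >= cand_cut)
    for p in cand:
        windows.append((max(0, p - pad), min(L, p + ncols + pad)))
    # sequence edges, where a truncated domain evades the full-length sweep
    windows.append((0, min(L, ncols + pad)))
    windows.append((max(0, L - ncols - pad), L))
    windows.sort()
    merged = [windows[0]]
    for s, e in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def scan_genome(profile: RuvCProfile, genome: Genome, score_threshold: float,
                min_hit_len: int = 50) -> list[ProteinHit]:
    """Scan all six frames of every contig for profile hits.

    Hits require local score >= score_threshold (bits) and a matched target
    segment of >= min_hit_len aa.  Overlapping hits within one frame are
    merged keeping the best score; hits are sorted by contig and start.
    """
    S2 = profile.halfbit_matrix()
    thr_half = 2.0 * score_threshold
    cand_cut = 0.5 * thr_half
    hits: list[ProteinHit] = []
    for cid in sorted(genome.contigs):
        nt = encode_nt(genome.contigs[cid])
        frames = six_frame_codes(nt)
        for frame, x in frames.items():
            frame_hits: list[tuple[int, int, float, int, int]] = []
            for ws, we in _prescan_candidates(S2, x, cand_cut):
                sc, qs, qe, ts, te = _align.profile_local(
                    S2, x[ws:we], profile.gap_open, profile.gap_extend)
                if sc < thr_half:
                    continue
                ts += ws
                te += ws
                if te - ts < min_hit_len:
                    continue
                frame_hits.append((ts, te, sc, qs, qe))
            # merge overlapping hits in this frame, best score wins
            frame_hits.sort()
            kept: list[tuple[int, int, float, int, int]] = []
            for h in frame_hits:
                if kept and h[0] < kept[-1][1]:
                    if h[2] > kept[-1][2]:
                        kept[-1] = h
                else:
                    kept.append(h)
            for ts, te, sc, _qs, _qe in kept:
                gs, ge = aa_to_nt_interval(frame, ts, te, len(nt))
                hits.append(ProteinHit(
                    genome_id=genome.genome_id, contig_id=cid, frame=frame,
                    protein_start=ts, protein_end=te,
                    genomic_start=gs, genomic_end=ge,
                    strand="+" if frame > 0 else "-",
                    score=sc / 2.0, matched_len=te - ts))
    hits.sort(key=lambda h: (h.contig_id, h.genomic_start, h.frame))
    return hits


# ---------------------------------------------------------------------------
# threshold calibration

def dinucleotide_shuffle(seq: str, rng: np.random.Generator,
                         max_tries: int = 100) -> str:
    """Altschul–Erikson shuffle preserving exact dinucleotide counts."""
    s = seq.upper()
    if len(s) < 3:
        return s
    verts = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    for _ in range(max_tries):
        # pick a random final edge for every vertex except the terminal one
        finals = {}
        ok = True
        for v in verts:
            if v == last:
                continue
            if not edges[v]:
                ok = False
                break
            finals[v] = edges[v][rng.integers(len(edges[v]))]
        if not ok:
            break
        # the chosen final edges must lead every vertex to the terminal one
        good = True
        for v in verts:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in finals:
                    good = False
                    break
                seen.add(cur)
                cur = finals[cur]
            if not good:
                break
        if not good:
            continue
        out = [s[0]]
        pools: dict[str, list[str]] = {}
        for v in verts:
            pool = list(edges[v])
            if v in finals:
                pool.remove(finals[v])
            rng.shuffle(pool)
            if v in finals:
                pool.append(finals[v])
            pools[v] = pool
        idx = {v: 0 for v in verts}
        cur = s[0]
        for _ in range(len(s) - 1):
            nxt = pools[cur][idx[cur]]
            idx[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    # degenerate composition: fall back to a plain shuffle
    arr = list(s)
    rng.shuffle(arr)
    return "".join(arr)


def calibrate_threshold(profile: RuvCProfile, genomes: list[Genome], seed: int,
                        n_decoys: int = 1000, decoy_len_aa: int = 200,
                        percentile: float = 99.9) -> float:
    """Decoy-based score threshold (bits).

    Draws n_decoys windows from the genomes, dinucleotide-shuffles each,
    translates frame +1 and records the best local profile score; returns
    the requested percentile.  Deterministic given the seed.
    """
    if not genomes:
        raise ValueError("no genomes to calibrate against")
    rng = np.random.default_rng(seed)
    S2 = profile.halfbit_matrix()
    win_nt = 3 * decoy_len_aa
    pool = [(g, cid) for g in genomes for cid in sorted(g.contigs)
            if len(g.contigs[cid]) > win_nt]
    if not pool:
        raise ValueError("contigs shorter than the decoy window")
    scores = np.empty(n_decoys)
    from .genetics import translate_codes
    for i in range(n_decoys):
        g, cid = pool[rng.integers(len(pool))]
        contig = g.contigs[cid]
        p = int(rng.integers(0, len(contig) - win_nt + 1))
        dec = dinucleotide_shuffle(contig[p:p + win_nt], rng)
        x = translate_codes(encode_nt(dec))
        sc, *_ = _align.profile_local(S2, x, profile.gap_open, profile.gap_extend)
        scores[i] = sc / 2.0
    return float(np.percentile(scores, percentile))


def _extract_domain_segments(reps: dict[str, str],
                             pad: int = 8) -> dict[str, str]:
    """Per-representative shared-domain segments.

    The representative with the highest summed local-alignment score to
    all others serves as the domain anchor (the role a curated domain
    model plays in the original procedure); every other sequence
    contributes the segment its best local alignment to the anchor
    covers.  Unrelated flanks never enter the alignment that the profile
    is built from, which keeps the domain block contiguous regardless of
    flank lengths.
    """
    import itertools

    from .genetics import encode_aa

    ids = sorted(reps)
    enc = {i: encode_aa(reps[i]) for i in ids}
    sums = {i: 0.0 for i in ids}
    for i, j in itertools.combinations(ids, 2):
        sc, *_ = _align.local_affine(enc[i], enc[j], 1.0, -1.0, 4.0, 1.0)
        sums[i] += sc
        sums[j] += sc
    center = max(ids, key=lambda i: (sums[i], i))
    segs = {}
    a_starts, a_ends = [], []
    for j in ids:
        if j == center:
            continue
        _sc, _m, _c, a0, a1, b0, b1 = _align.local_affine(
            enc[center], enc[j], 1.0, -1.0, 4.0, 1.0)
        if b1 - b0 >= 10:
            segs[j] = reps[j][max(0, b0 - pad): b1 + pad]
            a_starts.append(a0)
            a_ends.append(a1)
    if not segs:
        raise ValueError("no shared domain found among seed representatives")
    a_starts.sort()
    a_ends.sort()
    a0 = a_starts[len(a_starts) // 2]
    a1 = a_ends[len(a_ends) // 2]
    segs[center] = reps[center][max(0, a0 - pad): a1 + pad]
    return segs


def build_profile_from_seeds(seed_proteins: dict[str, str],
                             thresholds: CurationThresholds = CurationThresholds(),
                             pseudocount: float = 1.0,
                             background: np.ndarray | None = None) -> RuvCProfile:
    """Full profile-construction flow from raw seed proteins.

    Length curation -> greedy 80% redundancy clustering (representatives
    only) -> domain-segment extraction against the best-anchoring
    representative -> center-star alignment of the segments ->
    conserved-region trim -> 20% gap filter within that region -> PSSM
    build on the region columns of the retained rows.
    """
    from .cluster import center_star_msa, greedy_cluster

    cur = curate_seed(seed_proteins, thresholds)
    clusters = greedy_cluster(cur, thresholds.build_cluster_identity)
    reps = {c.representative_id: cur[c.representative_id] for c in clusters}
    if len(reps) < 2:
        raise ValueError("fewer than two representatives after curation")
    segs = _extract_domain_segments(reps)
    aln = center_star_msa(segs)
    region = conserved_region(aln, background)
    kept = gap_filter(aln, region, thresholds.max_gap_fraction)
    if len(kept) < 2:
        raise ValueError("gap filter removed too many rows")
    domain = slice_alignment(aln, region, kept)
    return build_profile(domain, pseudocount, background)
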