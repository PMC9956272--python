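"""Nucleotide/protein primitives: encoding, translation, six-frame scans.

All translation uses the bacterial genetic code (NCBI translation table 11),
whose codon-to-amino-acid mapping is identical to the standard code; the
table differs from the standard code only in its wider set of initiation
codons (ATG/GTG/TTG), which is handled by the ORF finder, not here.

Coordinates are 0-based half-open on the forward strand throughout.
"""

from __future__ import annotations

import numpy as np

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # canonical order, index 0..19
AA_X = 20  # unknown residue (from N in the DNA)
AA_STOP = 21

_NT_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_AA_CODE = np.full(256, AA_X, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_CODE[ord(_c)] = _i
    _AA_CODE[ord(_c.lower())] = _i
_AA_CODE[ord("*")] = AA_STOP

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Standard/table-11 codon table written out by second position for legibility.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

# codon index (base-5 with N=4) -> aa code; codons touching N give X
_CODON_AA = np.full(125, AA_X, dtype=np.int8)
for _codon, _aa in _CODON_TABLE.items():
    _idx = 0
    for _c in _codon:
        _idx = _idx * 5 + int(_NT_CODE[ord(_c)])
    _CODON_AA[_idx] = _AA_CODE[ord(_aa)]

# per-amino-acid synonymous codon lists, used by the reverse translator
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _v in CODONS_FOR_AA.values():
    _v.sort()


def encode_nt(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    """Encode a protein string to int8 codes (20 aa -> 0..19, X -> 20, * -> 21)."""
    return _AA_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_aa(codes: np.ndarray) -> str:
    lut = np.frombuffer((AA_ALPHABET + "X*").encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def decode_nt(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    return comp[codes[::-1]]


def translate_codes(nt_codes: np.ndarray) -> np.ndarray:
    """Translate encoded DNA (frame already applied) to encoded amino acids."""
    n = (len(nt_codes) // 3) * 3
    if n == 0:
        return np.empty(0, dtype=np.int8)
    c = nt_codes[:n].astype(np.int32).reshape(-1, 3)
    idx = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    return _CODON_AA[idx]


def translate(seq: str) -> str:
    """Translate a DNA string in frame +1; stops rendered '*', N -> 'X'."""
    return decode_aa(translate_codes(encode_nt(seq)))


FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_codes(nt_codes: np.ndarray) -> dict[int, np.ndarray]:
    """Encoded six-frame translation of an encoded contig."""
    rc = revcomp_codes(nt_codes)
    out = {}
    for k in range(3):
        out[k + 1] = translate_codes(nt_codes[k:])
        out[-(k + 1)] = translate_codes(rc[k:])
    return out


def six_frame_translate(seq: str) -> dict[int, str]:
    """Six-frame translation; frames +1..+3 forward, -1..-3 on the
    reverse complement. Returns frame -> protein string."""
    return {f: decode_aa(a) for f, a in six_frame_codes(encode_nt(seq)).items()}


def aa_to_nt_interval(frame: int, aa_start: int, aa_end: int, contig_len: int) -> tuple[int, int]:
    """Map an aa interval [aa_start, aa_end) in a frame's translation back to
    the forward-strand nucleotide interval [start, end)."""
    if frame > 0:
        off = frame - 1
        return off + 3 * aa_start, off + 3 * aa_end
    off = -frame - 1
    # interval on the reverse-complement sequence, mirrored to forward strand
    rc_start, rc_end = off + 3 * aa_start, off + 3 * aa_end
    return contig_len - rc_end, contig_len - rc_start


def nt_to_aa_offset(frame: int, nt_pos: int, contig_len: int) -> int:
    """Inverse helper: forward-strand position of the first base covered by a
    frame -> aa index containing it (approximate for off-frame positions)."""
    if frame > 0:
        return max(0, (nt_pos - (frame - 1)) // 3)
    rc_pos = contig_len - nt_pos - 1
    return max(0, (rc_pos - (-frame - 1)) // 3)


def reverse_translate(protein: str, rng: np.random.Generator,
                      start_atg: bool = True) -> str:
    """Back-translate a protein to a CDS, drawing synonymous codons uniformly.

    The first residue must be M when start_atg is set (templates use ATG-only
    starts so ground truth is unambiguous). No stop codon is appended.
    """
    codons = []
    for i, aa in enumerate(protein):
        if aa not in CODONS_FOR_AA:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        if i == 0 and start_atg:
            if aa != "M":
                raise ValueError("CDS must begin with M for an ATG start")
            codons.append("ATG")
        else:
            opts = CODONS_FOR_AA[aa]
            codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)
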