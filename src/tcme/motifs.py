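"""Protein motif predicates shared by the generator and the annotator.

Y1 transposases carry the HuH triad (His, bulky hydrophobic, His) of the
HuH nuclease superfamily plus a catalytic tyrosine and glutamine further
toward the C terminus; serine recombinases carry their catalytic serine
in the central domain.
"""

from __future__ import annotations

HYDROPHOBIC = set("LIVFMAW")


def find_y1_motif(protein: str) -> tuple[int, int, int] | None:
    """Positions (HuH start, Y, Q) of the first Y1 signature, or None.

    The triad is H-u-H with u bulky hydrophobic; the catalytic Y must lie
    downstream of the triad and the Q downstream of the Y.
    """
    n = len(protein)
    for i in range(n - 2):
        if protein[i] == "H" and protein[i + 2] == "H" \
                and protein[i + 1] in HYDROPHOBIC:
            j = protein.find("Y", i + 3)
            if j != -1:
                k = protein.find("Q", j + 1)
                if k != -1:
                    return i, j, k
    return None


def find_sr_motif(protein: str) -> int | None:
    """Position of a catalytic serine within the central third, or None."""
    n = len(protein)
    pos = protein.find("S", n // 3, 2 * n // 3)
    return pos if pos != -1 else None
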