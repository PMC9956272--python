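"""Subterminal repeat search: inverted repeats (hairpin stems) and short
direct repeats.

IS605/IS1341 ends carry palindromic (hairpin-forming) subterminal elements;
IS607 ends instead carry short direct repeats and lack inverted repeats.
Both searches are combinatorial (no thermodynamic folding): an inverted
repeat is a pair of reverse-complementary arms separated by a short loop,
a direct repeat is a short unit recurring within a small span.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class InvertedRepeat:
    arm1_start: int          # left arm [arm1_start, arm1_start + arm_len)
    arm_len: int
    loop_len: int            # loop between the arms
    mismatches: int

    @property
    def arm2_start(self) -> int:
        return self.arm1_start + self.arm_len + self.loop_len

    @property
    def end(self) -> int:
        return self.arm2_start + self.arm_len


@dataclass(frozen=True)
class DirectRepeat:
    unit_start: int
    unit_len: int
    occurrence_starts: tuple[int, ...]

    @property
    def end(self) -> int:
        return self.occurrence_starts[-1] + self.unit_len


def find_inverted_repeats(seq: str, min_arm: int = 11, max_arm: int = 40,
                          loop_min: int = 3, loop_max: int = 15,
                          max_mismatch: int = 1) -> list[InvertedRepeat]:
    """All maximal inverted repeats in seq with the given arm/loop limits.

    Arms are extended outward from each candidate loop while the mismatch
    budget holds; arms never end on a mismatched pair.  Maximal means the
    arm cannot be extended further within the budget and arm-length cap.
    """
    s = seq.upper()
    n = len(s)
    out = []
    for loop_len in range(loop_min, loop_max + 1):
        # e = first position of the loop; arm1 ends at e, arm2 starts at e+loop
        for e in range(1, n):
            a2 = e + loop_len
            if a2 >= n:
                break
            mism = 0
            best_k = 0
            k = 0
            while k < max_arm:
                i = e - 1 - k
                j = a2 + k
                if i < 0 or j >= n:
                    break
                ci = s[i]
                cj = s[j]
                if ci in _COMP and _COMP[ci] == cj:
                    k += 1
                    best_k = k
                else:
                    if mism + 1 > max_mismatch:
                        break
                    mism += 1
                    k += 1  # arm may pass through a mismatch but not end on one
            if best_k >= min_arm:
                # count mismatches within the reported (trimmed) arm
                mm = sum(1 for t in range(best_k)
                         if _COMP.get(s[e - 1 - t]) != s[a2 + t])
                ir = InvertedRepeat(e - best_k, best_k, loop_len, mm)
                out.append(ir)
    # deduplicate nested reports (same arm interval reported for each loop)
    seen = set()
    uniq = []
    for ir in out:
        key = (ir.arm1_start, ir.arm_len, ir.loop_len)
        if key not in seen:
            seen.add(key)
            uniq.append(ir)
    return uniq


def best_inverted_repeat(seq: str, prefer_right: bool, **kw) -> InvertedRepeat | None:
    """Best inverted repeat: longest stem, ties broken by proximity to the
    ORF side (prefer_right=True when the ORF lies right of the window)."""
    irs = find_inverted_repeats(seq, **kw)
    if not irs:
        return None
    if prefer_right:
        return max(irs, key=lambda r: (r.arm_len, r.end))
    return max(irs, key=lambda r: (r.arm_len, -r.arm1_start))


def find_direct_repeats(seq: str, unit_min: int = 9, unit_max: int = 12,
                        span: int = 60, min_occurrences: int = 2) -> list[DirectRepeat]:
    """Direct repeats: a unit of unit_min..unit_max nt recurring (exactly)
    at least min_occurrences times within a span-nt stretch.  Occurrences
    are non-overlapping and greedily collected left to right."""
    s = seq.upper()
    n = len(s)
    out = []
    for u in range(unit_max, unit_min - 1, -1):
        for i in range(0, n - u + 1):
            unit = s[i:i + u]
            if "N" in unit:
                continue
            occ = [i]
            j = i + u
            limit = i + span
            while j + u <= min(n, limit):
                if s[j:j + u] == unit:
                    occ.append(j)
                    j += u
                else:
                    j += 1
            if len(occ) >= min_occurrences:
                out.append(DirectRepeat(i, u, tuple(occ)))
    return out


def best_direct_repeat(seq: str, prefer_right: bool, **kw) -> DirectRepeat | None:
    """Best direct repeat: longest unit, then most occurrences, then
    proximity to the ORF side."""
    drs = find_direct_repeats(seq, **kw)
    if not drs:
        return None
    if prefer_right:
        return max(drs, key=lambda r: (r.unit_len, len(r.occurrence_starts), r.end))
    return max(drs, key=lambda r: (r.unit_len, len(r.occurrence_starts), -r.unit_start))
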