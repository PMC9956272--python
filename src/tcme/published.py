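"""Printed summary counts from the six-species TCME survey.

These integer counts are inputs: the published per-species distribution
table (surveyed genomes, detected loci, retained elements, element-positive
genomes, full elements) and the per-subgroup occupancy table (genomes
containing each subgroup, with group totals).  The derived quantities the
survey prints next to them — percentages and positive-genome means — are
recomputed by this package's summary code and compared against the
published values.

A few printed cells are arithmetically inconsistent with their own integer
counts (the C. difficile full-element percentage and four of the six
copy-number means); those are flagged ``consistent=False`` below and are
not used as reproduction checks.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpeciesCounts:
    species: str
    n_genomes: int
    n_loci: int                 # "detected elements"
    n_tcmes: int
    n_positive: int             # genomes containing >= 1 element
    n_full: int
    printed_pct_positive: int
    printed_mean: float
    printed_sd: float
    printed_pct_full: int
    mean_consistent: bool       # printed mean equals n_tcmes / n_positive
    pct_full_consistent: bool


TABLE1 = (
    SpeciesCounts("B. cereus", 152, 687, 687, 126, 520, 83, 5.28, 3.73, 76,
                  False, True),
    SpeciesCounts("C. difficile", 133, 1875, 1875, 132, 1760, 99, 14.15, 6.82, 93,
                  False, False),
    SpeciesCounts("D. radiodurans", 12, 52, 44, 12, 44, 100, 3.67, 1.65, 100,
                  True, True),
    SpeciesCounts("E. coli", 2467, 4837, 4825, 2325, 4412, 94, 2.05, 0.94, 91,
                  False, True),
    SpeciesCounts("H. pylori", 335, 735, 734, 214, 678, 64, 3.43, 2.99, 92,
                  True, True),
    SpeciesCounts("S. enterica", 1495, 1875, 1831, 658, 757, 44, 1.25, 0.61, 41,
                  False, True),
)


@dataclass(frozen=True)
class GroupCounts:
    species: str
    n_genomes: int
    subgroup_positive: dict[str, int]       # genomes containing the subgroup
    group_totals: dict[str, int]            # genomes containing the group
    printed_subgroup_pct: dict[str, float]
    printed_total_pct: dict[str, float]


TABLE2 = (
    GroupCounts("B. cereus", 152,
                {"IS605a": 0, "IS605b": 82, "IS605c": 0,
                 "IS607a": 39, "IS607b": 12, "IS1341": 112},
                {"IS605": 82, "IS607": 48, "IS1341": 112},
                {"IS605b": 53.95, "IS607a": 25.66, "IS607b": 7.89,
                 "IS1341": 73.68},
                {"IS605": 53.95, "IS607": 31.58, "IS1341": 73.68}),
    GroupCounts("C. difficile", 133,
                {"IS605a": 56, "IS605b": 132, "IS605c": 0,
                 "IS607a": 0, "IS607b": 15, "IS1341": 106},
                {"IS605": 132, "IS607": 15, "IS1341": 106},
                {"IS605a": 42.11, "IS605b": 99.25, "IS607b": 11.28,
                 "IS1341": 79.70},
                {"IS605": 99.25, "IS607": 11.28, "IS1341": 79.70}),
    GroupCounts("D. radiodurans", 12,
                {"IS605a": 12, "IS605b": 0, "IS605c": 0,
                 "IS607a": 0, "IS607b": 0, "IS1341": 0},
                {"IS605": 12, "IS607": 0, "IS1341": 0},
                {"IS605a": 100.0},
                {"IS605": 100.0}),
    GroupCounts("E. coli", 2467,
                {"IS605a": 0, "IS605b": 0, "IS605c": 2242,
                 "IS607a": 0, "IS607b": 0, "IS1341": 312},
                {"IS605": 2242, "IS607": 0, "IS1341": 312},
                {"IS605c": 90.88, "IS1341": 12.65},
                {"IS605": 90.88, "IS1341": 12.65}),
    GroupCounts("H. pylori", 335,
                {"IS605a": 58, "IS605b": 0, "IS605c": 123,
                 "IS607a": 81, "IS607b": 0, "IS1341": 0},
                {"IS605": 177, "IS607": 81, "IS1341": 0},
                {"IS605a": 17.31, "IS605c": 36.72, "IS607a": 24.18},
                {"IS605": 52.84, "IS607": 24.18}),
    GroupCounts("S. enterica", 1495,
                {"IS605a": 0, "IS605b": 0, "IS605c": 303,
                 "IS607a": 0, "IS607b": 0, "IS1341": 418},
                {"IS605": 303, "IS607": 0, "IS1341": 418},
                {"IS605c": 20.27, "IS1341": 27.96},
                {"IS605": 20.27, "IS1341": 27.96}),
)

#: co-invaded genome counts reported in the survey's distribution section
COINVASION = {
    ("E. coli", ("IS605", "IS1341")): 229,
    ("S. enterica", ("IS605", "IS1341")): 63,
    ("H. pylori", ("IS605", "IS607")): 44,
    ("B. cereus", ("IS605", "IS607", "IS1341")): 26,
    ("C. difficile", ("IS605", "IS607", "IS1341")): 15,
}


def reconstruct_records(t1: SpeciesCounts):
    """A per-element record list consistent with the printed counts.

    The per-genome allocation of elements is not published; the cells this
    reconstruction is used to recompute (percentages, and means over
    positive genomes) are invariant to the allocation, so elements are
    spread round-robin over the positive genomes.
    """
    from .stats import ElementRecord

    genomes = [f"g{i:04d}" for i in range(t1.n_genomes)]
    recs = []
    for k in range(t1.n_tcmes):
        gid = genomes[k % t1.n_positive]
        completeness = "full" if k < t1.n_full else "truncated_LE"
        recs.append(ElementRecord(t1.species, gid, "IS605b", "IS605",
                                  completeness))
    for _ in range(t1.n_loci - t1.n_tcmes):
        recs.append(ElementRecord(t1.species, genomes[0], "unclassified",
                                  "unclassified", "truncated_both",
                                  is_locus=True, is_element=False))
    return recs, {t1.species: genomes}
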