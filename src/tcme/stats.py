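"""Per-species and per-subgroup invasion and copy-number summaries.

These reproduce the published table layouts: per species the number of
detected loci and retained elements, how many genomes carry at least one
element (count and integer percent), the mean copy number over positive
genomes (two decimals, with population standard deviation), and the
full-element fraction; per subgroup the number and percentage (two
decimals) of genomes containing it, with IS605/IS607 group totals; plus
co-invasion counts and pairwise protein identity statistics.

All rounding is half-up at the printed precision (Python's round() is
banker's rounding, so decimal quantisation is used instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

SUBGROUP_ORDER = ("IS605a", "IS605b", "IS605c", "IS607a", "IS607b", "IS1341")
GROUP_OF = {"IS605a": "IS605", "IS605b": "IS605", "IS605c": "IS605",
            "IS607a": "IS607", "IS607b": "IS607", "IS1341": "IS1341"}


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ElementRecord:
    """The minimal per-element facts the summaries need."""

    species: str
    genome_id: str
    subgroup: str                  # IS605a..IS1341, "unclassified"
    group: str                     # IS605 | IS607 | IS1341 | decay | unclassified
    completeness: str              # full | truncated_* | decay
    is_locus: bool = True          # counted among detected loci
    is_element: bool = True        # retained, classified TCME


def _check_census(records: list[ElementRecord], census: dict[str, list[str]]):
    known = {g for gs in census.values() for g in gs}
    missing = sorted({r.genome_id for r in records} - known)
    if missing:
        raise ValueError(f"genome ids absent from census: {missing}")


def species_summary(records: list[ElementRecord],
                    census: dict[str, list[str]]) -> pd.DataFrame:
    """One row per species mirroring the headline distribution table.

    ``census`` maps species -> all surveyed genome ids (including those
    without any element).  Mean copy number is over element-positive
    genomes only; its sd is the population standard deviation.
    """
    _check_census(records, census)
    rows = []
    for sp in census:
        genomes = census[sp]
        recs = [r for r in records if r.species == sp]
        loci = [r for r in recs if r.is_locus]
        elems = [r for r in recs if r.is_element]
        per_genome: dict[str, int] = {}
        for r in elems:
            per_genome[r.genome_id] = per_genome.get(r.genome_id, 0) + 1
        n_pos = len(per_genome)
        counts = np.array(list(per_genome.values()), dtype=float)
        full = [r for r in elems if r.completeness == "full"]
        n_elem = len(elems)
        rows.append({
            "species": sp,
            "n_genomes": len(genomes),
            "n_loci_detected": len(loci),
            "n_tcmes": n_elem,
            "n_genomes_with_tcme": n_pos,
            "pct_genomes_with_tcme": round_half_up(100.0 * n_pos / len(genomes))
            if genomes else float("nan"),
            "mean_copies": round_half_up(counts.mean(), 2) if n_pos else float("nan"),
            "sd_copies": round_half_up(float(counts.std()), 2) if n_pos else float("nan"),
            "n_full": len(full),
            "pct_full": round_half_up(100.0 * len(full) / n_elem)
            if n_elem else float("nan"),
        })
    return pd.DataFrame(rows)


def group_summary(records: list[ElementRecord],
                  census: dict[str, list[str]]) -> pd.DataFrame:
    """Per-species subgroup occupancy: genomes containing each subgroup
    (count and two-decimal percent of all surveyed genomes) and the
    IS605/IS607 group totals (a genome with several subgroups counts once
    in its group total)."""
    _check_census(records, census)
    rows = []
    for sp in census:
        n_genomes = len(census[sp])
        recs = [r for r in records if r.species == sp and r.is_element]
        row: dict[str, object] = {"species": sp, "n_genomes": n_genomes}
        group_genomes: dict[str, set] = {"IS605": set(), "IS607": set(),
                                         "IS1341": set()}
        for sg in SUBGROUP_ORDER:
            gset = {r.genome_id for r in recs if r.subgroup == sg
                    and r.group == GROUP_OF[sg]}
            row[f"{sg}_n"] = len(gset)
            row[f"{sg}_pct"] = round_half_up(100.0 * len(gset) / n_genomes, 2) \
                if n_genomes else float("nan")
            group_genomes[GROUP_OF[sg]] |= gset
        for grp in ("IS605", "IS607", "IS1341"):
            row[f"{grp}_total_n"] = len(group_genomes[grp])
            row[f"{grp}_total_pct"] = round_half_up(
                100.0 * len(group_genomes[grp]) / n_genomes, 2) \
                if n_genomes else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def coinvasion_counts(records: list[ElementRecord],
                      census: dict[str, list[str]],
                      groups: tuple[str, ...]) -> dict[str, int]:
    """Per species: genomes containing at least one element of every
    listed group."""
    if not groups:
        raise ValueError("no groups given")
    valid = {"IS605", "IS607", "IS1341", "decay"}
    unknown = set(groups) - valid
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    _check_census(records, census)
    out = {}
    for sp in census:
        per_genome: dict[str, set] = {}
        for r in records:
            if r.species == sp and r.is_element:
                per_genome.setdefault(r.genome_id, set()).add(r.group)
        out[sp] = sum(1 for gs in per_genome.values()
                      if all(g in gs for g in groups))
    return out


@dataclass(frozen=True)
class IdentityStats:
    protein_class: str
    n: int
    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float


def identity_stats(proteins: dict[str, str], protein_class: str,
                   band_slack: int | None = None) -> IdentityStats | None:
    """Mean ± population sd and range of all unordered pairwise
    identities, as percentages; None for fewer than two proteins."""
    from .cluster import pairwise_identity

    ids = sorted(proteins)
    if len(ids) < 2:
        return None
    vals = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            vals.append(pairwise_identity(proteins[ids[i]], proteins[ids[j]],
                                          band_slack=band_slack))
    v = 100.0 * np.array(vals)
    return IdentityStats(protein_class, len(ids),
                         round_half_up(float(v.mean()), 2),
                         round_half_up(float(v.std()), 2),
                         round_half_up(float(v.min()), 2),
                         round_half_up(float(v.max()), 2))
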