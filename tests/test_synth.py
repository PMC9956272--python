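"""Template construction and dataset simulation invariants."""

import numpy as np
import pytest

from tcme.genetics import revcomp, translate
from tcme.motifs import find_sr_motif, find_y1_motif
from tcme.repeats import find_direct_repeats, find_inverted_repeats
from tcme.synth import (SUBGROUPS, GroupPriors, SimulationConfig,
                        make_seed_proteins, make_templates, mutate_sequence,
                        simulate_dataset)

_GROUP_RANGES = {
    "IS605a": "is605_length_range", "IS605b": "is605_length_range",
    "IS605c": "is605_length_range", "IS607a": "is607_length_range",
    "IS607b": "is607_length_range", "IS1341": "is1341_short_range",
}


@pytest.mark.parametrize("subgroup", SUBGROUPS)
def test_template_structure(templates_by_subgroup, priors, subgroup):
    t = templates_by_subgroup[subgroup]
    lo, hi = getattr(priors, _GROUP_RANGES[subgroup])
    assert lo <= t.length <= hi

    # reading frames reproduce the recorded proteins
    s, e = t.tnpb_cds
    assert translate(t.sequence[s:e]) == t.tnpb_protein + "*"
    if subgroup == "IS1341":
        assert t.orfa_cds is None
    else:
        a = t.sequence[t.orfa_cds[0]:t.orfa_cds[1]]
        if t.orfa_strand == "-":
            a = revcomp(a)
        assert translate(a) == t.orfa_protein + "*"

    # ORF arrangement per structural subgroup
    if subgroup in ("IS605a", "IS607a"):
        assert t.orfa_strand == "+"
        overlap = t.orfa_cds[1] - t.tnpb_cds[0]
        assert overlap >= 1
    elif subgroup in ("IS605b", "IS607b"):
        assert t.orfa_strand == "+"
        assert t.orfa_cds[1] < t.tnpb_cds[0]
    elif subgroup == "IS605c":
        assert t.orfa_strand == "-"

    # catalytic motifs
    prot = t.tnpb_protein
    d1 = prot.find("D")
    e1 = prot.find("E", d1 + 1)
    assert d1 != -1 and e1 != -1 and prot.find("D", e1 + 1) != -1
    if subgroup.startswith("IS605"):
        assert find_y1_motif(t.orfa_protein) is not None
    elif subgroup.startswith("IS607"):
        assert find_sr_motif(t.orfa_protein) is not None


@pytest.mark.parametrize("subgroup", SUBGROUPS)
def test_template_ends(templates_by_subgroup, subgroup):
    t = templates_by_subgroup[subgroup]
    le = t.sequence[t.le.start:t.le.end]
    re_ = t.sequence[t.re.start:t.re.end]
    assert t.sequence[:4] == t.le.tetramer
    assert t.sequence[-4:] == t.re.tetramer
    if subgroup.startswith("IS607"):
        for block in (le, re_):
            assert find_inverted_repeats(block) == []
            drs = find_direct_repeats(block)
            assert any(len(d.occurrence_starts) >= 2 for d in drs)
    else:
        for block, spec in ((le, t.le), (re_, t.re)):
            arm = block[: spec.arm_len]
            arm2 = block[-spec.arm_len:]
            assert revcomp(arm) == arm2        # perfect palindrome


def test_templates_deterministic(priors):
    a = make_templates(priors, seed=11)
    b = make_templates(priors, seed=11)
    assert [t.sequence for t in a] == [t.sequence for t in b]
    c = make_templates(priors, seed=12)
    assert [t.sequence for t in a] != [t.sequence for t in c]


def test_infeasible_priors_raise():
    bad = GroupPriors(is1341_short_range=(300, 320))
    with pytest.raises(ValueError):
        make_templates(bad, seed=0, subgroups=("IS1341",))


def test_dataset_determinism_and_conservation(templates):
    cfg = SimulationConfig(species=("Synthetica alpha",),
                           n_genomes_per_species=2, genome_length=80_000,
                           n_contigs=1, seed=3)
    g1, l1 = simulate_dataset(cfg, templates)
    g2, l2 = simulate_dataset(cfg, templates)
    assert [g.contigs for g in g1] == [g.contigs for g in g2]
    assert l1.to_rows() == l2.to_rows()
    # conservation: every record lies within its contig and matches the
    # planted copy exactly (plant-ability)
    for r in l1:
        g = next(x for x in g1 if x.genome_id == r.genome_id)
        assert 0 <= r.start < r.end <= len(g.contigs[r.contig_id])
        assert g.contigs[r.contig_id][r.start:r.end] == r.planted_seq


def test_requested_copies_appear_in_ledger(templates):
    cfg = SimulationConfig(species=("Synthetica alpha",),
                           n_genomes_per_species=1, genome_length=80_000,
                           n_contigs=1,
                           copy_number_distribution={"IS605b": 3.0},
                           poisson_copy_numbers=False,
                           truncation_fraction=0.0, decay_fraction=0.0,
                           seed=4)
    _g, ledger = simulate_dataset(cfg, templates)
    assert sum(1 for r in ledger if r.subgroup == "IS605b") == 3
    assert len(ledger) == 3


def test_zero_noise_copies_are_exact_substrings(templates):
    cfg = SimulationConfig(species=("Synthetica alpha",),
                           n_genomes_per_species=1, genome_length=120_000,
                           n_contigs=1, divergence=0.0,
                           truncation_fraction=0.0, decay_fraction=0.0,
                           seed=5)
    genomes, ledger = simulate_dataset(cfg, templates)
    by_id = {t.template_id: t for t in templates}
    assert len(ledger) > 0
    for r in ledger:
        tpl = by_id[r.template_id]
        planted = r.planted_seq if r.strand == "+" else revcomp(r.planted_seq)
        assert planted == tpl.sequence


def _brute_remnant(flank: str, ref: str, k: int) -> bool:
    """Any shared ungapped k-mer between flank and ref (either strand)."""
    for target in (ref, revcomp(ref)):
        kmers = {target[i:i + k] for i in range(len(target) - k + 1)}
        if any(flank[i:i + k] in kmers for i in range(len(flank) - k + 1)):
            return True
    return False


@pytest.mark.parametrize("remnant_len,expected", [(25, True), (15, False)])
def test_decay_remnant_present_iff_long_enough(templates, remnant_len, expected):
    cfg = SimulationConfig(species=("Synthetica alpha",),
                           n_genomes_per_species=2, genome_length=120_000,
                           n_contigs=1, divergence=0.0,
                           truncation_fraction=0.0, decay_fraction=1.0,
                           decay_remnant_len=remnant_len,
                           copy_number_distribution={"IS1341": 2.0},
                           poisson_copy_numbers=False, seed=6)
    genomes, ledger = simulate_dataset(cfg, templates)
    decays = [r for r in ledger if r.completeness == "decay"]
    assert decays
    by_id = {t.template_id: t for t in templates}
    for r in decays:
        donor = by_id[r.template_id]
        s, e = donor.orfa_cds
        orfa_cds = donor.sequence[s:e]
        if donor.orfa_strand == "-":
            orfa_cds = revcomp(orfa_cds)
        planted = r.planted_seq
        # the remnant region sits between the planted ends and the TnpB CDS
        assert _brute_remnant(planted, orfa_cds, 21) is expected


def test_genome_too_short_raises(templates):
    cfg = SimulationConfig(species=("Synthetica alpha",),
                           n_genomes_per_species=1, genome_length=8_000,
                           n_contigs=1, min_separation=3500,
                           copy_number_distribution={"IS605b": 6.0},
                           poisson_copy_numbers=False, seed=1)
    with pytest.raises(ValueError):
        simulate_dataset(cfg, templates)


def test_negative_copy_numbers_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(copy_number_distribution={"IS605a": -1.0})


def test_mutation_respects_protection_and_frames(templates):
    tpl = next(t for t in templates if t.subgroup == "IS605b")
    rng = np.random.default_rng(0)
    mutated = mutate_sequence(tpl.sequence, 120, rng, set(tpl.protected),
                              list(tpl.cds_list))
    assert mutated != tpl.sequence
    for p in tpl.protected:
        assert mutated[p] == tpl.sequence[p]
    # reading frames stay open and stop-free internally
    s, e = tpl.tnpb_cds
    prot = translate(mutated[s:e])
    assert "*" not in prot[:-1] and prot[-1] == "*"
    s, e = tpl.orfa_cds
    a = mutated[s:e]
    if tpl.orfa_strand == "-":
        a = revcomp(a)
    prot = translate(a)
    assert "*" not in prot[:-1] and prot[-1] == "*"


def test_seed_protein_set_composition():
    seeds = make_seed_proteins(seed=101)
    lens = [len(v) for v in seeds.values()]
    assert any(l < 200 for l in lens)      # short rejects present
    assert any(l > 600 for l in lens)      # long rejects present
    assert sum(200 <= l <= 600 for l in lens) >= 20
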