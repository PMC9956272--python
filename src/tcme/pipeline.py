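"""End-to-end mining pipeline: profile → scan → loci → annotate →
cluster → families → phylogeny → summary tables.

``run_pipeline`` executes every stage on in-memory inputs and, when an
output directory is given, writes the standard files (TSV tables, GFF3,
aligned FASTA, Newick, PHYLIP) together with a manifest holding the
resolved configuration and SHA-256 checksums of the inputs.  All stages
are deterministic under the configured seed; nothing reads the clock, so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, field, replace

import yaml

from . import io as tio
from .annotate import AnnotationParams, Element, annotate_locus, assign_family, \
    group_hits_to_loci
from .cluster import Cluster, IdentityParams, center_star_msa, consensus, \
    greedy_cluster, pairwise_identity
from .phylo import bootstrap_support, label_branches, protein_distance, \
    write_phylip
from .profile import CurationThresholds, ProteinHit, RuvCProfile, \
    build_profile_from_seeds, calibrate_threshold, scan_genome
from .stats import ElementRecord, IdentityStats, coinvasion_counts, \
    group_summary, identity_stats, species_summary
from .synth import Genome, ReferenceEntry


@dataclass(frozen=True)
class PipelineConfig:
    """The mining thresholds (published defaults) plus run controls."""

    curation: CurationThresholds = CurationThresholds()
    annotation: AnnotationParams = AnnotationParams()
    locus_cluster_identity: float = 0.70
    family_cluster_identity: float = 0.90
    bootstrap_replicates: int = 1000
    calibration_decoys: int = 1000
    calibration_percentile: float = 99.9
    band_slack: int = 200          # identity-alignment band for long loci
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


@dataclass
class FamilyRecord:
    family_id: str
    species: str
    name: str
    consensus: str
    member_elements: list[int]     # indices into the element list
    representative: int


@dataclass
class PipelineResult:
    profile: RuvCProfile
    threshold: float
    hits: list[ProteinHit]
    elements: list[Element]
    families: list[FamilyRecord]
    locus_clusters: dict[str, list[Cluster]]
    species_table: object
    group_table: object
    coinvasion: dict[tuple[str, ...], dict[str, int]]
    identity: list[IdentityStats]
    trees: dict[str, object]
    branch_labels: dict[str, str]
    stage_counts: dict[str, int]


def _sha256(data: str | bytes) -> str:
    if isinstance(data, str):
        data = data.encode()
    return hashlib.sha256(data).hexdigest()


def run_pipeline(config: PipelineConfig,
                 genomes: list[Genome],
                 seed_proteins: dict[str, str],
                 references: list[ReferenceEntry] | None = None,
                 outgroup: dict[str, str] | None = None,
                 outdir: str | None = None,
                 log=print) -> PipelineResult:
    """Run every mining stage; optionally write outputs under outdir."""
    import warnings

    if not genomes:
        raise ValueError("run_pipeline: no genomes")
    references = references or []
    if not references:
        warnings.warn("no reference library: every family will be named new")
    counts: dict[str, int] = {}
    ap = config.annotation

    # 1. profile + threshold calibration
    profile = build_profile_from_seeds(seed_proteins, config.curation)
    threshold = calibrate_threshold(
        profile, genomes, seed=config.seed + 1,
        n_decoys=config.calibration_decoys,
        percentile=config.calibration_percentile)
    counts["profile_columns"] = profile.n_columns
    log(f"[profile] {profile.n_columns} columns, threshold "
        f"{threshold:.1f} bits")

    # 2. scan + loci
    hits: list[ProteinHit] = []
    loci_by_genome = {}
    for g in genomes:
        ghits = scan_genome(profile, g, threshold, config.curation.min_hit_len)
        hits.extend(ghits)
        loci_by_genome[g.genome_id] = group_hits_to_loci(ghits, g, ap.flank)
    counts["hits"] = len(hits)
    counts["loci"] = sum(len(v) for v in loci_by_genome.values())
    log(f"[scan] {counts['hits']} hits -> {counts['loci']} loci")

    # 3. per-species locus clustering at 70% (reporting/consensus level)
    species_of = {g.genome_id: g.species for g in genomes}
    locus_seqs_by_species: dict[str, dict[str, str]] = {}
    for gid, loci in loci_by_genome.items():
        sp = species_of[gid]
        d = locus_seqs_by_species.setdefault(sp, {})
        for i, loc in enumerate(loci):
            d[f"{gid}:{loc.contig_id}:{loc.start}"] = loc.sequence
    locus_clusters = {
        sp: greedy_cluster(seqs, config.locus_cluster_identity,
                           band_slack=config.band_slack)
        for sp, seqs in sorted(locus_seqs_by_species.items())}
    counts["locus_clusters"] = sum(len(v) for v in locus_clusters.values())

    # 4. annotation (decay references: library ORFA CDS, then augmented
    #    with the ORFA CDS of the elements detected in this run)
    decay_refs = sorted({r.orfa_cds for r in references if r.orfa_cds})
    orfbs = [r.tnpb_protein for r in references]
    elements: list[Element] = []
    by_genome = {g.genome_id: g for g in genomes}
    for gid in sorted(loci_by_genome):
        g = by_genome[gid]
        for loc in loci_by_genome[gid]:
            e = annotate_locus(loc, g.species, profile, threshold,
                               decay_refs, orfbs, ap)
            if e is not None:
                elements.append(e)
    detected_orfa = sorted({e.orfa_cds_seq for e in elements
                            if e.orfa_cds_seq and e.subgroup in
                            ("IS605a", "IS605b", "IS605c", "IS607a", "IS607b")})
    if detected_orfa:
        from .annotate import has_flank_remnant
        # family-level ORFA references: deduplicate the detected CDS set at
        # 90% so the remnant search runs against a handful of distinct
        # sequences, not one near-copy per element (whose sheer number
        # would inflate the chance-match rate of the >20 bp rule)
        orfa_reps = greedy_cluster(
            {f"a{i:04d}": s for i, s in enumerate(detected_orfa)},
            0.90, band_slack=config.band_slack)
        rep_seqs = {detected_orfa[int(c.representative_id[1:])]
                    for c in orfa_reps}
        all_refs = sorted(set(decay_refs) | rep_seqs)
        for e in elements:
            if e.subgroup == "IS1341" and not e.decay_flag:
                # regions between the element ends (or the boundary search
                # window, for ends that went undetected) and the TnpB CDS,
                # taken from the contig so a missing boundary cannot empty
                # the search region; both orientations are checked inside
                # has_flank_remnant, so contig orientation is immaterial
                contig = by_genome[e.genome_id].contigs[e.contig_id]
                tnpb = max((o for o in e.orfs if o.role == "TnpB"),
                           key=lambda o: o.score)
                ts = e.locus_start + tnpb.start
                te = e.locus_start + tnpb.end
                left = contig[max(0, min(e.start, ts - ap.boundary_window)):ts]
                right = contig[te:max(e.end, min(len(contig),
                                                 te + ap.boundary_window))]
                e.decay_flag = has_flank_remnant(
                    left, right, all_refs, ap.decay_min_match,
                    ap.decay_min_identity, ap.decay_exact)
    counts["elements"] = len(elements)
    counts["decays"] = sum(e.decay_flag for e in elements)
    log(f"[annotate] {counts['elements']} elements "
        f"({counts['decays']} decays)")

    # 5. family clustering at 90% on full elements, per species
    families: list[FamilyRecord] = []
    for sp in sorted({e.species for e in elements}):
        idx = [i for i, e in enumerate(elements)
               if e.species == sp and e.completeness == "full"
               and e.subgroup != "unclassified" and not e.decay_flag]
        if not idx:
            continue
        seqs = {f"e{i:05d}": elements[i].sequence for i in idx}
        clusters = greedy_cluster(seqs, config.family_cluster_identity,
                                  band_slack=config.band_slack)
        fam_inputs = []
        for ci, cl in enumerate(clusters):
            fid = f"{sp}:fam{ci:03d}"
            members = [int(m[1:]) for m in cl.member_ids]
            # consensus over up to 8 members keeps the MSA desk-sized
            sub = {m: seqs[m] for m in cl.member_ids[:8]}
            cons = consensus(center_star_msa(sub)).sequence \
                if len(sub) > 1 else seqs[cl.member_ids[0]]
            rep = int(cl.representative_id[1:])
            families.append(FamilyRecord(fid, sp, "", cons, members, rep))
            fam_inputs.append((fid, cons, elements[rep]))
        names = assign_family(fam_inputs, references, sp, params=ap)
        for fam in families:
            if fam.family_id in names:
                fam.name = names[fam.family_id]
        for fam in families:
            for m in fam.member_elements:
                elements[m].family = fam.name
    # non-full elements adopt the best-matching family of their species
    for i, e in enumerate(elements):
        if e.family or e.subgroup == "unclassified":
            continue
        best = ("", 0.0)
        for fam in families:
            if fam.species != e.species:
                continue
            ident = pairwise_identity(e.sequence, fam.consensus,
                                      band_slack=config.band_slack)
            if ident > best[1]:
                best = (fam.name, ident)
        if best[1] >= config.locus_cluster_identity:
            e.family = best[0]
    counts["families"] = len(families)
    counts["known_families"] = sum(
        1 for f in families if not f.name.startswith("IS" + _abbrev(f.species)))
    log(f"[families] {counts['families']} families")

    # 6. phylogeny per protein class (family representatives + outgroup)
    trees = {}
    branch_labels: dict[str, str] = {}
    class_proteins: dict[str, dict[str, str]] = {"TnpB": {}, "Y1": {}, "SR": {}}
    for fam in families:
        rep = elements[fam.representative]
        class_proteins["TnpB"][fam.name or fam.family_id] = rep.tnpb_protein
        if rep.orfa_protein:
            role = "Y1" if rep.subgroup.startswith("IS605") else "SR"
            class_proteins[role][fam.name or fam.family_id] = rep.orfa_protein
    from .profile import score_local
    for cls, prots in class_proteins.items():
        taxa = dict(prots)
        if cls == "TnpB" and outgroup:
            taxa.update(outgroup)
        if cls == "TnpB":
            # align the RuvC core segments (profile-matched spans): the
            # flanks are family-specific and carry no cross-family signal
            cores = {}
            for name, prot in taxa.items():
                _sc, _cols, (ts, te) = score_local(profile, prot)
                seg = prot[max(0, ts - 10): te + 10]
                if len(seg) >= 30:
                    cores[name] = seg
            taxa = cores
        if len(taxa) < 3:
            continue
        aln = center_star_msa(taxa, free_ends=False)
        tree = bootstrap_support(aln, config.bootstrap_replicates,
                                 seed=config.seed + 2)
        trees[cls] = tree
        if cls == "TnpB" and outgroup:
            branch_labels = label_branches(tree, set(outgroup))
    counts["trees"] = len(trees)

    # 7. summary statistics
    census: dict[str, list[str]] = {}
    for g in genomes:
        census.setdefault(g.species, []).append(g.genome_id)
    records = []
    for gid, loci in loci_by_genome.items():
        n_elem_loci = sum(1 for e in elements if e.genome_id == gid)
        # loci dropped by annotation still count as detected
        for _ in range(len(loci) - n_elem_loci):
            records.append(ElementRecord(species_of[gid], gid, "unclassified",
                                         "unclassified", "truncated_both",
                                         is_locus=True, is_element=False))
    for e in elements:
        records.append(ElementRecord(
            e.species, e.genome_id, e.subgroup, e.group,
            "decay" if e.decay_flag else e.completeness,
            is_locus=True,
            is_element=e.group in ("IS605", "IS607", "IS1341")))
    species_table = species_summary(records, census)
    group_table = group_summary(records, census)
    coinv = {}
    for combo in (("IS605", "IS607"), ("IS605", "IS1341"),
                  ("IS607", "IS1341"), ("IS605", "IS607", "IS1341")):
        coinv[combo] = coinvasion_counts(records, census, combo)
    ident = []
    for cls, prots in class_proteins.items():
        st = identity_stats(prots, cls)
        if st is not None:
            ident.append(st)
    log(f"[stats] {len(species_table)} species rows")

    result = PipelineResult(profile, threshold, hits, elements, families,
                            locus_clusters, species_table, group_table,
                            coinv, ident, trees, branch_labels, counts)
    if outdir is not None:
        _write_outputs(result, config, genomes, outdir)
    return result


def _abbrev(species: str) -> str:
    from .synth import species_abbrev
    return species_abbrev(species)


def _write_outputs(res: PipelineResult, config: PipelineConfig,
                   genomes: list[Genome], outdir: str):
    os.makedirs(outdir, exist_ok=True)
    tio.write_hits_tsv(res.hits, os.path.join(outdir, "hits.tsv"))
    max_s = max((h.score for h in res.hits), default=1.0)
    tio.write_hits_bed(res.hits, os.path.join(outdir, "hits.bed"), max_s)
    tio.write_elements_tsv(res.elements, os.path.join(outdir, "elements.tsv"))
    tio.write_elements_gff3(res.elements, os.path.join(outdir, "elements.gff3"))
    tio.write_fasta({f.name or f.family_id: f.consensus for f in res.families},
                    os.path.join(outdir, "family_consensus.fasta"))
    res.species_table.to_csv(os.path.join(outdir, "species_summary.tsv"),
                             sep="\t", index=False)
    res.group_table.to_csv(os.path.join(outdir, "group_summary.tsv"),
                           sep="\t", index=False)
    with open(os.path.join(outdir, "coinvasion.tsv"), "w") as fh:
        fh.write("groups\tspecies\tn_genomes\n")
        for combo, per_sp in res.coinvasion.items():
            for sp, n in sorted(per_sp.items()):
                fh.write(f"{'+'.join(combo)}\t{sp}\t{n}\n")
    with open(os.path.join(outdir, "identity_stats.tsv"), "w") as fh:
        fh.write("class\tn\tmean_pct\tsd_pct\tmin_pct\tmax_pct\n")
        for st in res.identity:
            fh.write(f"{st.protein_class}\t{st.n}\t{st.mean_pct}\t{st.sd_pct}"
                     f"\t{st.min_pct}\t{st.max_pct}\n")
    for cls, tree in res.trees.items():
        with open(os.path.join(outdir, f"tree_{cls}.nwk"), "w") as fh:
            fh.write(tree.newick() + "\n")
    if res.branch_labels:
        with open(os.path.join(outdir, "branch_labels.tsv"), "w") as fh:
            fh.write("taxon\tbranch\n")
            for t, b in sorted(res.branch_labels.items()):
                fh.write(f"{t}\t{b}\n")
    # manifest: resolved config + input checksums + stage counts (no clock)
    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "inputs": {g.genome_id: _sha256("".join(
            g.contigs[c] for c in sorted(g.contigs))) for g in genomes},
        "stage_counts": dict(sorted(res.stage_counts.items())),
        "threshold_bits": round(res.threshold, 4),
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
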