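"""Readers and writers for the pipeline's on-disk formats.

Genomes travel as multi-FASTA (one file per genome, headers
``<genome_id>|<contig_id>``) with a sidecar species table; the truth
ledger, hits, clusters and element tables as TSV with headers; elements
additionally as GFF3 (1-based inclusive) and hits optionally as BED6
(0-based half-open).  FASTA handling is Biopython's.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Element
from .profile import ProteinHit
from .synth import Genome, ReferenceEntry, TruthLedger, TruthRecord

_VALID_NT = set("ACGTN")


def write_fasta(seqs: dict[str, str], path: str):
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(path, "fasta")):
        if not rec.seq:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) is empty")
        if rec.id in out:
            raise ValueError(f"{path}: record {i} duplicates id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_genome_fasta(genome: Genome, path: str):
    write_fasta({f"{genome.genome_id}|{cid}": seq
                 for cid, seq in sorted(genome.contigs.items())}, path)


def write_genomes(genomes: list[Genome], outdir: str) -> str:
    """One FASTA per genome plus a genomes.tsv species table; returns the
    table path."""
    os.makedirs(outdir, exist_ok=True)
    table = os.path.join(outdir, "genomes.tsv")
    with open(table, "w") as fh:
        fh.write("genome_id\tspecies\tfasta\n")
        for g in genomes:
            fa = os.path.join(outdir, f"{g.genome_id}.fasta")
            write_genome_fasta(g, fa)
            fh.write(f"{g.genome_id}\t{g.species}\t{os.path.basename(fa)}\n")
    return table


def read_genomes(table_path: str) -> list[Genome]:
    base = os.path.dirname(table_path)
    genomes = []
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["genome_id", "species", "fasta"]:
            raise ValueError(f"{table_path}: unexpected header {header}")
        for line in fh:
            gid, species, fa = line.rstrip("\n").split("\t")
            contigs = {}
            for i, (name, seq) in enumerate(read_fasta(os.path.join(base, fa)).items()):
                if "|" not in name:
                    raise ValueError(f"{fa}: record {i} header lacks "
                                     "'<genome_id>|<contig_id>'")
                rec_gid, cid = name.split("|", 1)
                if rec_gid != gid:
                    raise ValueError(f"{fa}: record {i} genome id mismatch")
                bad = set(seq) - _VALID_NT
                if bad:
                    raise ValueError(f"{fa}: record {i} has invalid "
                                     f"characters {sorted(bad)}")
                contigs[cid] = seq
            genomes.append(Genome(gid, species, contigs))
    return genomes


LEDGER_COLS = ("genome_id", "contig_id", "start", "end", "strand",
               "subgroup", "completeness", "template_id")


def write_ledger(ledger: TruthLedger, path: str):
    with open(path, "w") as fh:
        fh.write("\t".join(LEDGER_COLS) + "\n")
        for row in ledger.to_rows():
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_ledger(path: str) -> TruthLedger:
    ledger = TruthLedger()
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != LEDGER_COLS:
            raise ValueError(f"{path}: unexpected ledger header")
        for line in fh:
            gid, cid, s, e, strand, sg, comp, tid = line.rstrip("\n").split("\t")
            ledger.records.append(TruthRecord(gid, cid, int(s), int(e),
                                              strand, sg, comp, tid))
    return ledger


def write_hits_tsv(hits: Iterable[ProteinHit], path: str):
    with open(path, "w") as fh:
        fh.write("genome_id\tcontig_id\tstrand\tframe\tgenomic_start\t"
                 "genomic_end\tscore\tmatched_len\n")
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.contig_id}\t{h.strand}\t{h.frame}\t"
                     f"{h.genomic_start}\t{h.genomic_end}\t{h.score:.2f}\t"
                     f"{h.matched_len}\n")


def write_hits_bed(hits: Iterable[ProteinHit], path: str, max_score: float):
    """BED6; scores scaled into 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            s = 0 if max_score <= 0 else min(1000, int(1000 * h.score / max_score))
            fh.write(f"{h.contig_id}\t{h.genomic_start}\t{h.genomic_end}\t"
                     f"{h.genome_id}\t{s}\t{h.strand}\n")


ELEMENT_COLS = ("genome_id", "species", "contig_id", "start", "end", "strand",
                "group", "subgroup", "completeness", "decay", "family",
                "length", "le_tetramer", "re_tetramer")


def write_elements_tsv(elements: Iterable[Element], path: str):
    with open(path, "w") as fh:
        fh.write("\t".join(ELEMENT_COLS) + "\n")
        for e in elements:
            fh.write("\t".join(str(x) for x in (
                e.genome_id, e.species, e.contig_id, e.start, e.end, e.strand,
                e.group, e.subgroup, e.completeness, int(e.decay_flag),
                e.family, e.length,
                e.le.cleavage_tetramer if e.le else ".",
                e.re.cleavage_tetramer if e.re else ".")) + "\n")


def write_elements_gff3(elements: Iterable[Element], path: str):
    """GFF3 (1-based inclusive): mobile_genetic_element records with child
    CDS features for the role-assigned ORFs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, e in enumerate(elements):
            eid = f"tcme{i:05d}"
            attrs = (f"ID={eid};subgroup={e.subgroup};group={e.group};"
                     f"completeness={e.completeness};family={e.family or '.'};"
                     f"cleavage_LE={e.le.cleavage_tetramer if e.le else '.'};"
                     f"cleavage_RE={e.re.cleavage_tetramer if e.re else '.'}")
            fh.write(f"{e.contig_id}\ttcme\tmobile_genetic_element\t"
                     f"{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n")
            for j, o in enumerate(e.orfs):
                if o.role == "unknown":
                    continue
                cs, ce = e.locus_start + o.start, e.locus_start + o.end
                fh.write(f"{e.contig_id}\ttcme\tCDS\t{cs + 1}\t{ce}\t"
                         f".\t{o.strand}\t0\tID={eid}.orf{j};Parent={eid};"
                         f"role={o.role}\n")
    return path


def write_clusters_tsv(clusters, path: str):
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\tidentity_to_rep\n")
        for i, cl in enumerate(clusters):
            for m in cl.member_ids:
                fh.write(f"cl{i:04d}\t{cl.representative_id}\t{m}\t"
                         f"{cl.identities.get(m, 1.0):.4f}\n")


def write_alignment_fasta(aln, path: str):
    write_fasta(dict(zip(aln.ids, aln.rows)), path)


def write_references(refs: list[ReferenceEntry], fasta_path: str, tsv_path: str):
    write_fasta({r.name: r.sequence for r in refs}, fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("name\tsubgroup\tle_tetramer\tre_tetramer\ttnpb_protein\t"
                 "orfa_protein\torfa_role\torfa_cds\n")
        for r in refs:
            fh.write(f"{r.name}\t{r.subgroup}\t{r.le_tetramer}\t{r.re_tetramer}"
                     f"\t{r.tnpb_protein}\t{r.orfa_protein}\t{r.orfa_role}\t"
                     f"{r.orfa_cds}\n")


def read_references(tsv_path: str, fasta_path: str | None = None) -> list[ReferenceEntry]:
    seqs = read_fasta(fasta_path) if fasta_path else {}
    out = []
    with open(tsv_path) as fh:
        fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(ReferenceEntry(f[0], f[1], seqs.get(f[0], ""),
                                      f[2], f[3], f[4], f[5], f[6], f[7]))
    return out
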