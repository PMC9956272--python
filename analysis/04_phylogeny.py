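#!/usr/bin/env python
"""Neighbor-joining trees of the recovered protein families.

Aligns the family-representative TnpB proteins (plus the IscB-like
outgroup), builds the NJ tree with 1000 bootstrap replicates, roots on
the outgroup and reports the supported branch groups.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from tcme import io as tio
from tcme.cluster import center_star_msa
from tcme.phylo import bootstrap_support, label_branches, protein_distance, \
    write_phylip

SIM_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "sim")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 20230219


def main():
    fam = tio.read_fasta(os.path.join(RESULTS, "mining", "family_tnpb.fasta"))
    outgroup = tio.read_fasta(os.path.join(SIM_DIR, "outgroup.fasta"))
    taxa = dict(fam)
    taxa.update(outgroup)
    print(f"{len(fam)} family TnpB representatives + "
          f"{len(outgroup)} outgroup proteins")

    aln = center_star_msa(taxa, free_ends=False)
    tree = bootstrap_support(aln, b=1000, seed=SEED)
    labels = label_branches(tree, set(outgroup))

    outdir = os.path.join(RESULTS, "trees")
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tnpb_nj.nwk"), "w") as fh:
        fh.write(tree.newick() + "\n")
    dm = protein_distance(aln)
    with open(os.path.join(outdir, "tnpb_distances.phylip"), "w") as fh:
        fh.write(write_phylip(dm))
    with open(os.path.join(outdir, "branch_groups.tsv"), "w") as fh:
        fh.write("taxon\tbranch\n")
        for t, b in sorted(labels.items()):
            fh.write(f"{t}\t{b}\n")

    groups = {}
    for t, b in labels.items():
        groups.setdefault(b, []).append(t)
    print("branch groups (support >= 70, outgroup-rooted):")
    for b in sorted(groups):
        print(f"  TnpB-{b}: {', '.join(sorted(groups[b]))}")
    print(f"tree -> {os.path.relpath(os.path.join(outdir, 'tnpb_nj.nwk'))}")


if __name__ == "__main__":
    main()
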