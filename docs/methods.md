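# Methods

`tcme` re-implements, as a tested desk-scale pipeline, the procedure used
to survey TnpB-containing mobile elements (TCMEs — the IS605, IS607 and
IS1341 insertion-sequence groups) in bacterial genomes, and validates it
end to end on synthetic genomes with planted elements.  This note records
the models, the tunable parameters, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The mining procedure

The pipeline mirrors the published survey design stage by stage:

1. **Seed curation.** Candidate TnpB proteins shorter than 200 aa or
   longer than 600 aa are discarded (boundaries inclusive: the rule is
   strictly `<200` / `>600`).  The survivors are clustered at 80%
   identity by greedy incremental clustering and only cluster
   representatives proceed.
2. **Domain model.** The representative with the highest summed
   local-alignment score to all others acts as the domain anchor (the
   role the curated domain model plays in the original procedure); each
   representative contributes the segment its best local alignment to
   the anchor covers.  The segments are multiply aligned (center-star),
   the conserved block trimmed, rows with more than 20% gaps in that
   block discarded, and the remainder becomes a log-odds PSSM.
   Anchoring on local segments — rather than aligning full-length
   proteins — keeps the domain block contiguous regardless of how the
   unrelated flanks around each protein's domain are arranged.
3. **Scan.** All six reading frames of every contig are scored by local
   affine-gap alignment against the PSSM; hits shorter than 50 aa are
   discarded.
4. **Loci.** Each hit (overlapping hits merged) is extended by 1.7 kb on
   both sides; loci are clustered per species at 70% identity for
   family-level reporting.
5. **Annotation.** ORFs (ATG/GTG/TTG starts, in-frame stop, ≥50 codons)
   are predicted on both strands and given roles: TnpB by profile score,
   Y1 by the HuH triad with a downstream catalytic Y then Q, SR by a
   catalytic serine in the central third; each role also carries a
   length window derived from the published protein-length ranges
   (±15 aa tolerance; TnpB ±30 aa).  Subgroups follow the structural
   rules: Y1+TnpB same strand overlapping → IS605a, separated → IS605b,
   opposite strands → IS605c; SR+TnpB likewise → IS607a/IS607b; TnpB
   alone → IS1341.
6. **Boundaries.** Up to 250 nt outside the outermost ORF ends are
   searched for subterminal repeats; the 4 nt immediately external to the
   accepted repeat is the cleavage site.  An element is *full* iff both
   ends carry a detectable repeat with its cleavage tetramer.
7. **Decay rule.** An IS1341 candidate whose regions between the element
   ends and the TnpB CDS align to any Y1/SR CDS (either orientation)
   with **more than 20 identical positions** at ≥80% identity is
   reclassified as a decayed IS605/IS607 copy.
8. **Families.** Full elements are clustered per species at 90% identity;
   each cluster's consensus keeps a reference-library name when it is
   >90% identical to that reference *and* both boundary repeats were
   detected *and* both cleavage tetramers match; otherwise it gets a new
   name `IS<Abbrev><n>` (genus initial + two epithet letters, numbering
   per species).
9. **Phylogeny.** Family-representative proteins are aligned on their
   profile-matched core segments; pairwise p-distances over mutually
   ungapped columns feed classical neighbor joining (Saitou–Nei Q
   criterion, ties to the smallest index pair; negative branch estimates
   clamped to zero and flagged), with Felsenstein column-resampling
   bootstrap support and outgroup rooting.  Branch groups are the maximal
   supported (≥70%) proper ingroup clades plus one residual group.
10. **Summaries.** Per-species invasion percentages (integer, half-up),
    copy-number means over element-positive genomes (two decimals, with
    population sd), full-element fractions, per-subgroup occupancy
    percentages (two decimals), group totals (a genome carrying several
    subgroups counts once), co-invasion counts, and pairwise protein
    identity statistics.

### Simplifications relative to the tool chain it emulates

The original survey drove external tools (profile HMM software, cd-hit,
USEARCH, MAFFT, BLAST, ML tree inference with ultrafast bootstrap, and
thermodynamic hairpin folding).  Here every such role is re-implemented
in a simplified, fully specified form: a PSSM with affine-gap local
dynamic programming instead of a profile HMM; greedy longest-first
clustering against cluster representatives with no k-mer prefilter;
center-star multiple alignment; neighbor joining with standard bootstrap
instead of maximum likelihood; combinatorial inverted/direct-repeat
search instead of free-energy folding.  These are deliberate design
choices that make every step oracle-checkable; no attempt is made to
reproduce tree topologies or E-value statistics of the original tools.

## Scoring and numerical conventions

* PSSM: `score(c, a) = log2(((count_c(a) + p·bg(a)) / (n_c + p)) / bg(a))`
  with pseudocount `p = 1` and uniform background 1/20 (overridable).
  Unknown residues score −2 bits and stop symbols −4 bits, so reading
  frames crossing stops are discouraged without being forbidden.
  Alignment runs in half-bit units with gap open 11 and gap extend 1
  (first gap column of a run costs the open penalty); reported scores
  are bits.
* There is no hmmsearch-default equivalent for a PSSM threshold, so the
  scan threshold is calibrated per run as the 99.9th percentile of local
  scores over ≥1000 dinucleotide-preserving (Altschul–Erikson) shuffled
  windows of the input genomes.  On the synthetic data this lands near
  20 bits while true hits score 250–350 bits; the measured false-hit
  rate per 200-aa decoy is ~0.1–0.3%.
* Scanning is exact-with-prescreen: an exhaustive ungapped full-profile
  sweep over every frame position proposes candidate windows (cutoff set
  at half the reporting threshold, far below any true hit), and the
  exact local DP runs inside each window.  Under the substitution-only
  divergence model the optimal local path of a true hit is ungapped, so
  the prescreen loses nothing; the exact scorer is exposed separately
  (`profile.score_local`) and is what the brute-force oracles test.
* Pairwise identity is computed on a *fitting* alignment: match +1,
  mismatch −1, gap open −2, gap extend −1, the shorter sequence consumed
  end to end, terminal gaps free only along the longer sequence, and
  identity = identical columns / aligned columns excluding terminal
  gaps.  A fully end-gap-free ("overlap") reading was rejected because
  two unrelated sequences can then attain ~80% "identity" over a tiny
  corner overlap, which collapses greedy clustering.  Equal-length pairs
  reduce to plain global alignment.  For long collinear sequences the
  pipeline restricts the DP to a diagonal band (±200 around the
  length-difference corridor); on dissimilar pairs the band can only
  underestimate identity, which is conservative for clustering.
* Boundary search: inverted repeats need arms ≥11 nt (≤1 mismatch, loop
  3–15 nt), direct repeats a unit of 9–12 nt occurring ≥2 times within
  60 nt.  These minima put the chance of a spurious structure in a
  random 250-nt window at the few-percent level (a random window
  contains an arm-8/≤1-mismatch repeat with probability ≈0.7, which
  would make truncated ends read as full).  The repeat *mode* is chosen
  per element — palindromic or direct-repeat ends, whichever explains
  more sides, ties to palindromic — because per-side mixing lets a
  chance hairpin in flanking DNA displace one end of a direct-repeat
  element.  Tie-breaks inside a mode: longest stem/unit, most unit
  occurrences, then proximity to the ORFs.
* The decay aligner uses match +1, mismatch −1, gap open −4, extend −2:
  a decayed ORFA remnant is contiguous, and cheaper gaps would let a
  20-mer seed chain with distant chance matches and cross the >20-match
  bar spuriously.  "Matched length" counts identical positions on the
  optimal local path; counting aligned columns instead lets random
  150–400-nt flank/CDS pairs cross the bar by chance at the percent
  level.  An exact-substring reading of the rule is available
  (`decay_exact`).
* ORFA/TnpB partner selection: the partner must sit on the LE side of
  TnpB within 150 nt; a same-strand partner may overlap the predicted
  TnpB start (which can slide upstream through ORFA's tail to an
  upstream in-frame start codon) by at most min(160 nt, 60% of the
  partner's length); an opposite-strand partner may not overlap.  ORFs
  buried in the TnpB CDS are antisense/frame noise and are excluded by
  these rules.  If the chosen partner lies outside the detected element
  boundaries, or including it costs a boundary, the locus is
  re-annotated without it ("best-supported interpretation").
* Rounding is half-up at the printed precision everywhere (decimal
  quantisation, not banker's rounding).

## The synthetic data generator

The generator defines the study conditions; its defaults are the
conditions under which the recovery claims hold.

* **Panel**: six pseudo-species × 20 genomes × 0.5 Mb in two contigs,
  i.i.d. background nucleotides at GC 0.5 (order-0; composition is the
  only controlled property).
* **Templates**: one per subgroup, built inside the published length
  priors (IS605 1740–1950 nt, IS607 1620–2400 nt, IS1341 short form
  1252–1393 nt; Y1 102–164 aa, SR 150–217 aa, TnpB 340–489 aa, IS1341
  TnpB 362–489 aa).  All TnpBs embed a family-diverged copy (12% aa) of
  one ancestral 120-aa RuvC core with the catalytic D–E–D preserved; Y1s
  carry the HuH triad plus downstream Y and Q; SRs a central catalytic
  serine (and are resampled until free of a chance Y1 signature, which
  would otherwise claim them under the Y1-first precedence).  IS605a and
  IS607a use the classical 4-nt ATGA junction (ORFA's stop overlaps the
  TnpB start one frame over).  IS605/IS1341 ends are perfect 14–18-nt
  palindromic stems with 4–8-nt loops; IS607 ends are three copies of a
  12-nt direct-repeat unit, and templates are rejected if a detectable
  inverted repeat sneaks into an end region.  Spacers are capped so each
  end structure fits the 250-nt boundary search window.
* **Guard stops** sit immediately 5' of every separated ORF start (in
  that ORF's frame): without them a chance upstream in-frame start codon
  extends the predicted ORF, blurring the overlapping/separated
  distinction and the protein length windows.  For the a-types, where no
  guard can sit inside ORFA's coding sequence, the build verifies that
  the nearest in-frame stop bounds the TnpB start slide to ≤150 nt and
  protects that stop.  Templates are also rejected unless the boundary
  detector recovers each planted repeat's external edge exactly in
  context.
* **Divergence** (default 4%, the upper half of the ≤5% regime the
  recovery claims cover) is applied as substitutions only: positions are
  drawn uniformly, resampled away from a small protected set (start and
  stop codons, guard and junction codons, catalytic-motif codons, repeat
  arms/units, cleavage tetramers), and a substitution never introduces
  an in-frame stop in any annotated CDS.  This emulates purifying
  selection on functional element families; unconstrained mutation at
  4%/nt disrupts most planted ORFs (more than one expected premature
  stop per TnpB CDS), which would describe dead copies, not an element
  family.  Decayed copies are planted explicitly instead: an
  IS605b/c/IS607b template whose ORFA is eroded to a 25-nt remnant
  (protected from further substitutions — the remnant *is* the defining
  feature of the condition) occupying part of the configured IS1341
  copy budget.
* **Copy numbers**: Poisson per genome with per-subgroup mean 1.0 (most
  published subgroup means sit between one and four copies per positive
  genome); 10% of copies are truncated (LE, RE or both ends removed);
  10% of IS1341-like copies are decays.  Elements are planted ≥3.5 kb
  apart on either strand, never across contig ends; every copy is
  recorded in the truth ledger with its exact post-mutation sequence.
* **Profile inputs**: 18 seed-protein families (1–4 near-identical
  variants each, core 20% diverged from the ancestor) plus deliberate
  curation rejects (150-aa and 650-aa entries, and proteins with a
  half-deleted core that survive the length filter but fail the 20% gap
  rule); a reference element library covering three of six subgroups
  (so both known and new family naming paths run); three IscB-like
  outgroup proteins (same catalytic geometry, 45%-diverged core).

### What the synthetic experiments show — and what they do not

Passing recovery tests show the pipeline implements its own rules
exactly and robustly under substitution divergence, truncation and decay
at the configured rates: at 4% divergence across 120 genomes (~730
planted copies) detection is 100%, subgroup and completeness calls are
≥99%, boundaries are within ±5 nt for ≥97% of full elements, and decay
copies are all flagged; with divergence, truncation and decay at zero,
recovery is exact to the base pair.  They do not show field performance
on real assemblies: real elements carry indels, nested and fragmented
copies, composition biases, target-site duplications and homologous
flanking context that the generator deliberately omits (substitutions
only, order-0 background, linear contigs, no transposition history).
The published headline numbers (9996 elements in 4594 genomes, 39
families) depend on thousands of NCBI assemblies and curated reference
databases and are not reproducible at this scale; what is reproduced
exactly is the survey's summary arithmetic from its printed counts.

## Published-count arithmetic

The printed distribution tables are carried as input data (integer
counts only) and the summary code recomputes the derived cells.  All
positive-genome percentages, all subgroup and group-total percentages,
and two of six copy-number means reproduce exactly under half-up
rounding.  The other four printed means (5.28, 14.15, 2.05, 1.25) and
one full-element percentage (C. difficile 93%) are inconsistent with
their own printed integer counts under any rounding (e.g. 1875 elements
over 658 positive genomes is 2.78, not 1.25); these cells are flagged in
`tcme.published` and excluded from the reproduction checks, since the
survey's averaging denominator for them is unknowable from the printed
material.

## Problem sizes

The acceptance computations run the full default panel twice (divergent
and noise-free), about 60 Mb of genome per run; a run takes roughly five
minutes on one core, dominated by the six-frame prescan and the
clustering alignments.  The analysis drivers use a five-genome panel per
species so the whole chain completes in a few minutes; all sizes are
configuration, not code.

## Known limitations

* Substitution-only divergence keeps identity arithmetic exact but means
  indel robustness is untested (an indel mode exists nowhere; it is a
  stated non-goal).
* The 70%-identity locus clustering operates on nucleotide locus
  sequences; whether the original survey clustered nucleotides or
  proteins at that step is not stated in its methods.
* "Detected elements" versus retained elements: loci whose TnpB has no
  homology to the reference ORFB set and no detectable boundaries are
  dropped; the per-species tables report both raw locus counts and
  retained element counts, which is one consistent reading of the two
  published columns.
* Family naming is per species within a run; cross-run stability of new
  names is not guaranteed beyond determinism under a fixed seed.
* Branch-group labelling reports maximal supported proper clades plus a
  residual group; on radiations with supported deep structure the
  grouping follows the deepest supported edges, which may be coarser
  than a curator's reading of the same tree.
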