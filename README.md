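# tcme — mining TnpB-containing mobile elements

`tcme` is a desk-scale, fully testable pipeline for finding, structurally
classifying and summarising **TnpB-containing mobile elements** (TCMEs) in
bacterial genomes.  TCMEs are the insertion-sequence groups *IS605*,
*IS607* and *IS1341*: compact elements whose ORFB encodes the RNA-guided
nuclease TnpB (RuvC I/II/III catalytic segments, zinc fingers, an RK-rich
region and an N-terminal HTH), paired — except in *IS1341* — with an ORFA
transposase, either the single-tyrosine HuH recombinase Y1 (*IS605*) or a
serine recombinase (*IS607*).  The elements are flanked by subterminal
left/right ends (LE/RE): palindromic hairpin stems in *IS605*/*IS1341*,
short direct repeats in *IS607*, each with a ~4-nt cleavage site
immediately external to the repeat.

The pipeline is aimed at mobile-element and genome-evolution researchers
who want every mining rule explicit and testable.  Because the real
survey scale (thousands of assemblies, curated IS and domain databases)
is out of reach on a desk, the package ships a first-class **synthetic
data generator** that plants diverged element copies of all six
structural subgroups (*IS605a/b/c*, *IS607a/b*, *IS1341*) into random
genomes with a machine-readable truth ledger, so every downstream stage
is validated by recovery, not by eye.

## What it computes

* a **RuvC-domain PSSM** from curated seed proteins
  (length filter 200–600 aa → 80% redundancy clustering → domain-block
  extraction → 20% gap filter), with log-odds scores
  `s(c,a) = log2(((n_c(a) + p·q_a)/(n_c + p))/q_a)`;
* a **six-frame scan** of every contig by affine-gap local dynamic
  programming against the PSSM (gap open 11, extend 1 half-bits; hits
  ≥ 50 aa; threshold calibrated as the 99.9th percentile of scores on
  dinucleotide-preserving shuffles);
* **loci** (hits ± 1.7 kb), ORF prediction, role assignment (TnpB by
  profile score; Y1 by the HuH triad with downstream catalytic Y and Q;
  SR by the central catalytic serine), structural **subgroup calls**,
  subterminal-repeat **boundary detection** with cleavage tetramers,
  full/truncated calls, the *IS1341* **decay rule** (>20 bp flank match
  to a Y1/SR CDS), and known/new **family naming** at 90% identity;
* **neighbor-joining trees** (p-distance, Saitou–Nei Q criterion) with
  Felsenstein bootstrap and outgroup-rooted branch groups;
* per-species **invasion and copy-number tables**, co-invasion counts and
  protein identity statistics, with half-up rounding at the printed
  precision.

## Worked example

The numbered drivers under `analysis/` run a compact study (six
pseudo-species × five genomes × 250 kb, 4% divergence, 10% truncation,
10% decay):

```bash
python analysis/01_simulate.py       # plant elements, write truth ledger
python analysis/02_build_profile.py  # curate seeds, build + calibrate PSSM
python analysis/03_mine_elements.py  # scan, annotate, classify, name
python analysis/04_phylogeny.py      # NJ + bootstrap of family TnpBs
python analysis/05_summaries.py      # tables + published-count check
```

`02_build_profile.py` prints the curation funnel:

```
profile construction:
  input seed proteins                      46
  after 200-600 aa length filter           42
  80% identity cluster representatives     21
  conserved-region columns                 108
  rows surviving 20% gap filter            18
  profile match columns                    98
  calibrated threshold (99.9th decoy pct)  23.9 bits
```

46 seed proteins shrink to 18 usable alignment rows (the planted
too-short/too-long and truncated-domain decoys fall at exactly the
stages the rules target), yielding a 98-column domain model; genuine
TnpB hits score 250–350 bits against a 23.9-bit decoy threshold.

`03_mine_elements.py` then scores recovery against the truth ledger:

```
recovery against the truth ledger:
  n_planted                    171
  n_detected                   171
  detection_rate_pct           100.00
  subgroup_accuracy_pct        98.82
  completeness_accuracy_pct    100.00
  boundary_within_5_pct        100.00
  boundary_mae_nt              0.05
  decay_detection_pct          100.00
  n_false_loci                 0
```

— every planted copy is found, subgroup structure is read correctly for
all but two copies, element ends land within ±5 nt of the planted
coordinates, and all decayed copies are reclassified out of *IS1341* by
the >20 bp remnant rule.  `05_summaries.py` finishes with the
published-table arithmetic: all printed positive-genome percentages are
reproduced exactly from the printed integer counts, while the handful of
printed cells that are inconsistent with their own counts (four
copy-number means and one full-element percentage) are flagged rather
than matched.

A thin CLI (`tcme simulate|build-profile|scan|run|summarize`) exposes
the same stages for ad-hoc use; `docs/methods.md` documents the models,
parameter choices and limitations.

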