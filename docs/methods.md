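# Methods

This note documents the models, parameters and numerical choices behind
`vgzinc`, and what the synthetic benchmarks do and do not demonstrate.

## ICP-MS reduction

Inputs are per-sample Zn concentrations on the instrument (post-dilution)
scale in μg/L, a dilution factor (default 5), and the undiluted protein
mass concentration in g/L. The reduction is deliberately minimal:

- corrected Zn = reading × dilution factor;
- molar ratio r = (c_Zn/M_Zn)/(c_protein/M_protein), with
  M_protein = 201 147.7 g/mol (theoretical full-length Vg) and
  M_Zn = 65.30 g/mol by default (both configurable; note 65.30 is the
  value used historically for this analysis, slightly below the IUPAC
  65.38);
- LOD = 3·SD and LOQ = 10·SD of the blank readings, sample SD with n−1
  denominator, so LOQ/LOD = 10/3 identically. Analytes below the LOD are
  flagged and excluded from the summary by default (flag-and-keep is an
  option).

Assumptions: readings are already internal-standard (Rh) normalised and,
when acquired at mass 64, already corrected for the ⁶⁴Ni isobar; the
package treats both as upstream instrument processing and carries any Ni
signal as metadata only. Group separation uses the Kruskal–Wallis rank
test with tie correction (scipy); for two tie-free groups of five the
statistic is bounded by H = 6.82, which is what fully separated data
produce.

## Conservation score

For each reference (non-gap) position, the score is the frequency of the
reference letter among the column's non-gap symbols, multiplied by the
column's non-gap fraction; columns with > 50 % gaps are additionally
flagged low-confidence. A similarity-class mode pools exchange groups
({AVLIM}, {FYW}, {ST}, {DE}, {NQ}, {KR}, {C}, {H}, {G}, {P}) before
counting. This is a deterministic, phylogeny-free stand-in for Bayesian
conservation servers: adequate for flagging the clearly conserved
His/Cys/Asp/Glu/Ser residues the cluster search needs, but it does not
correct for sequence redundancy — a heavily sampled clade inflates scores.

Grades 1–9 (9 = most conserved) are by default a **linear** binning of the
absolute score into ninths (grade k covers [(k−1)/9, k/9), score 1.0 →
grade 9). A rank-based quantile binning is available
(`grade_binning="quantile"`), but it is not the default: relative bins tie
the grade of a column to the rest of the protein, so a fully conserved
column can fall out of grade 9 (or background columns rise into it)
depending on how many conserved columns exist — which breaks the exact
planted-column recovery the synthetic benchmark requires and makes the
seeding threshold mean different things on different proteins. With linear
bins the default seeding threshold grade ≥ 7 corresponds to score ≥ 2/3.

## Cluster search

Parameters (`SearchConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `min_grade` | 7 | conservation grade for seeds and auxiliaries |
| `d_pair` | 8.0 Å | donor–donor edge cutoff of the proximity graph |
| `d_aux` | 8.0 Å | spatial reach of Asp/Glu/Ser augmentation |
| `seq_adjacency` | 2 | sequence reach of augmentation (±residues) |
| `min_coordinators` | 4 | minimum ligand count of a complete site |
| `buried_neighbors` | 18 | CB neighbours (10 Å) for "buried" |

The 8 Å donor-atom cutoff reflects that two ligands of one Zn²⁺ sit at
most ~4.8 Å apart when bound (2.0–2.4 Å bonds), plus slack for side-chain
rearrangement on a static apo model; 6–12 Å is the sensible range, and the
run log always records the value used. Grouping is exact graph connected
components (the only deterministic reading of "inspecting positions in 3D
space"), verified in tests against a brute-force all-pairs BFS oracle.
Augmentation adds **every** conserved Asp/Glu/Ser within reach of a
sub-minimal component, not just enough to reach four: a nearby conserved
acidic pair is evidence about the site, and dropping half of it on a
counting rule would make membership depend on iteration order.

Classification is a rule table: redox-switch-like for four-cysteine
clusters arising from crossing disulfide bridges (all four SG mutually
within `d_pair`); sub-minimal below `min_coordinators`; structural-like
for ≥ 3 His/Cys members with mean burial ≥ the buried threshold;
catalytic-like otherwise. Burial is a CB-neighbour count (CA for Gly)
within 10 Å — a solvent-accessibility proxy chosen for determinism and
zero dependencies; it is coarse near the surface of small models. Domain
assignment is a majority vote over configured residue windows (ties break
to the lowest member; membership itself is purely geometric, so a residue
can sit in a cluster dominated by another domain).

## Hydrophobic contrast

For each cluster the centroid of member donor atoms defines two shells:
residues whose nearest qualifying atom (donor atoms where present, else
CB/CA) lies ≤ 5 Å (inner) or in (5, 10] Å (outer). The statistic is
Δ = mean(outer) − mean(inner) over the packaged Eisenberg normalized
consensus scale; each residue counts once, in its nearer shell. Positive Δ
is the favourable contrast. An empty outer shell leaves Δ undefined rather
than zero. Δ is invariant under rigid motion and exactly negates when the
shell compositions are swapped (tested). No numeric reference values exist
for the real protein, so the contrast is validated by these symmetries and
by sign on constructed polar-core/hydrophobic-shell sites.

## Motif scanning

Literal scanning reports all, possibly overlapping, occurrences. The C2H2
consensus `C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H` is matched
leftmost-shortest, non-overlapping (lazy spacers, the C–C spacer varying
slowest); tests pin this semantics to a brute-force sliding-window oracle.
Ligand-column mapping projects annotated (position, ligand-class) pairs of
finger-bearing sequences through the alignment onto the target, dropping
gap-aligned columns and deduplicating; output is sorted by target position
and therefore stable under record permutation.

## Synthetic generators

`make_structure` plants each site's donor atoms 2.1 Å from a virtual ion
along tetrahedral directions (pairwise donor distances ≈ 3.43 Å), spaces
sites 60 Å apart, puts His/Cys decoys ≥ 15 Å from everything (beyond any
default cutoff), and fills the chain with alanine CA atoms from a
self-avoiding random walk confined away from the sites; an optional
hydrophobic shell wraps sites in six Leu/Ile/Phe/Val residues at 7.5 Å.
Residues carry CA plus donor atoms only — readers must (and do) tolerate
truncated side chains. `make_msa` copies conserved columns verbatim and
substitutes the rest independently (uniform over the other 19 letters), no
gaps. `make_icpms` mirrors the study layout: five analytes with protein at
1.2–2.8 g/L, five blanks, 5× dilution; analyte readings get multiplicative
Gaussian noise (default SD 5 %), blanks are Normal(level, level/3)
truncated at zero with a default level of 5 μg/L — small against the
~200–600 μg/L analyte signal, as buffer blanks should be. All three are
byte-deterministic under a fixed seed.

What passing these benchmarks shows: the machinery (scoring, graph
grouping, augmentation, unit conversions) is correct against ground truth.
What it does not show: performance on real predicted structures, where
side-chain placement is uncertain, conservation is phylogenetically
structured, sites are not ideal tetrahedra, and decoys are not 15 Å away.
The planted margins are chosen to make recovery a correctness check, not a
sensitivity study; threshold-sensitivity experiments should shrink the
decoy margin deliberately.

## Degenerate inputs and tie-breaks

Unequal alignment rows, empty files, unknown accessions, residues missing
from the structure, windows with start > end, < 2 blanks, and non-positive
protein concentrations all raise typed errors. Identical blanks give
LOD = LOQ = 0 with a warning; an all-identical Kruskal–Wallis input
returns H = 0, p = 1. Disulfide pairing is greedy nearest-first (each Cys
in at most one bridge); cluster naming and ordering follow the lowest
member position, so identical inputs give byte-identical reports (the run
log's timestamp is the only non-reproducible output).

## Problem sizes

The test suite and acceptance script use structures of 40–80 residues with
2–3 planted sites, 30-sequence alignments, and 50–200 replicate ICP-MS
tables per condition — sizes at which the brute-force oracles remain
exact cross-checks and the full suite runs in seconds.
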