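# vgzinc

Zinc-binding site discovery and Zn:protein stoichiometry for honey bee
vitellogenin (Vg) — and for any protein where the same question arises:
*how many Zn²⁺ ions does the protein carry, and where on the structure
could they sit?*

Vitellogenin is the main circulating zinc carrier in honey bee workers.
`vgzinc` implements the two halves of that analysis as a reusable library
with a CLI:

1. **ICP-MS stoichiometry.** Instrument readings (μg/L Zn, post-dilution)
   are corrected for dilution and reduced to a per-sample molar ratio

   *r* = (c_Zn / M_Zn) / (c_protein / M_protein),

   with defaults M_protein = 201 147.7 g/mol (full-length Vg) and
   M_Zn = 65.30 g/mol. Detection limits follow the blank convention
   LOD = 3·SD(blanks), LOQ = 10·SD(blanks), and analyte/blank groups are
   compared with a Kruskal–Wallis rank test.

2. **Candidate coordination clusters.** Per-column conservation is scored
   from a multiple sequence alignment and projected onto the structure's
   numbering. Conserved His/Cys residues seed a proximity graph over
   side-chain donor atoms (His ND1/NE2, Cys SG, Asp OD1/OD2, Glu OE1/OE2,
   Ser OG); connected components within `d_pair` (default 8 Å) become
   clusters; components smaller than four coordinators — Zn²⁺'s most common
   ligand count — are augmented with nearby conserved Asp/Glu/Ser.
   Crossing disulfide-bridge pairs are reported as candidate ZnC₄ redox
   switches. Each cluster gets a classification (structural-like /
   catalytic-like / redox-switch-like / sub-minimal), a domain label, and a
   hydrophobic-contrast score (outer-shell minus inner-shell mean Eisenberg
   hydrophobicity; positive = polar core in a hydrophobic environment, the
   signature of a productive site). Motif scanning locates literal motifs
   (e.g. the DNA-binding SRSSTSR stretch) and C2H2 zinc-finger consensus
   matches, and projects annotated zinc-ligand columns of finger-bearing
   sequences through the MSA onto the target.

A synthetic-data module generates structures with planted tetrahedral
coordination sites (donor atoms 2.1 Å from a virtual ion), alignments with
controlled per-column conservation, and ICP-MS tables drawn from a known
true ratio — so the whole pipeline is testable against ground truth.

## Worked example

Generate a synthetic bundle (two planted sites + decoys, a 30-sequence
alignment conserving the planted columns, an ICP-MS table at a true ratio
of 3 mol Zn per mol protein) and run the full pipeline:

```python
from vgzinc.synthetic import write_fixtures
from vgzinc.pipeline import RunConfig, run_pipeline

paths = write_fixtures("demo/fixtures", seed=1)
cfg = RunConfig(
    structure_path=str(paths["structure"]),
    alignment_path=str(paths["alignment"]),
    icpms_path=str(paths["icpms"]),
    ref_id="REF",
    outdir="demo/out",
    domain_boundaries={"site region": (1, 12), "filler region": (13, 60)},
)
summary = run_pipeline(cfg)
```

which prints (via `summary` and `demo/out/clusters.tsv`):

```
n_clusters = 2
n_clusters_min4 = 2
zn_ratio_mean = 3.032995141404542
zn_ratio_min = 2.804526415259345
zn_ratio_max = 3.1358033800009673
lod_ugL = 2.2087068284208797
loq_ugL = 7.362356094736265
kruskal_wallis = {'H': 6.818181818181813, 'df': 1, 'p': 0.009023438818080334}

id    domain       classification  size  members      roles                                  grades
sr.1  site region  catalytic-like  4     C1;C2;C3;C4  primary;primary;primary;primary        9;9;9;9
sr.2  site region  catalytic-like  4     H5;H6;D7;E8  primary;primary;auxiliary;auxiliary    9;9;9;9
```

Both planted sites are recovered exactly: the all-cysteine tetrad directly
from conserved-His/Cys seeding, and the His/His/Asp/Glu site as a two-His
seed augmented with its conserved acidic neighbours. The stoichiometry half
recovers the planted ratio of 3 (mean 3.03, range 2.80–3.14 over five
samples at 5 % measurement noise), the detection limits sit far below the
analyte signal, and the rank test separates analytes from blanks
(H = 6.82, df = 1, p = 0.009 — the maximum attainable H for two tie-free
groups of five).

The same stages are exposed as CLI subcommands:

```sh
vgzinc fixtures demo/fixtures --seed 1
vgzinc conserve demo/fixtures/synthetic_msa.fasta --ref-id REF
vgzinc clusters demo/fixtures/synthetic_structure.pdb demo/fixtures/synthetic_msa.fasta --ref-id REF
vgzinc stoich demo/fixtures/synthetic_icpms.csv
vgzinc run config.yaml
```

To analyse a real protein, point `structure_path` at a PDB/mmCIF model
(e.g. the published full-length Vg model), `alignment_path` at an ortholog
MSA in FASTA or Clustal format with the model's sequence as reference, and
`icpms_path` at a sample table with columns
`id,group,zn_ugL,dilution,protein_gL`.

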