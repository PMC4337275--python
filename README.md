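# portrace

Analytics for the evolutionary history of the two non-homologous,
isofunctional enzymes that catalyse the penultimate step of chlorophyll *a*
synthesis in algae:

* **POR** — the nuclear-encoded, light-dependent protochlorophyllide
  oxidoreductase, a member of the short-chain dehydrogenase-reductase (SDR)
  family;
* **LIPOR** — the chloroplast-encoded, light-independent enzyme (genes
  *chlL*, *chlN*, *chlB*), an oxygen-sensitive, nitrogenase-like complex.

The history of these genes in eukaryotic algae is reticulate: *por* genes
have been duplicated, replaced, and horizontally transferred between
lineages, while LIPOR gene complements have been repeatedly lost or
pseudogenized. `portrace` packages the analyses needed to trace that
history, for phycologists and molecular evolutionists working from protein
sequences, alignments, gene trees, and chloroplast annotation tables.

## What it does

**Homolog curation** (`portrace.curation`). POR cannot be separated from
near-miss SDR relatives by search scores alone, so candidates are screened
for three diagnostic features anchored onto a cyanobacterial reference by
pairwise alignment: the Rossman-fold pattern `G-x-x-x-G-x-G` (NADPH
binding), the `Y-x-x-x-K` pair (catalytic proton donation and
cofactor/substrate coordination), and the catalytic cysteine. Sequences
missing only their N-terminus (typical transcriptome fragments) are kept as
fragments when `Y-x-x-x-K` and the Cys are intact. Length, undetermined-
residue, and same-taxon duplicate filters complete the curation.

**Alignment analytics** (`portrace.alignment`). Conserved-core trimming by
per-column gap/`X` fractions; logo preparation (removal of insertion
columns borne by ≤ 2 sequences); per-column frequency/information-content
matrices (IC = log₂20 − H, in bits); and residue-class similarity, with two
rows scored as similar at a column when both residues share a chemical
class — polar `GSTYC`, neutral `QN`, positive `KRH`, negative `DE`,
hydrophobic `AVLIPWFM` — over mutually occupied columns.

**Gene-tree events** (`portrace.trees`, `portrace.events`). Newick in/out
with posterior probabilities and bootstrap percentages normalized onto one
0–1 scale; outgroup rooting; a neighbor-joining stand-in builder for
fixture-scale work. Duplications are called by the species-overlap rule
(an internal node whose child clades share ≥ 2 taxa), and each leaf of a
secondary-plastid lineage is classified **vertical** or **xenolog** by
walking rootward to the first well-supported anchor clade (support ≥ 0.95
by the dashed-branch convention) and comparing its dominant lineage with
the host's expected plastid donor (CASH lineages → rhodophyte, euglenids →
prasinophyte, chlorarachniophytes → UTC chlorophyte).

**LIPOR complements** (`portrace.lipor`). Per-species *chlL/chlN/chlB*
status tables (symbols `+`, `+,2`, `-`, `ψ`, `?`) classified as
complete/partial/pseudogenized/absent/indeterminate, summarized by group,
and associated with *por* copy number through a two-sided exact
(hypergeometric) test. Machine-readable survey tables for chlorophyte,
chlorarachniophyte, euglenid, rhodophyte and CASH chloroplast genomes ship
with the package.

**Degenerate primers** (`portrace.primers`). Conserved-window discovery,
IUPAC reverse translation covering every residue observed at each column,
degeneracy accounting, reverse-complementation, and non-degenerate 23-bp
sequencing tails.

**Synthetic data** (`portrace.simulate`). Seeded generators with planted
ground truth: POR families with SDR-style decoys and N-truncated fragments,
lineage-labelled gene trees with planted duplications and HGT grafts, and
complement tables with tunable por-copy/LIPOR-loss coupling.

## Worked example

```python
from portrace import (simulate_por_family, apply_curation,
                      simulate_gene_tree, detect_duplications, assign_origins)

sim = simulate_por_family(n_decoys=4, n_fragments=2, seed=1)
accepted, rejected = apply_curation(sim.records, sim.anchor)
print(f"accepted {len(accepted)} of {len(sim.records)} candidates")
for r in rejected:
    print(f"  rejected {r.report.seq_id}: {r.reason}")

tree, truth = simulate_gene_tree(n_duplications=1, n_hgt=2, seed=1)
for call in detect_duplications(tree):
    print(f"duplication at node {call.node_id}: "
          f"{len(call.shared_taxa)} shared taxa, support {call.support}")
for call in assign_origins(tree):
    if call.mode == "xenolog":
        print(f"xenolog: {call.leaf} emerges within {call.donor_lineage} "
              f"(purity {call.donor_purity:.2f})")
```

prints

```
accepted 41 of 45 candidates
  rejected decoy_00: motif_fail
  rejected decoy_01: motif_fail
  rejected decoy_02: motif_fail
  rejected decoy_03: motif_fail
duplication at node 146: 5 shared taxa, support 1.0
xenolog: dinoflagellate_0 emerges within cyanobacteria (purity 1.00)
xenolog: chlorarachniophyte_1 emerges within rhodophyte (purity 0.81)
```

The 4 rejected sequences are exactly the planted SDR decoys (each breaks
one diagnostic residue); both planted HGT grafts are recovered with their
true donor lineages, and the planted 5-taxon duplication is the only
duplication call. The same stages are available from the shell via
`portrace screen|trim|logo|similarity|root|nj|duplications|origins|paralogs|lipor|primers|simulate|run`;
`portrace run config.yaml` executes the whole pipeline and writes per-stage
TSVs plus a `summary.json`.

## Limitations

Phylogenetic inference itself (ML/Bayesian tree building, model selection,
convergence diagnostics) is out of scope: trees are inputs, and the
bundled neighbor-joining builder is a desk-scale stand-in only. See
`docs/methods.md` for the model assumptions, parameter defaults, and what
the synthetic generators do and do not emulate.
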