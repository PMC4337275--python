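# Methods

## Motif-anchored curation

POR is a short-chain dehydrogenase-reductase (SDR), a family dense with
near-miss homologs, so curation rests on diagnostic residues with known
catalytic roles rather than on search scores: the Rossman-fold pattern
`G-x-x-x-G-x-G` needed for NADPH binding, the `Y-x-x-x-K` pair whose
tyrosine donates the catalytic proton, and the active-site cysteine.
Coordinates for the three features live on a cyanobacterial reference
(`ReferenceAnchor`, 1-based), validated on construction: the reference must
literally carry `G/G/G`, `Y`, `K`, `C` at the declared positions, with
`tyr_pos + 4 == lys_pos`.

A query is globally aligned to the reference (Biopython `PairwiseAligner`,
Gotoh affine gaps; defaults BLOSUM62, gap open −11 / extend −1; a gap of
length L costs `open + (L−1)·extend`). Equal-score optima are resolved by
the aligner's deterministic enumeration order, so the reference→query
column map is reproducible. Each motif is searched within ±`window`
(default 10) residues of its projected position — projection uses the
mapped column when present, else offsets from the nearest mapped column —
and `X` never satisfies a motif position.

**N-truncation.** Transcriptome-derived sequences often lack the
N-terminus; such sequences are kept (`accept_fragment`) when `Y-x-x-x-K`
and the Cys are found. A query counts as N-truncated when fewer than half
of the reference columns from position 1 through the end of the Rossman
pattern are mapped. A "first mapped column" rule was considered and
rejected: the optimal global alignment of a genuinely truncated query
frequently pairs one stray leading residue with the reference start before
opening the long gap, which would mask the truncation.

Filter defaults (`apply_curation`): minimum length 150 aa, maximum
undetermined fraction 0.05, same-taxon duplicates at ≥ 0.99 identity over
the shorter sequence (longest kept). These thresholds are package choices;
the underlying filters (short, low-quality, duplicate removal) are
standard curation practice. Curation is idempotent on its accepted set.

## Alignment analytics

* `trim_core` keeps columns whose gap fraction and `X` fraction are within
  bounds (defaults 0/0, i.e. the fully determined core). Exposed because
  published conserved-core lengths depend on the trimming rule used.
* `logo_prune` removes insertion columns borne by ≤ `max_gap_rows`
  sequences (default 2). Only columns actually containing a gap are
  candidates, which also keeps degenerate few-row alignments intact. The
  alternative reading — dropping columns in which ≤ 2 sequences have gaps
  — would delete near-complete columns and was rejected.
* `compute_logo` reports per-column frequencies over the 20 residues
  (gaps/`X` excluded from the denominator) and information content
  `log₂20 − H` in bits, without small-sample correction (an optional
  concern at the 18–22-sequence scale the logos are used at).
* `group_similarity` scores two rows as matching at a column when both
  residues share a chemical class (polar `GSTYC`, neutral `QN`, positive
  `KRH`, negative `DE`, hydrophobic `AVLIPWFM`), over mutually occupied
  columns; `X` is treated like a gap. Under the identity partition the
  measure reduces to percent identity and bounds the class-based value
  from below. Published within-/between-group similarity percentages do
  not state their exact metric, so reproducing them is approximate by
  construction.

## Gene-tree events

Supports are normalized to [0, 1] on parse (values in (1, 100] are read as
bootstrap percentages). Missing support passes every threshold check:
conclusions are blocked only by *measured* weak support, mirroring the
convention of dashing branches below 0.95 posterior probability.

`detect_duplications` implements the species-overlap rule: an internal
node is called when two of its child clades share ≥ `min_shared` taxa
(default 2) and the node's support passes. At multifurcations all child
pairs are evaluated and only the maximally overlapping pair is reported.

`assign_origin` classifies a leaf against an expected plastid-donor map
(stramenopile/haptophyte/cryptophyte/dinoflagellate → rhodophyte, euglenid
→ prasinophyte, chlorarachniophyte → UTC chlorophyte). Walking rootward,
the anchor is the first supported ancestor whose clade holds ≥
`min_context` (default 3) leaves outside the query's own lineage; if the
modal context lineage reaches `purity_threshold` (default 0.8) it is the
donor — vertical when it equals the expected donor, xenolog otherwise. A
tie for the mode at a qualifying anchor yields `unresolved` (a donor is
never guessed); reaching the root without a qualifying anchor also yields
`unresolved`. Calls are invariant to leaf order and branch-length scaling.

Rooting places the new root at the midpoint of the branch separating a
monophyletic outgroup, carrying the branch's support to both root children
(deterministic round trips). Neighbor joining is the standard Saitou–Nei
agglomeration with lexicographic tie-breaks and negative branch estimates
clamped to zero; on additive matrices it reproduces the generating
topology and lengths exactly. It exists for fixture-scale work — real
trees are expected to come from dedicated ML/Bayesian inference upstream.

## LIPOR complements and the association test

Complement classes, in rule order: **complete** (all of chlL/chlN/chlB
present, multi-copy allowed), **absent** (all three absent),
**pseudogenized** (≥ 1 pseudogene, nothing intact), **partial**
(present/absent mix, fully determined), **indeterminate** (an unknown
blocks the above). The order makes the classification total over all 5³
status combinations; records mixing intact genes, pseudogenes and
unknowns fall conservatively to indeterminate.

The por-copy × LIPOR-loss association is an explicit statistical extension
of a qualitatively documented pattern: rows with known por count and a
determinate complement enter a 2×2 table (por ≥ 2 vs ≤ 1; complement
reduced — absent/pseudogenized/partial — vs complete) tested with the
two-sided exact hypergeometric (Fisher) test. Range-valued por counts
("1–2") contribute their minimum, which is conservative toward the
duplication-with-loss hypothesis. Caveat carried from the source tables:
por counts are genus-level while LIPOR rows are species-level. On the
bundled survey the test gives p ≈ 6.6 × 10⁻⁴ (computed by
`scripts/acceptance.py`, key `survey_association_p_value`).

## Degenerate primers

Candidate windows (default 7 aa) are ranked by mean modal-residue
frequency; any column with > 10% gaps disqualifies its windows. The
degenerate core covers, per column, the union of codons of **every residue
observed** at that column — required for primers meant to amplify across
taxa — with the per-position IUPAC covering possibly exceeding the exact
codon set (e.g. Leu → `YTN`). Degeneracy is the product of per-position
cardinalities and equals the count of distinct expansions. Reverse primers
are IUPAC reverse-complemented; the non-degenerate 5′ sequencing tail
(conventionally 23 bp) is prepended after orientation. Default degeneracy
cap 512 and 6–8 aa windows follow common degenerate-primer practice.
Melting temperature, dimer screening, and consensus-clamp scoring are out
of scope.

## Synthetic data: what it emulates, and what it does not

**Families.** Sequences descend from a seeded 320-residue ancestor with
diagnostic sites fixed (Rossman at 35, Y/K at 190/194, C at 230). All
other sites mutate independently to a residue of a different chemical
class, with the per-site probability solved in closed form so the expected
pairwise class similarity matches the request (default 0.75 within groups,
0.60 between; requests below 0.2 are infeasible under this model and
rejected). Within the motif search windows (±12 of each diagnostic site)
the residues that could mimic the motif (`G`, `Y`/`K`, `C` respectively)
are excluded from the mutable background; without this, decoys that break
one diagnostic residue could be legitimately rescued by a chance
compensating residue inside the screen's ±10 tolerance, and perfect
decoy separation would be unattainable by construction rather than by
implementation fault. Fragments delete the first 60 residues (past the
Rossman region); decoys substitute one diagnostic residue into a different
class. Not emulated: indels, rate heterogeneity, empirical substitution
matrices, compositional bias.

**Gene trees.** The backbone is species-consistent, with each
secondary-plastid host lineage nested as one monophyletic group inside its
expected donor clade — the vertical expectation under plastid-donor gene
ancestry. Donor clades are sampled densely relative to nested host groups
(36 rhodophytes, 12 prasinophytes, 12 UTC chlorophytes vs ≤ 3-leaf host
groups in the default panel, echoing broad donor-lineage sampling in real
surveys); this guarantees the donor lineage stays modal at ≥ 0.8 purity at
the clade root while no wrong lineage can reach 0.8 at any inner anchor.
Duplications copy a clade of ~5 distinct taxa in place (leaf ids suffixed
`.1`/`.2`); HGTs regraft a recipient leaf beside a leaf of a foreign
primary lineage. All supports equal `support_level` (default 1.0). Branch
lengths are exponential with mean 0.1 — tree shape, not branch-length
realism, is the point.

**Complement tables.** Each species draws por ∈ {1, 2} (fair coin); LIPOR
loss probability is `loss_rate + coupling·(por−1)` clipped to [0, 1]
(defaults: loss 0.3, coupling 0). Lost complements show pseudogenes
instead of clean absence with probability `pseudo_rate` (default 0.15),
emulating gradual loss. Partial complements are not generated (losses are
all-or-nothing, matching the dominant observed pattern); partial
classification is exercised by the bundled survey instead.

Because the generators hold the diagnostic motifs fixed, plant events into
clean backbones, and use idealized supports, passing recovery tests
demonstrates correctness of the algorithms under their stated assumptions
— not robustness to alignment error, incomplete lineage sorting, weak
support, or contamination in real data.

## Numerical and procedural choices

* One integer seed drives each generator through a single `numpy`
  Generator; identical seeds give byte-identical outputs.
* NJ tie-breaks are lexicographic; negative branch estimates clamp to 0.
* Rooting splits the outgroup branch 50/50.
* Logo and similarity computations treat `X` as missing, never as a match.
* Exact-test p-values come from `scipy.stats.fisher_exact` and are
  verified in the test suite against exhaustive hypergeometric
  enumeration. Under the null the test is conservative (measured type-I
  error ≈ 2.5–4.5% at α = 0.05 across acceptance runs).
* Problem sizes in the test and acceptance suites (families of ~40–60
  sequences, trees of ~60–90 leaves, 50–200 replicate seeds) are desk-scale
  choices that keep the full run in seconds while leaving every recovery
  statistic well away from small-sample noise.

## Known limitations

* The origin classifier uses a single normalized support scale; it cannot
  weigh posterior probability and bootstrap jointly.
* Reproduction of published similarity percentages is approximate: the
  original metric (identity vs class similarity; pairwise mean vs
  consensus) is unstated.
* The duplication caller reports species-overlap calls only; it does not
  reconcile against a dated species tree, and it does not decide whether a
  duplication preceded or followed a transfer.
* Genus-level por counts paired with species-level LIPOR rows blur the
  association test's unit of analysis; the caveat is surfaced in the CLI
  output.
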