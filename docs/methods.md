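# Methods

This note documents the models and procedures implemented in
`irminer`, their assumptions, the defaults and why they were chosen,
and what the synthetic data does and does not emulate.

## Motif model

An ITIM/ITSM occurrence is any six-residue window
`(V|L|I|S|T)xYxx(I|L|V)`: position 1 drawn from {V,L,I,S,T} (T marks
the switch-motif variant), position 3 exactly tyrosine, position 6
from {I,L,V}, and positions 2/4/5 unconstrained. Coordinates are
1-based closed intervals. Three deliberate choices:

- **Overlapping windows all count.** "Number of occurrences" is
  ambiguous for overlapping matches; counting all windows is the
  simplest well-defined rule, and because the permutation null uses
  the identical counter the resulting statistic is internally
  consistent. Switching to non-overlapping counting would change both
  numerator and null in the same direction.
- **Ambiguity codes (X, U) match wildcards only.** An unknown residue
  must never supply evidence at a constrained position.
- **ITSM vs ITIM labelling is positional** (T at position 1) and
  purely annotational: both classes are treated identically
  downstream.

ITAM embedding — two `Yxx(I|L)` half-sites separated by 6–12
residues — is likewise an annotation, never a filter: ITAM-bearing
receptors can relay either activating or inhibitory signals, so
flagged candidates are surfaced for the analyst rather than removed.

## Topology

Per-residue states {i, o, M, S} are consumed as given (typically from
TOPCONS); the package does not second-guess upstream predictions, and
a known failure mode of that kind (a receptor whose transmembrane
helix is mispredicted, e.g. MPIG6B in the packaged reference) is
therefore out of reach by design. Classification: zero maximal `M`
runs → soluble; ≥ 2 → multi-pass; exactly one → single-pass, type II
when the residue preceding the helix is cytoplasmic, type I otherwise
(a signal-peptide or extracellular N-terminus). A one-helix protein
with no cytoplasmic flank at all is conventionally typed I; it carries
no intracellular domain, so every downstream result is empty either
way.

Candidate motifs must be **fully** intracellular (all six residues
state `i`). The looser reading — any overlap with a cytoplasmic
segment — would admit tyrosines buried in the membrane; full
containment is the strictest defensible interpretation and is what
the tests pin down.

The 10,000-residue length filter (boundary inclusive) mirrors the
practical input limit of consensus topology predictors.

## Permutation null

For each protein with ≥ 1 intracellular motif, every intracellular
domain is shuffled independently (Fisher–Yates via numpy's generator
shuffle), motifs are recounted per domain (windows never span domain
boundaries), and the chance likelihood is the fraction of iterations
with total count ≥ the observed count — a valid one-sided permutation
p-value, since the identity arrangement is always reachable.

- **Per-domain (not concatenated) shuffling** preserves the length
  structure and cannot create cross-boundary motifs; a
  `shuffle_mode="concatenated"` switch exists for sensitivity
  analysis.
- **Defaults:** N = 10,000 iterations; inclusion threshold
  0.25 + ε with ε ~ U[0, 0.01) drawn once per protein. ε randomises
  borderline decisions; it is drawn from a per-protein child generator
  (seeded from the run seed and a CRC of the protein id) and recorded
  in the output, so every decision is reproducible and independent of
  the order in which proteins are processed.
- **Oracle.** `exact_likelihood` enumerates all `len!` orderings of a
  short domain (≤ 9 residues; identical letters weighted by
  multiplicity) and returns the exact probability as a fraction. For
  the canonical test domain `SAYAAL` this gives 1/120, and the
  Monte-Carlo estimate is required to agree within three binomial
  standard errors. The oracle shares no code path with the Monte-Carlo
  estimator beyond the window counter itself.

No multiple-testing correction is applied across proteins: the
threshold is a calibrated inclusion cutoff, not an error rate.

## Structure confidence

Per-residue pLDDT is read from the B-factor column of single-model,
single-chain PDB files (the AlphaFold monomer convention), taking the
CA atom's value and requiring all atoms of a residue to agree within
1e-3; residue numbering must be gap-free. A motif's score is the
arithmetic mean over its six residues; a protein passes when any
motif's mean is **strictly below** 80. The strict boundary follows the
"below 80" reading of the rule rather than the complementary
"above 80 excluded" phrasing, and the threshold is configurable.
Values below 50 are additionally flagged as likely intrinsic
disorder. The underlying caveat — monomer structure predictions ignore
conformational changes on ligand binding or complex formation — means
a sub-80 motif is *accessible in the modelled state*, not proven
functional.

## Expression classification

Counts are normalised by median-of-ratios size factors (per-sample
factor = median over genes with an all-positive geometric mean of
count/geometric-mean), TPM inputs are log2(x+1)-scaled directly; the
pseudocount keeps zeros at zero, and all category logic depends only
on median ranks and differences, not the absolute scale. Expression
calls compare each gene's per-condition mean against the median of
**all** genes' means in that condition (strict inequality; a
candidates-only universe is rejected as an error). The alternative
reading — call each sample separately, then take the per-condition
majority — is available as `call_mode="per-sample-majority"`.

Categories are a total, single-valued partition of
(expressed at rest, expressed activated, log2FC): the ±0.5 log2FC
boundaries belong to *threshold* (the up/down categories are printed
as strict inequalities), and a gene expressed at rest but not after
activation is *threshold-disinhibition* regardless of fold change.
Genes absent from a dataset are reported as not detected, distinct
from not expressed. Sharing across cell types uses the
"expressed in either state" rule and partitions genes exclusively
(upset-style), so combination counts sum to the number of genes
expressed anywhere.

For tumour-infiltrating T cells, a gene is called expressed in a
subset when the subcluster-weighted mean of cell-level Z-scores is
strictly positive (weights per subset must sum to 1); an alternative
median-across-subsets rule is exposed as an option without any claim
about which variant matches published heatmaps.

## Synthetic data

The generators emulate only the statistical structure the pipeline
assumes, not biology: uniform-composition sequences with planted
motifs (a rejection step re-draws accidental consensus windows so
planted counts are exact ground truth), block topologies per protein
class, extended-chain PDB geometry carrying prescribed pLDDT profiles
at %6.2f precision, and expression matrices with log-normal
backgrounds (log2 mean 5, sd 2 — arbitrary but documented) and
planted genes at log2 9/1 baselines shifted by the planned effect on
activation. Passing tests therefore demonstrate correctness of the
pipeline's logic under its own assumptions; they say nothing about
topology- or structure-prediction quality on real proteins, isoform
arbitration in real annotation, or real expression noise.

The end-to-end fixture (ten proteins, one designed failure per stage)
uses tyrosine-free backgrounds so that planted motif counts are exact
and the chance likelihood of true candidates stays uniformly low
(~0.03) for every seed, while the designed permutation failure uses a
composition-rich domain (`SDYSEL` + S×10 + Y×10 + L×10: observed
count 1, shuffle likelihood ≈ 0.8). This makes the fixture's expected
outcome a property of its construction rather than of a particular
seed.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scale — a
ten-protein fixture at the full N = 10,000 permutations, 1,000 random
sequences for the scanner oracle, 50 short domains (≤ 8 residues, so
exhaustive enumeration stays below 8! orderings) for the Monte-Carlo
vs exact comparison, and 100 planted genes over a 400-gene
background — sizes chosen so the whole suite completes in seconds
while every stage is still exercised at its published defaults.
Gene-level aggregation keeps the best isoform (lowest likelihood,
then lowest minimum motif pLDDT, then lexicographic protein id);
proteins lacking a structure file are carried with an explicit
`no-structure` status rather than dropped. Degenerate inputs fail
loudly: empty proteomes, all-membrane topologies, candidate-only
expression universes, multi-chain structures, and residue-numbering
gaps are errors, not silent coercions.

## Known limitations

- Absolute proteome-scale survivor counts depend on a specific genome
  annotation, topology predictor, and structure database, none of
  which the package runs; only the filtering rules are implemented.
- The permutation likelihood is itself a Monte-Carlo estimate; at
  N = 10,000 its standard error near the 0.25 threshold is ≈ 0.004,
  which is the reason the ε jitter exists.
- Isoform-level expression cannot be resolved from gene-level
  matrices; categories describe genes, not isoforms.
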