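# Methods

## Quantification model

The counting unit is the triple (protein accession, peptide sequence,
localized phosphosite set). Distinct peptides covering the same residue
remain separate rows, and multiply-phosphorylated peptides are one unit
keyed by their full site set — counts are never split across the
residues of a multi-site peptide. A per-residue aggregation view
(`quant.collapse_to_sites`) sums the counts of every unit containing a
residue, but all statistics run at unit level. Protein coordinates are
1-based; FLR thresholding is inclusive (≤), with 0.01 as the default
threshold.

Simulated FLR values separate cleanly at 1%: correctly localized PSMs
draw FLR ~ U[0, 0.01], mislocalized PSMs U[0.01, 0.5]. Real localization
scores overlap across that boundary, so on real data the threshold
trades sensitivity against localization purity in a way the synthetic
tests do not exercise; passing tests show the plumbing and the
threshold semantics are right, not that 1% is optimal for any
instrument.

## Differential test

Counts `y_sj` for unit `s` in sample `j` are modelled as Poisson with
rate `μ_s · L_j · θ_c(j)`, where `L_j` is the sample's library total and
`θ` a condition effect. The test is a likelihood-ratio of `θ_HFD =
θ_LFD` against free rates, referred to χ²(1); q-values come from
Benjamini–Hochberg, with ties broken by unit key so the output is
deterministic. The reported fold change is

    lnFC = ln[(Y_HFD + c)/N_HFD] − ln[(Y_LFD + c)/N_LFD]

with condition totals `Y`, condition library sizes `N`, and pseudo-count
`c = 0.5` guarding zero totals. All-zero units are reported as p = 1,
lnFC = 0. A unit is regulated when |lnFC| ≥ ln 2 and q ≤ 0.10.

This is a deliberately transparent stand-in for hierarchical-Bayes
spectral-count tools: the downstream stages consume only (lnFC, FDR)
pairs, and the Poisson LRT is exactly testable (label-swap antisymmetry,
BH monotonicity, simulated type-I error ≈ nominal). It does not model
biological over-dispersion; the generator's optional gamma rate
multiplier (`dispersion`, default off) exists to probe that gap. Fold
changes use the natural-log convention, under which a lnFC of −2.1929
corresponds to the reported ~9-fold decrease at the ACACA S79 activity
site; published statements implying base-2 for other sites exist, and
the package simply fixes one convention rather than resolving that
inconsistency.

## Kinase activity

NetworKIN-dialect predictions are kept when score > 2 **or** NetPhorest
probability > 0.1 (both strict); iGPS-dialect rows carry no scores and
are assumed pre-filtered upstream (10% FPR), then everything is
restricted to kinases detected in the phosphoproteome. The enrichment
background is the set of detected units carrying at least one retained
prediction — "all detected phosphopeptides with kinase–substrate
relationships" — and the test is the exact hypergeometric upper tail
P(X ≥ k) with k the kinase's substrates in a direction group, K its
substrates in the background, n the group size, N the background size.
Significance is p < 10⁻⁴ per source (iGPS and NetworKIN enrichments are
computed separately and unioned for reporting; a merged mode exists).

Kinases significant in exactly one group are assigned HFD (up) or LFD
(down). Kinases significant in both get a KSEA z-score

    z = (mean(substrate log2FC) − mean(all log2FC)) · √m / sd(all)

with population standard deviation (the convention is not uniquely
fixed in the literature; population sd is used and documented here) and
natural-log fold changes divided by ln 2. z > 0 assigns HFD, z < 0 LFD.
Human-ortholog substrate mapping for NetworKIN-style inputs is an
optional two-column identifier map; identity by default.

## Network integration and modules

Edges are undirected, unweighted after thresholding (STRING combined
score > 0.6, strict; curated sources kept wholesale), restricted to
pairs of regulated phosphoproteins (no linker nodes — out-of-set edges
are counted and logged), canonicalized and deduplicated with source
provenance unioned. Significant kinases enter as extra nodes with
`ksr`-source edges to substrate proteins already in the network.

Module detection follows the cohesiveness objective
`f(V) = w_in / (w_in + w_bound + p·|V|)` with penalty p = 2, greedy
growth from the highest-degree unassigned seed by the single
add/remove step that most increases f, merging of candidates with match
coefficient |A∩B|²/(|A||B|) > 0.8, minimum size 3, and a one-sided
Mann–Whitney test of members' in-cluster vs out-of-cluster degrees at
p < 0.05 (the published analysis names only the p cut; the test choice
is this package's). Ties break lexicographically, so results are
deterministic. Hub reporting includes all degree ties at the top-10%
cutoff; the power-law fit is least squares on log₁₀ frequency vs log₁₀
degree over degrees ≥ 1.

Known limitation: with penalty 2 on sparse unweighted backgrounds, the
greedy search willingly absorbs weakly attached background chains (a
pendant node joins whenever `w_bound + p·|V| > w_in`), so
planted-module recovery is seed-dependent around the Jaccard ≈ 0.75
level under the default planted-partition conditions. The recovery
experiment evaluates the detector on the full union of generated edge
sources: synthetic combined scores are uniform decorations with no
reliability signal, and thresholding them would only randomly thin the
structure being recovered.

## Term enrichment and heat map

Per direction group, the same hypergeometric upper tail runs over GMT
term sets against a detected-protein background. Terms survive when at
least one group has p < 0.005 and ≥ 3 overlapping genes (both conditions
in the same group). Values are −log₁₀ p (base 10 chosen; the convention
is documented rather than inherited), with untested term/group cells
encoded as 0 (p = 1) so Euclidean distances stay defined. Rows follow
the UPGMA (average-linkage) dendrogram leaf order; rows are pre-sorted
by term identifier so ties resolve deterministically. Ontology
propagation is out of scope — term sets are expected pre-propagated.

## Synthetic data

The generator emulates the study design it exists to test: 2 conditions
× 3 biological replicates, 200 quantified sites on 76 proteins, Poisson
spectral counts (event counts; over-dispersion optional and off by
default), expected count 10 per site per sample, 10% of sites planted
differential at 4-fold (half up, half down — "up" means higher in HFD),
5% of PSMs mislocalized to an adjacent S/T/Y decoy residue, 12 kinases
with 30 predicted substrates each of which 4 are active (80% of an
active kinase's substrates drawn from its direction group; 30% of
non-planted NetworKIN pairs given sub-threshold scores), two 8-node
dense interactome modules (within-module edge probability 0.9) over a
0.02 background, and 20 annotation terms of 15 genes with four planted
direction associations. Values stated by the emulated design (replicate
count, fold cut, module geometry, baseline rate, differential fraction)
are taken from it; the remaining defaults are single realistic choices
made for testability, since inter-replicate dispersion and
prediction-score distributions of the real data are not published.

Each component (counts, predictions, interactome, annotations) draws
from an independent child stream of the config seed, so identical seed
and config give byte-identical output files. Identifiers are synthetic
accessions (P00001…, KIN01…, T0001…) with sites as residue+position.

What the generator does *not* emulate: peptide-to-protein inference
ambiguity, correlated site behaviour within proteins, realistic FLR
score overlap, prediction-score correlation with true kinase activity
strength, scale-free interactome topology outside the planted modules,
and ontology structure among terms. Recovery results on synthetic data
therefore validate correctness of the inference chain, not expected
performance on real tissue phosphoproteomes.

## Problem sizes in the validation experiments

The reproduction script and acceptance tests use 10 seeded repeats for
differential recovery (2,000 unit tests), 20 repeats for null type-I
error (4,000 tests) and kinase recovery, and the prescribed
planted-partition fixture (seed 3) for module recovery. Observed FDR is
averaged over repeats because FDR control is a statement about the
expectation of the false-discovery proportion, which fluctuates
substantially in any single 200-unit realization.
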