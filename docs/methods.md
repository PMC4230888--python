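# Methods

This note documents the models and procedures halopan implements, the
parameters that matter, the synthetic data the test suite runs on, and
the numerical choices made where the design was genuinely open.

## Scope and shape

halopan is a library-first package: the importable API plus the
narrative scripts in `examples/` are the interface, and no console
entry point is installed. The analyses it covers are the stages of a
clade-scale comparative-genomics study — assembly QC, protein-family
construction, pangenome structure, gene-tree-based transfer detection,
compositional (G+C) landscapes, proteome electrostatics, and
phylogenetic profiling — each usable independently on the shared data
model in `halopan.io`.

## Assembly contamination screen (`halopan.io`)

Contigs are screened against hits to a contaminant database (e.g. the
host strain and cloning vector used in library preparation). A hit is
significant at E ≤ 10⁻²⁰. A contig is removed when significant hits
cover ≥ 80% of its length, or when it is ≤ 1 kb and has any significant
hit. Longer contigs with only a small-portion hit are removed when they
carry no native annotated features; if they carry features not
attributable to a contaminant taxon (substring match against a
configurable taxon list, default *E. coli*/vector names) they are kept
but flagged for manual review. The filter is idempotent, and
kept ∪ removed partitions the input. All coordinates in the package are
0-based half-open internally; GFF3's 1-based closed convention is
converted at the file boundary. Ambiguity codes other than A/C/G/T —
not just N — count as ambiguous bases wherever ambiguity matters.

## Protein families (`halopan.families`)

Edge filter: an all-vs-all similarity edge survives iff
min(qcov, scov) ≥ 0.80, min(qlen, slen)/max(qlen, slen) ≥ 0.75 and
E ≤ 10⁻¹⁰ (clustering) or 10⁻²⁰ (targeted homolog screens, where the
stricter cutoff separates closely related transporter families).
Coverage is the single best aligned span over the full sequence length;
multiple HSPs are not merged. Self-edges are dropped and reciprocal
duplicates merged keeping the lowest E-value. The upstream all-vs-all
search itself is out of scope: the module consumes its tabular output.

Markov clustering is implemented natively (dense numpy): edge weights
w = −log₁₀E capped at 200 (E = 0 maps to the cap; a bitscore transform
is available), self-loops at each node's maximum incident weight,
columns normalized to a stochastic matrix, then alternating expansion
(matrix square) and inflation (entrywise power I, column renormalized)
with pruning of entries below 10⁻⁵, to a 10⁻⁸ convergence tolerance
with a 200-iteration cap (non-convergence returns the current state
with a warning flag — it has not been observed on test inputs).
Clusters are the connected components of the limit matrix's support;
proteins absent from the edge set become singleton families. The
protein universe is sorted lexicographically before matrix
construction, so results are independent of edge order. Inflation
defaults to 2.5; `benchmark_inflation` scores a grid (e.g. 1.4–8.0)
against curated families by adjusted Rand index restricted to the
curated proteins and flags the argmax. Cluster granularity grows with
inflation, but strict monotonicity of the cluster count is treated as a
diagnostic, not an invariant.

## Pangenome analysis (`halopan.pangenome`)

The family × genome matrix stores copy numbers; a binarized view
underlies presence/absence operations. Rarefaction draws, for each
sample size n in 0..N, a configurable number of uniform subsets of n
distinct genomes (default 10,000) and averages the count of families
present in at least one sampled genome; the exact expectation
E[U(n)] = Σ_f [1 − C(N−m_f, n)/C(N, n)] is returned alongside as a
closed-form companion, and the test suite checks it against exhaustive
subset enumeration on a 6-genome toy. Sample sizes run 0..N inclusive
and are configurable. "Singletons" excluded under the
`mcl_no_singletons` definition are single-member families (one protein
total), not single-genome families. Core families have copy number > 0
in every genome; genus-private families occur only within one genus;
genus markers additionally require universality within the genus and
copy number exactly 1 in every member. Genus reports give 25th/50th/75th
percentiles with linear interpolation between closest ranks (the
numpy default) — the percentile convention is fixed and documented
rather than configurable.

Missed-gene rescue scans the sequence between two anchor families, in
species where both anchors lie within 5 kb on one contig and the target
family has no call between them, for ORFs in all six frames whose
nucleotide length is within ±20% of the target family's median member
length. ORFs start at ATG/GTG/TTG (archaeal usage) and end at the first
in-frame stop; a fixed-length window mode (e.g. 117 nt) subsumes the
simpler scan of translating every contiguous window. Candidates are
reported best-first by ungapped identity (position-wise comparison,
adequate because the synthetic model is indel-free; real data with
indels would need an aligning comparison) against any family member,
at a default floor of 30%.

## Transfer classification (`halopan.hgt`)

Tips carry domain tags from their ID prefix: H (haloarchaea), A (other
archaea), E ((eu)bacteria). Monophyly of a tag is unrooted: some edge's
bipartition must separate exactly the tagged tips; one tagged tip, or
all tips tagged, is trivially monophyletic. Trees are handled as plain
adjacency structures (parsed via dendropy) with degree-2 roots spliced
out, so the answer is independent of how the newick string was rooted
or rotated.

"Attaches among bacteria" has no canonical unrooted definition, so it
is operationalized as a nearest-neighbor rule: root on the H-separating
edge and collect the tags of the non-H tips reachable through at most
`neighbor_depth` (default 1) intervening internal nodes from the
attachment node. Under the default strict rule the verdict is
`basal_import` iff that composition contains at least one E and no A;
a `majority_bacterial` alternative requires only more E than A. Strict
is the default because it can only lower, never raise, the basal-import
count — the conservative choice when re-testing a transfer claim.
Branch support values on input trees are ignored. Family extension
recruits additional homologs at E ≤ 10⁻¹⁰ and identity ≥ 30%; extended
families beyond `max_family_size` (default 200 — a practical bound on
feasible tree inference, configurable) are flagged `excluded_too_large`
and drop out of the assessed denominator, as do all-H (`untestable`)
trees. Summaries report basal/non-monophyly counts with percentages
rounded to one decimal. Clade support for a guide tree is the fraction
of replicate trees containing each non-trivial guide bipartition
(canonicalized as the side not containing the lexicographically
smallest tip); replicates with a differing tip set are skipped and, by
default, still counted in the denominator.

## G+C landscape (`halopan.gc`)

%G+C is computed in 100 bp windows at 20 bp steps per contig; the
terminal sub-window residue of each contig is skipped. The denominator
excludes ambiguous bases within the window (so sub-threshold ambiguity
does not bias composition); windows with > 10% ambiguous bases are
imputed to the contig mean and flagged, and means are computed over
non-imputed windows only.

Changepoints in the window series are found by penalized change-in-mean
detection: binary segmentation (default) with a final refinement pass
that re-locates each changepoint as the single best split between its
neighbors (removing the bias of splits found while an interval still
contained several true changepoints), or an exact O(n²) optimal-
partitioning dynamic program for short series. The default penalty is
BIC-style, 2σ̂²·log(n)·lag, where σ̂ is a robust (MAD) estimate from
differences at the smallest non-overlapping lag and the lag factor
(window/step, 5 at the defaults) compensates for the moving-average
autocorrelation that overlapping windows induce — without it the
penalty assumes n independent observations and over-segments badly.
Segmentation is invariant to adding a constant to the series.
Divergent regions are segments whose mean differs from the contig mean
by ≥ `divergence_min` (default 5 percentage points — above the ~4.9
point binomial noise SD of a 100 bp window at 62% G+C), converted to bp
intervals; no minimum region length is imposed beyond
`min_segment_windows` (default 10). This fully automated pipeline
replaces manual curation of changepoints with explicit (penalty,
min_segment_windows, divergence_min) knobs; no numerical identity with
any particular changepoint package is claimed. Analyses are neutral to
replicon size and to the direction of divergence.

Features whose midpoint falls in a divergent region (an any-overlap
mode is available) feed the enrichment test: for family f,
fold = (k_f/R)/(K_f/G) with k_f of the family's K_f features among the
R region features out of G total. Rows are reported at fold ≥ 8 with
K_f ≥ 5 (small families excluded to avoid trivially infinite
enrichment), with an unannotated-family flag carried through.

## Isoelectric points (`halopan.pi`)

Net charge at a given pH is the Henderson–Hasselbalch sum over
ionizable groups: free N- and C-termini once per chain, D/E/C/Y acidic
and H/K/R basic side chains per occurrence. The default pKa table is
the EMBOSS-style set (N-term 8.6, C-term 3.6, D 3.9, E 4.1, C 8.5,
Y 10.1, H 6.5, K 10.8, R 12.5) and is swappable; cysteine counts as
ionizable, and unknown/ambiguous residues (B, Z, X) contribute no
charge. Because every term is strictly decreasing in pH the charge has
a unique zero, found by bisection on [0, 14] to 10⁻⁴. pI depends only
on composition, not residue order. Absolute pI values depend on the pKa
set — different published tables shift proteins by up to ~1 pH unit —
so only distributional properties (bimodality, mode ordering, high-pI
fractions) are asserted, and the biopython implementation (a different
pKa set) is used as a rank-order cross-check in tests, not as a
numerical target. Proteomes are histogrammed into 100 equal bins on
[2, 13] (bin k covers [2+0.11k, 2+0.11(k+1)), last bin closed;
out-of-range pIs counted separately); the high-pI census uses the
inclusive pI ≥ 7.5 rule and per-annotation tallies are sorted by
high-pI instances. A subunit-level report labels a family high/low/
variable by whether ≥ 60% of members fall on one side of pI 7.5.

## Phylogenetic profiling (`halopan.profiles`)

Distances are Euclidean on binarized profiles by default (a copy-number
mode exists); clustering is scipy agglomerative with average linkage
(the linkage is a parameter — no published default exists to match),
cut either at a height or into k clusters, with ties broken by sorted
family ID. Annotation transfer: in any cluster where ≥ 80% of the
annotated members share one category (categories come from a
user-supplied map, since category assignment is inherently curatorial),
every unannotated member is proposed to carry that category with the
supporting members listed. Only families unannotated on input are ever
labeled, and proposals are stable under family order permutation.

## Synthetic data (`halopan.synth`)

Every generator is a pure function of (parameters, seed) — reruns are
bit-identical — and ships a `TruthBundle` (scenario, seed, parameters,
planted structure) sufficient to score the corresponding stage without
reading generator internals.

What the generators emulate, and defaults: pangenomes of 12 genomes in
4 genera (a desk-scale stand-in for a clade of tens of genomes) with 25
core and 60 accessory families, accessory presence probability 0.4,
paralog probability 0.05, member sequences point-mutated from a family
ancestor at rate 0.05, lengths uniform on 80–400 aa; the emitted edge
table contains all within-family pairs at threshold-passing coverage
and E-values plus optional sub-threshold noise edges. Genomes are
i.i.d. base draws at a local target G+C (background 62%, the
haloarchaeal norm) with planted composition segments and optional N
sprinkling. Proteomes mix a D/E-enriched acidic composition (majority,
default 80% — matching the strongly acidified haloarchaeal profile)
with a K/R-enriched basic minority; at the default presets the high-pI
fraction tracks the basic fraction to within a few points. Gene trees
are built under four scenarios — basal transfer (H clade inside the
bacterial subtree), multiple transfer (H split across two bacterial
attachment points), no transfer (H nested among archaea), scattered
(each H tip paired with its own bacterial sister) — with optional
random NNI moves applied after construction (truth verdicts recorded
before noise). Missed-gene cases plant a conserved
anchor–target–anchor synteny and delete the target from the feature
table of chosen species while leaving it in sequence; inter-anchor
spacers are A/C-only so the planted gene is the only qualifying ORF.

What the generators do **not** emulate: indels (sequence evolution is
point-mutation only, keeping pairwise identity analytically
predictable), codon usage and amino-acid exchangeability structure,
rate heterogeneity, gene order beyond the single planted neighborhood,
assembly artifacts, and alignment/tree-inference error (trees are
perturbed topologically, not re-inferred from sequences). Passing
tests therefore demonstrate correctness of the implemented statistics
and decision rules on data matching their assumptions, not robustness
to every failure mode of real draft genomes.

## Problem sizes used in verification

The automated checks run at desk scale, chosen to exercise every code
path while keeping the whole suite fast: 1,000 gene trees across
scenarios, 500 random trees against the exhaustive monophyly oracle,
100 G+C simulations of 800-window series with two planted segments
(|Δ| 8–16 points, σ = 3), 1,000 random proteins against the 10⁻⁴
grid-scan pI oracle, 10,000 rarefaction replicates on a 6-genome toy
matrix, and 60-node planted-partition graphs for clustering. The
published genome-scale totals from the motivating 80-genome study
(17,591 clusters, 304 core families, 497 removed contigs) require the
original proteomes and search results and are not reproduced here;
the percentage bookkeeping that follows from printed count pairs is.

## Known limitations

- MCL is dense-matrix; fine for thousands of proteins, not for
  hundreds of thousands (a sparse backend would be the next step).
- Ungapped identity in the rescue scan under-scores homologs with
  indels; swap in an aligning scorer for real data.
- The basal-import neighbor rule is one defensible operationalization
  of an informally stated criterion; both provided sister rules are
  reported with the neighbor composition so calls can be audited.
- The contamination filter's contaminant-annotation detection is a
  substring match against a taxon list; annotation conventions vary.
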