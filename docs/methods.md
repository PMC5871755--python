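# Methods

This note documents the models, algorithms, and numerical choices behind
`amplicord`, and what the synthetic-data design does and does not establish
about real sequencing data.

## The two classification paths

**Long reads.** Reads spanning the whole 16S gene are classified by optimal
semi-global alignment against every shortlisted reference: the query is
aligned end-to-end while leading/trailing reference gaps are free, the right
shape for an amplicon read against a full-length gene. Scoring is match +1,
mismatch −1, gap −1 per base (the "open" penalty is charged on the first gap
base and "extend" on each subsequent one, and both are −1, so gaps are
effectively linear; the engine only supports open == extend). The best hit
is selected by score; the ≥80% identity gate is applied afterwards, so a
read whose best hit is still too diverged is reported unclassified rather
than re-assigned to a worse hit. Identity is matches / alignment columns
over the aligned span (gap columns count against identity; free end gaps do
not). Ties on the top score go to the lexicographically smallest accession
and are flagged — this determinism is what makes the bias audit's counts
exact rather than run-dependent.

The DP kernel is numba-compiled (~4 ms for a 1.4 kb × 1.4 kb score-only
pass). Candidate references are shortlisted by shared 8-mer count (top 5,
ties kept) with a full-scan fallback when the query shares no 8-mer with any
reference; an exact-containment short-circuit recognises that a query
contained in a reference already attains the maximal possible score
(match × query length), which is what makes zero-error simulations cheap
without changing any result. Sequences above 5,000 bp are rejected to guard
the quadratic DP.

**Short reads.** Mates are merged by scanning all overlaps ≥ 20 bp,
keeping those with mismatch fraction ≤ 0.1, and choosing the one with most
matching bases (disagreements resolve to the higher-quality base, first mate
winning ties). Merged reads are collapsed to unique sequences and clustered
greedily at 97% identity in order of decreasing duplicate count, then
length, then id; each sequence joins the first existing centroid it matches,
else founds a new cluster. Representatives are then assigned
closed-reference style: best database hit at ≥97% identity, otherwise the
whole cluster is discarded (logged, and reported as dropped reads). Greedy
centroid clustering is order-dependent by nature; fixing the order makes it
reproducible, at the cost of not exactly replicating any particular external
clustering tool.

## The error-free bias audit

Given a set of identified taxa, the audit recreates their exact reference
sequences, extracts the V3–V4 product of the short-read primer pair, and
pushes those regions through (a) best-hit alignment and (b) clustering +
closed-reference assignment, comparing each sequence's new accession to its
original identity (exact accession match — the strictest reading; rank-level
agreement can be recovered from the reported assignment maps). Full-length
recreated sequences are reclassified as a control path and must be 100%
concordant on any sane database. Because inputs are error-free, any
discordance isolates the information lost by the shorter region: taxa
identical over the amplicon collapse onto one accession via the tie-break,
and the audit reports per-path Venn counts, the cross-path comparison, and
the unique-sequence reduction from clustering.

## Synthetic data: what it emulates

Reference sequences are 1,447 bp: nine variable regions (V1–V9; V3 and V4
are 150 bp, the rest 100 bp) embedded in a conserved scaffold shared across
the database, with exact binding sites for both primer pairs — the
full-gene pair at the ends, and the V3–V4 pair placed so the short-read
product is exactly 440 bp (hence 2×250 mates overlap by 60 bp; 402 bp
remain after primer trimming). Confusable groups share the entire V3–V4
amplicon region byte-for-byte while all other variable regions are drawn
independently (≈75% divergence per site there, far above the 3% the design
requires). Random non-group pairs agree only on the scaffold, keeping
full-length identity far below the 97% OTU radius.

Abundance models: `even`, `staggered` (geometric, spanning slightly over
three decades — 3.01 — so the ≥10³ max/min span survives floating-point
normalisation), and `lognormal` (σ = 1.5), all normalised to sum exactly
to 1.

Read simulation works on amplicons (post-PCR), not genomes, and does not
model chimeras — the audit of interest concerns read length, not PCR
artefacts. The long-read error model is derived from the platform's mean
read quality: p = 10^(−12.65/10) ≈ 5.43% total error, split
substitution:insertion:deletion = 10:2.5:1. Emitted qualities are drawn
per-base from N(12.65, 3) clipped to [1, 41] and are *decorative*: they
match the quality model in distribution but are not coupled to the actual
error positions. Short reads get 0.3% substitution-only error and N(35, 3)
qualities. Consequences: passing tests demonstrate the pipeline mechanics
and their calibration under these idealised error processes; they do not
demonstrate robustness to homopolymer-biased nanopore errors, quality-error
correlation, chimeras, or contamination, none of which are modelled.

## Diversity statistics

Generalized UniFrac d^(α) is computed from per-branch community proportions
(fraction of each community's mass descending through the branch), summing
bᵢ(p_Ai+p_Bi)^α |p_Ai−p_Bi|/(p_Ai+p_Bi) over occupied branches and
normalising by Σ bᵢ(p_Ai+p_Bi)^α. α = 1 is weighted-normalized UniFrac;
α = 0 removes abundance weighting of shared branches; d^U uses
presence/absence only. The variance-adjusted form d^VAW divides each branch
term by √(mᵢ(m_total − mᵢ)) with mᵢ = p_Ai+p_Bi and m_total = 2; branches
where that factor vanishes (empty, or carrying the entire combined mass)
are excluded from both sums. Because published figure panels are labelled
inconsistently between d^VAW and d^0.5/d^0 in this literature, the matrix
API emits all five variants (d^W, d^0.5, d^0, d^U, d^VAW) under distinct
names rather than guessing.

Trees for synthetic runs come from neighbour joining on (1 − alignment
identity) distances, midpoint-rooted; externally built Newick trees are
accepted through the same parser. Negative NJ branch lengths are clamped to
zero with the deficit shifted to the sibling branch (logged). Midpoint
rooting of a 2-leaf tree is handled explicitly (root exactly between the
tips), since the general re-rooting routine degenerates there.

PCoA double-centres −D²/2 and eigendecomposes; axes with eigenvalues below
a relative 1e-12 tolerance are dropped, negative eigenvalues are reported
(UniFrac matrices need not be Euclidean), proportions explained are taken
over the positive spectrum, and axis signs are fixed by making the
largest-magnitude loading positive.

perMANOVA computes pseudo-F from squared distances via the standard
partition (SS_total = Σ_{i<j} d²ᵢⱼ/n; within-group SS analogously per
group); p is (1 + #{F_perm ≥ F_obs})/(1 + n_permutations) over seeded label
permutations, or the exact fraction over all distinct label arrangements
when `exact=True`. With g groups of k samples the attainable p has a floor
of (number of arrangements tied with the identity)/(total arrangements) —
e.g. 2/20 = 0.1 for 3+3 and 2/70 ≈ 0.029 for 4+4 — which dictates the
replicate counts used in the separation demonstrations. A constant or
all-zero distance matrix yields F identical across permutations and p = 1.

Rarefaction subsamples without replacement (multivariate hypergeometric)
and reports mean ± sd of inverse Simpson (1/Σp²) per depth.

## Reproducibility

One global seed drives everything. Each stochastic stage draws from a
substream seeded by `stage_seed(global_seed, stage_name)` (the seed mixed
with a CRC32 of the stage name, reduced mod 2³¹), so stages are independent
and individually re-runnable. Pipeline runs write a manifest recording the
config, derived seeds, and every artefact path; rerunning a config
reproduces the classification tables byte-for-byte.

## Problem sizes

The bundled scale is 20 reference taxa with 4 confusable pairs, two
lognormal communities of 12 taxa, and 2,000 reads per library
(`PipelineConfig` defaults); the pytest suite exercises the same stages at
120–400 reads, and the acceptance script uses 10,000 reads for the
mock-recovery test, 2,000 for the zero-error gate, 100 for the degraded
gate, 1,000 random instances for the UniFrac oracle, and 200 datasets ×
999 permutations for the perMANOVA null calibration. These sizes were
chosen so the statistical assertions have comfortable power while the whole
battery runs on a single CPU in minutes.

## Known limitations

* No real-database reproduction is bundled: results on SILVA-style
  databases and real reads depend on database completeness and chemistry
  effects the simulator does not model.
* The aligner supports linear gap costs only; true affine scoring (open ≠
  extend) would require a three-matrix DP.
* Primer matching is gapless (Hamming), the standard virtual-PCR
  semantics; primer-template bulges are not considered.
* The k-mer shortlist is a heuristic: a best hit sharing no top-5 8-mer
  count with the query could in principle be missed at extreme divergence,
  though the full-scan fallback covers the no-shared-k-mer case entirely.
* MAF input is consumed directly; the axt intermediate some external
  pipelines produce is deliberately skipped.
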