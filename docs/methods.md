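# Methods

`clonescape` reconstructs the clonal evolution of a tumor from multi-region
deep sequencing of a single patient: which mutations arose together, in what
order, and how the resulting clones are distributed over the sampled
regions — including regions that are histologically normal but carry a trace
tumor population. This note documents the model, the numerical choices, and
what the synthetic cohorts used for testing do and do not establish about
real data.

## The cellular mixture model

A sequenced sample mixes diploid normal cells (fraction `1 − t`) with tumor
cells (fraction `t`, the purity). A fraction `f` of tumor cells carries a
copy-number variant (CNV) of total integer state `M`, giving the
sample-average ("composite") copy number

```
c = (1 − t)·2 + t·[(1 − f)·2 + f·M].
```

A somatic mutation carried at multiplicity `n` by a fraction `g` of the
CNV-positive cells has expected variant allele fraction (VAF)

```
v = t·f·g·n / c        ⇒        g = v·c / (t·f·n),
```

and its cancer cell fraction is `CCF = g·f` (equivalently `CCF = v·c/(t·n)`,
independent of `f`). The constraint `f, g ∈ [0, 1]` is the feasibility rule:
a multiplicity/timing model that pushes either quantity outside the unit
interval beyond a noise tolerance (default 0.05, matched to binomial noise
at ~2500X) is rejected and the alternative models are considered. Because
somatic back-mutation is vanishingly rare, one mutation belongs to one
lineage, so a model must be feasible in *every* region where the mutation is
detected (detection: ≥3 alt reads and VAF ≥ 0.002).

Multiplicity candidates per segment of haplotype states `(a, b)`: mutation
after the CNV (`n = 1`), before it on the duplicated haplotype (`n = a`),
before it on the retained haplotype (`n = b`, only when `b ≥ 2`; `b = 1`
duplicates the after-model and `b = 0` leaves nothing to observe). Because a
feasible model fits each region's VAF exactly (one free `g` per region),
residuals discriminate candidates only through boundary clamping; residuals
within one noise band (1e-3 in squared-VAF units) are treated as ties and
broken toward the later timing, the more parsimonious default. Alternatives
are reported, never discarded silently.

## Purity

Purity comes from the clonality of the designated founder mutation (in
diffuse midline glioma, histone H3 K27M), present in every cancer cell:
with `f = g = 1`, the model inverts to `t = 2v / (n − v·(M − 2))`; diploid
reduces to `t = 2v`. A truncal cluster whose CCF exceeds 1 diagnoses an
underestimated purity ("superclone") and rescales `t` upward by the maximal
truncal CCF.

A single founder site at 2500X carries binomial noise of about ±0.02 on `t`
at high purity, so the pipeline additionally re-anchors each sample's purity
on the **median CCF of clonal truncal variants** (`refine_purity`). This is
the two-sided completion of the superclone rescale: the truncal cluster must
sit at CCF 1, and its median pools the depth of all truncal sites. With
20 truncal variants this brings purity error to ~0.004 mean absolute.

## Allelic imbalance and CNV prevalence

An unbalanced copy change shifts het-SNP B-allele fractions away from 0.5.
For state `(a, b)` at cellular prevalence `CP` (fraction of *all* cells),
the folded deviation is `AI = CP·d / (2c)` with `d = a − b`, inverted as
`CP = 4·AI / (d − 2·AI·(M − 2))`. Balanced events (bi-allelic duplication,
`a = b`) leave `AI = 0` and are resolved from the composite copy alone,
`CP = (c − 2)/(M − 2)`. Candidate states default to one-copy loss, CN-LOH,
single and double gain, bi-allelic duplication, plus one focal-amplicon
state; candidates are scored by the squared mismatch of predicted versus
observed `(c, AI)` (AI weighted ×4 so a full one-copy imbalance weighs like
one copy of `c`), and one `(a, b)` state is enforced per segment per
patient.

**Identifiability caveat.** All `(a, 1)` gain states share the same
`(c, AI)` signature up to a CP rescaling (`AI = u/(2(2+u))`, `c = 2 + u`
with `u = CP·(a − 1)`), so low-prevalence gains of different amplitude are
indistinguishable from a segment summary; the inversion returns the lowest
state consistent with `CP ≤ 1` and lists the others as alternatives. High
prevalence amplicons (e.g. a clonal sevenfold gain) are identified uniquely
because the impostor states would need `CP > 1`. Mutant-allele amplicons
are additionally pinned by the mutation dosage through `n`.

CNV timing (early truncal versus late branch acquisition) is resolved by
least squares against per-sample predictions `CP = t·CCF(node)`: a truncal
event shows `CP ≈ t` in every region. Placements must agree within 0.1
absolute CP (array-scale noise) in every sample.

## Clustering

Mutations sharing a branch share a CCF in every region, so variants are
clustered on their multi-sample CCF profiles with a finite binomial mixture:
variant `i` in cluster `k` contributes `Binomial(alt; depth, t·CCF_k·n_i/c_i)`
per sample. EM with k-means++ initialization (distinct starts only, default
20 seeds), weighted-MLE M-step solved exactly per cluster-sample by
bracketed root finding, K selected by BIC (`k·S + k − 1` parameters, default
range 1..min(15, variants)). Labels are canonicalized by descending mean
CCF; convergence at relative log-likelihood change < 1e-8 or 500
iterations. Clusters of any size are kept — a subclone separated from its
parent by a single mutation can be real and important. Variants with
uncovered samples contribute likelihood only where covered.

## Tree construction

Two rules constrain ancestry. *Sum rule* (pigeonhole): within a sample,
children's CCFs cannot sum beyond their parent's. *Crossing rule*: clusters
whose CCF ordering reverses between samples cannot be ancestor and
descendant. The search enumerates rooted arborescences (root = the
support-weighted clonal cluster, weighting samples by purity × CCF support)
depth-first in descending-CCF order with incremental pruning; an unordered
exhaustive pass backs it up for near-tie profiles. Samples under 5% purity
are excluded; their compositions are inferred afterwards from the clusters
fit in high-purity samples and flagged `inferred_only`.

All valid trees reproduce the node CCFs identically, so they differ only in
how much of the rule tolerance (default 0.05 absolute CCF) they consume.
The search therefore minimizes total slack usage (child-over-parent excess
plus sum-rule overage — both ≈ 0 for the generating tree) and breaks ties
toward the tightest containing parent. When several trees remain valid, one
is returned and every alternative parent that keeps the tree valid is
recorded in `ambiguous_attachments`; in simulations at study-like
conditions roughly a quarter of patients contain at least one genuinely
ambiguous attachment, and the truth is essentially always within the
reported set. Flat subclonal-truncal clusters (present everywhere at a
near-constant CCF in [0.5, 1)) carry no ordering signal and attach directly
under the founder, unless that forcing alone makes the instance infeasible.

Clone fractions per region are CCF(node) − Σ CCF(children), clipped at zero
within tolerance; a founder clone of purely truncal variants absorbs the
remainder so fractions sum to 1. Regions where more than one child-of-founder
lineage holds ≥5% of cancer cells are flagged multi-lineage. Lineage
statistics: molecular age = mutation count from the trunk (exclusive) to the
most distant descendant; average CCF = mean over qualifying regions of the
lineage subtree's summed fractions; the age–CCF association is summarized by
Pearson correlation across lineages.

## Tumor-in-normal detection

Two stages. (1) The founder site's alt count is tested one-sided against
its background error rate (exact binomial); a non-significant founder ends
the assessment — no cluster can be present without the trunk. (2) Each
cluster's member-site p-values are combined by Fisher's method and corrected
across clusters by Benjamini–Hochberg (call at q ≤ 0.05). The tumor
fraction comes from the founder-clonality inversion (`2v` at a diploid
founder) with an exact binomial CI, and CCFs within the contaminating
population use that fraction as purity. Background rates come from a
leave-one-out panel of normals, `(Σalt + 0.5)/(Σdepth + 1)` per site,
floored at 1e-6 — sites with systematic artifacts get honestly high rates.

## The synthetic cohort

The generator emulates an autopsy-style multi-region cohort: one truncal
founder mutation; 4–15 mutation clusters (default 6) of 8–15 mutations on a
random tree biased toward broad main lineages; allele-specific CNVs
(defaults: truncal 17p-style loss, truncal CN-LOH, a branch gain, a branch
bi-allelic duplication) with a few mutations timed before/after each event;
3–7 tumor regions (default 5) whose compositions are Dirichlet draws over a
sparse support (trunk + a connected node subset, with multi-lineage support
in about half of regions); purities Beta(8, 2) (median ≈ 0.82); depth
Poisson around 2500 (floor 1 read); symmetric per-read error, default 1e-5
as appropriate for error-suppressed deep sequencing; normals with 0–12%
tumor content composed of the trunk plus one invading lineage. Het-SNP BAFs
mirror at 0.5 (unphased), carry Gaussian noise (sd 0.03), and are
summarized per segment with the noise-corrected estimator
`sqrt(max(0, mean((BAF−0.5)²) − sd²))` so null segments shrink to zero.
Everything is deterministic given (config, seed).

What the generator does **not** model: read-level artifacts and mapping
error, overdispersed depth, trinucleotide signatures, sex chromosomes,
subclonal copy-number heterogeneity within a segment, and phased
haplotypes. Passing tests therefore establish correctness of the inference
given the mixture model's assumptions — not robustness to alignment or
segmentation errors, which are upstream of this package.

The age-coupled cohort generator (for the lineage statistics) draws lineage
molecular ages uniform on 5–60 mutations and regional occupancies Dirichlet
with concentration proportional to age × lognormal(0, 0.2) noise at
concentration scale 8 — a tight expansion–accrual coupling (true Pearson
ρ ≈ 0.9) such that the association is detectable per 10-lineage cohort.

## Numerical and degenerate-input conventions

- Depth 0 means "not covered": VAF and CCF are absent there, never 0.
- `cnv_ccf` is undefined at `M = 2` (copy-neutral events carry no `c`
  signal) and at `t = 0`; both raise typed errors.
- Feasibility clamps inside `[−tol, 1 + tol]` and hard-rejects outside.
- Purity estimates above 1 are clipped and flagged.
- EM ties and k-means duplicates are deduplicated; all randomness flows
  from explicit integer seeds.
- Problem sizes in the test-suite and acceptance script (replicate counts,
  cohort sizes) are scaled to give stable rates on a single CPU; each
  statistical assertion states its own sample size.

## Known limitations

- Tree identifiability is bounded: when a non-ancestral cluster dominates a
  small cluster in every sampled region, multiple trees satisfy both rules
  and only the ambiguity report distinguishes the cases. More regions with
  distinctive compositions shrink this set.
- The `(a, 1)` gain degeneracy above limits state calls at low prevalence.
- Clustering assumes a shared CCF per cluster per sample; gradual CCF
  drift within a lineage will be split into discrete clusters.
- Contamination error rates assume the panel of normals shares the
  artifact profile of the tested sample.
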