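# Methods

## Model

A vaginal community profile is a composition `p` on the probability
simplex over a phylotype vocabulary. Classification is nearest-centroid:
the sample is assigned to the sub-CST whose reference centroid `q`
maximizes Yue–Clayton's θ,

    θ(p, q) = Σ pᵢqᵢ / (Σ (pᵢ − qᵢ)² + Σ pᵢqᵢ)
            = Σ pᵢqᵢ / (Σ pᵢ² + Σ qᵢ² − Σ pᵢqᵢ).

The two denominators are algebraically identical; the implementation uses
the dot-product form (it vectorizes as three matrix products) and the test
suite holds it to the difference form, evaluated by a naive per-pair
python loop, to 1e-12 on 10,000 random simplex pairs. θ is clipped to
[0, 1] to absorb last-ulp rounding.

**Vocabulary alignment.** Sample and centroid vocabularies are unioned
with zero fill before scoring. A taxon present in the sample but absent
from every centroid therefore depresses similarity (its Σp² mass inflates
the denominator) rather than silently vanishing — unknown organisms make
assignments less confident, which is the behaviour a QC user wants.

**Confidence.** An assignment is flagged low-confidence when the winning
score is below `low_conf_threshold` (default 0.5) or the top-two margin is
below `margin` (default 0.1). Both defaults are configurable and echoed
into output metadata; no single pair of values is canonical, these are
conservative choices that flag the grey zone between related types
(e.g. III-B vs V). Exact score ties resolve to the first centroid in file
order and are flagged — reproducibility over neutrality.

## Training

Stage 1 clusters the cohort's relative-abundance vectors by Ward linkage
on the condensed Bray–Curtis distance matrix (`scipy.cluster.hierarchy`,
Ward.D2-style squared-distance update). Bray–Curtis is non-Euclidean, so
Ward here is a heuristic; it is retained because it is the established
practice for defining CSTs. The dendrogram is cut at every k in 2..20 and
each cut is scored with the Davies–Bouldin index and the silhouette
coefficient. Davies–Bouldin is computed on the abundance vectors with its
standard Euclidean internals (`sklearn`); silhouette is reported both
Euclidean and on the Bray–Curtis matrix, since the scoring space is a
genuinely open choice. The chosen k is the Davies–Bouldin argmin, smallest
k on ties, with a manual override (`k_stage1`).

Stage 2 pools **all** samples whose stage-1 cluster is coarse-named IV-C
and re-clusters the pool (same algorithm) into `ivc_k = 5` subtypes. If
stage 1 already split the diverse communities, pooling and re-cutting at
k=5 recovers that split; if it lumped them, the second cut provides it.
Pools smaller than `ivc_k` are named as a single group.

**Naming.** Clusters are named from their mean composition, in order:

1. top taxon *L. crispatus* → I-A if its mean ≥ `dominance_threshold`
   (default 0.75, "the focal species clearly dominates"), else I-B;
   *L. iners* likewise → III-A / III-B; *L. gasseri* → II;
   *L. jensenii* → V.
2. *Ca. L. vaginae* ≥ 0.15 → IV-A.
3. otherwise *G. vaginalis* ≥ 0.30 → IV-B.
4. remainder → IV-C; the marker genus (*Streptococcus* / *Enterococcus* /
   *Bifidobacterium* / *Staphylococcus*), when it is the top taxon at
   mean ≥ 0.25, selects IV-C1..C4; an even community (typically with
   notable *Prevotella*) falls back to IV-C0.

All thresholds are keyword parameters. The A/B split is threshold-driven
rather than tree-driven: the dendrogram does not guarantee that subtype
boundaries coincide with merge heights, while a dominance threshold is
deterministic and auditable. When two clusters derive the same name the
default for the standalone `name_clusters` is to raise (the caller should
revisit k or the thresholds); the end-to-end `CommunityStateTyper`
defaults to merging them instead, because the Davies–Bouldin-chosen k need
not match the canonical label set one-to-one and merging same-named
clusters is exactly what the name asserts about them.

**Centroids and uncertainty.** Each sub-CST centroid is the arithmetic
mean of its members' compositions (renormalized to guard rounding; means
of simplex vectors already sum to 1). Bootstrap SEs: 100 replicates, each
drawing ⌈0.10·N⌉ samples with replacement from the full (unstratified)
table; a label's centroid is recomputed from the replicate's members of
that label, and the SE is the across-replicate standard deviation.
Rare sub-CSTs can be absent from many replicates; they contribute nothing
to those replicates and a warning is attached when a label appears in
fewer than half of them. Resampling is governed by a single
`random_state`.

## Synthetic cohorts

The generator emulates the structure of large 16S cohorts of
reproductive-age women. Thirteen target profiles over 12 key taxa encode
the qualitative dominance structure of the sub-CSTs (I-A: 0.90
*L. crispatus*; V: 0.65 *L. jensenii* with 0.20 co-occurring *L. iners*;
IV-A: 0.45 *Ca. L. vaginae* + 0.20 *G. vaginalis*; IV-C0: even with 0.20
*Prevotella*; C1–C4 dominated by their marker genus; etc.), with each
profile's remainder spread over a 20-taxon minor tail with geometric
decay so rare-taxon filtering and union-vocabulary handling are
exercised. Mixture weights make *Lactobacillus*-dominated types the
majority and IV-C as a whole rare (6%). Per sample: sub-CST ~ mixture,
composition ~ Dirichlet(concentration × profile, restricted to the
profile's support), depth ~ log-uniform over 1005–411,805 reads, counts ~
multinomial(depth, composition). Default concentration is 50 — moderate
within-type spread that produces a genuine grey zone between related
types (III vs V); recovery tests that need near-separable types raise it
to 200. A master seed spawns per-stage substreams (labels, compositions,
depths, counts), so adding a stage never perturbs earlier draws.

What the generator does **not** emulate: longitudinal within-subject
correlation, sequencing-run batch effects, taxonomic misannotation, and
novel community types absent from the reference. Passing recovery tests
therefore demonstrate correctness of the classifier and trainer under the
stated mixture model, not field performance on arbitrary real cohorts.

Label-conditional clinical metadata (pH, Nugent score) is drawn from
per-sub-CST category probabilities; the default P(pH ≤ 4.5 | sub-CST)
values follow published cohort characterizations for the types where such
figures exist (I-A 0.83, III-A 0.61, V 0.61, IV-C0 0.24, IV-C1 0.15,
IV-C2 0.42, IV-C3 0.28, IV-C4 0.39) and plausible interpolations for the
rest. A continuous pH (uniform within the drawn bin) and an integer
Nugent score are emitted so the binning operations are exercised on raw
values.

## Numerical and I/O choices

- Relative abundance defaults to dividing by the row sum of taxa counts
  (vectors land exactly on the simplex, which the θ math requires); the
  declared `read_count` divisor is retained as an option, reporting the
  pre-renormalization coverage per sample, because the file contract
  mandates the column while the divisor itself is a free choice.
- Rare-taxon filtering measures "study-wide frequency" as the pooled read
  fraction (taxon total / table total), default threshold 1e-5; mean
  per-sample relative abundance is exposed as an alternative mode since
  the phrase admits both readings.
- Composition validation: vectors must sum to 1 within 1e-9; centroid
  file rows are renormalized with a warning when within 1e-3 of 1 and
  rejected beyond that. All accumulation is double precision; no
  compensated summation (vocabularies are ≤ a few hundred taxa).
- pH bins: ≤4.5, (4.5,5.0), [5.0,5.5], >5.5 — the boundary 5.5 belongs to
  the inclusive middle bin; 4.5 to the first. Nugent: 0–3 low, 4–7
  intermediate, 8–10 high.
- Headers are case-sensitive by default (`sampleID`, `read_count`,
  `sub_CST`) with an opt-in case-insensitive mode; dialect sniffing is
  limited to comma vs tab.
- Degenerate inputs: all-zero samples raise (or are collected as
  per-sample failures in table classification, which continues and exits
  with a distinct code from the CLI); identical-sample cohorts raise in
  training unless a single-cluster fallback is requested.

## Problem sizes

Unit and property tests run on cohorts of 60–1,000 samples over a
32-taxon vocabulary; recovery and round-trip checks use n = 1,000 at
concentration 200 and n = 500 at the default 50, sizes at which the
mixture's rarest sub-CSTs still receive enough members to form clusters.
The oracle-equivalence check uses 10,000 random simplex pairs.

## Known limitations

- The classifier cannot place communities unlike any centroid (e.g.
  *Prevotella*-dominated profiles common in some populations); they are
  assigned to the nearest existing type with a depressed score — the QC
  report's median-vs-reference comparison (flag gap 0.2, configurable) is
  the intended detector for this.
- Ward on Bray–Curtis lacks the variance-minimization guarantee it has in
  Euclidean space.
- Trained sub-CST names depend on naming thresholds where a cohort's
  cluster means sit near them; the training report records each
  cluster's mean key-taxon abundances so such calls are auditable.
- The simulator draws independent samples; no repeated-measures structure.
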