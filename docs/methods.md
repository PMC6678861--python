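# Methods

## The question and the procedure

Knockout of a transcription factor (TF) changes the expression of many
genes the TF never binds. One candidate mechanism is spatial: an affected
gene may sit, in the folded nucleus, next to a gene that *is* bound by the
TF, and be co-regulated through the protein complexes assembled there.
`sarloc` operationalises this idea on three inputs: per-TF bound-gene
lists from ChIP binding P-values, per-TF knockout-affected (KO) gene
lists, and a genome-wide list of interacting kilobase segment pairs from
chromosome-conformation capture, called at an FDR cutoff.

The pipeline:

1. **Regulon filtering.** For each TF, genes present in both the bound and
   KO sets are removed from both, as is any gene whose TSS lies within
   3 kb (same chromosome) of a gene of the opposite set. Exclusion is
   computed against the original sets on both sides simultaneously, which
   makes it symmetric, order-independent and idempotent. TFs with more
   than 20 genes remaining on *both* sides are analyzable ("more than" is
   read strictly; `FilterConfig(strict_min=False)` switches to ≥).
2. **Gene–segment mapping.** A gene is attached to every segment whose
   interval is within 2.5 kb of its TSS on the same chromosome (0 if the
   TSS falls inside the interval). Genes with no segment are kept and can
   simply never colocalize, so pooled denominators are not silently
   shrunk.
3. **Linear-proximity control.** Intra-chromosomal interactions whose
   segments are separated by less than 60 kb are discarded. The anchor is
   midpoint-to-midpoint (symmetric and natural at kilobase segment
   resolution); `anchor="edge"` gives the closest-edge alternative.
4. **SAR classification.** A KO gene of TF *t* is a *spatially adjacent
   regulated* (SAR) gene if two distinct segments — one mapped to the KO
   gene, one mapped to any bound gene of *t* — form a retained interaction.
   Sharing a segment is deliberately *not* colocalization: only the
   interaction list defines nuclear proximity. Inter- and intra-chromosomal
   flags are kept separately; "SAR" means their union.
5. **Permutation test.** The pooled frequency (fraction of (TF, KO gene)
   pairs colocalized with ≥ 1 bound gene; the bound-side direction swaps
   the roles) is compared with a chromosome-matched null: each gene of
   each per-TF set is replaced by a gene drawn uniformly from the same
   chromosome, without replacement within one drawn set; for the
   colocalization test both sides are randomized each replicate, for the
   cellular co-component test only the gene side (the binding structure is
   data, not a label to permute — the two tests are intentionally
   asymmetric). The empirical P value is the fraction of replicates whose
   statistic *strictly* exceeds the observed one; ties do not count as
   exceeding. Because a discrete statistic can tie often, a conservative
   (k+1)/(N+1) estimator is provided (`PermutationResult.p_conservative`)
   and is the right choice for calibration statements; when no replicate
   exceeds, the result is additionally reported as "< 1/N".
6. **Downstream contrasts.** Flat GO semantics throughout (co-membership
   in ≥ 1 shared term; no ontology propagation — the inputs are flat
   term→gene lists): cellular co-component of the TF with another TF that
   binds the SAR gene; biological co-process of the (non-)SAR gene with
   any bound gene of its TF. Co-expression is Pearson r over the
   expression conditions (pairwise-complete under missing values; pairs
   with < 3 shared observations are skipped and logged). Group contrasts
   use the two-sided Mann-Whitney U test; bootstrap percentile intervals
   (1,000 resamples by default, seeded) give the error bars on medians.
   Expression variability is the per-gene sample SD across conditions
   (`metric="cv"` for the coefficient of variation). Promoter nucleosome
   occupancy is averaged over strand-oriented positions [−500, −1]
   relative to the TSS (position −1 abuts the TSS on the coding strand;
   minus-strand genomic windows are reversed at construction, see
   `orient_promoter_window`); genes that are both bound and SAR are
   excluded from the bound-vs-SAR occupancy contrast by the pipeline.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `binding_p_cutoff` | 0.005 | ChIP binding P defining a bound gene (inclusive) |
| `interaction_fdr_cutoff` | 1e-4 | FDR defining a chromosomal interaction |
| `proximity_bp` | 3000 | TSS–TSS exclusion radius between bound and KO sets |
| `min_set_size` | 20 | both regulon sides must exceed this |
| `tss_window_bp` | 2500 | gene-to-segment attachment radius |
| `min_intra_sep_bp` | 60000 | minimum midpoint separation of intra pairs |
| `n_reps` | 10000 | permutation replicates |
| `n_boot` | 1000 | bootstrap resamples for median CIs |

The binding "affinity" of an event is stored as −log10 of its binding
P-value (larger = stronger); any strictly monotone rescaling leaves every
contrast unchanged because all contrasts are rank-based.

## Randomness and reproducibility

One user seed drives everything. Permutation replicate *r* draws from a
generator seeded with the pair (seed, r), so results are bit-identical
for a fixed seed and independent of execution order; the pipeline derives
fixed per-stage offsets from its global seed so disabling one analysis
never shifts another's draws. Two runs of `run_pipeline` with the same
configuration produce byte-identical summary JSON.

## The synthetic test bed

`sarloc.simulate` generates a complete input suite with known ground
truth. Genes sit at fixed 5 kb spacing on 16 chromosomes (40 genes each by
default); kilobase segments (3 kb) tile every chromosome contiguously, so
each gene maps to at least one segment by construction. Contacts are
Bernoulli per eligible segment pair at `background_contact_rate` (1e-3),
drawn over all separations so the 60 kb filter has real work to do. Each
of the 20 TFs gets 30 bound and 30 KO genes, sampled disjointly and
uniformly. With `planted_enrichment` e > 1, the primary-segment pair of
every (bound, KO) gene pair of a TF is additionally connected so that its
*total* contact probability is e·r; at e = 1 nothing is planted and every
(bound, KO) pair has exactly the background probability — the generator
is then an exact null for the permutation test, which is what makes the
calibration check meaningful. Every planted contact is recorded; the
planted-SAR truth labels only contacts that survive the interaction
filters. Default rates for the feature layers (CC co-planting 0.5, BP
co-membership 0.78 for planted-SAR vs 0.66 background, motif rates
0.30/0.32, occupancy offset +0.5, within-block expression correlation
0.5, affinity shift +1 on colocalized bound events, 112 expression
conditions) mirror the contrast structure the analysis is meant to
detect, at magnitudes a genome-scale yeast compendium would show.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: yeast-specific nuclear geometry (centromere
clustering, rDNA), realistic contact-degree heavy tails, the empirical
asymmetry between the KO-side and bound-side enrichment (planting is
symmetric here, so both directions light up), realistic GO term-size
distributions, missing values in expression (supported by the code,
exercised by unit tests, absent from generated matrices), and any
dependence between feature layers beyond the planted SAR labels. One
consequence worth naming: because TF binding is assigned uniformly over
genes, SAR genes are no more likely than random same-chromosome genes to
be bound by a CC-sharing partner TF, so the cellular-co-component
permutation test is itself null on synthetic data — its calibration, not
its power, is what the shipped checks establish. Likewise, pipeline-
classified SAR groups mix planted-SAR genes with genes made SAR by
background contacts, which dilutes the planted feature contrasts (BP
co-membership, occupancy, motif rates) at genome scale; the feature-layer
tests therefore contrast ground-truth planted labels, while the
classifier itself is checked by recall against those labels.

## Numerical choices

- Coordinates are 1-based with closed intervals; a TSS is a single base.
- Unordered segment pairs are canonicalised (lexicographically sorted,
  deduplicated keeping the smallest FDR); self-pairs are rejected.
- Strict ties in the permutation test (see above); the exact rank-sum
  method is used for tie-free samples with min(n, m) ≤ 8, the
  tie-corrected continuity-corrected normal approximation otherwise; a
  contrast whose pooled values are all equal (or with an empty group) is
  returned as an explicit no-contrast sentinel rather than a P value.
- Table writers emit floats as %.17g and readers parse with round-trip
  precision, so write→read is the identity.
- Degenerate inputs: empty regulon sides are allowed everywhere and
  produce empty classifications; zero denominators raise.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: oracle equivalence on 100 random instances (≤ 50 genes, ≤ 100
interactions); null calibration on 200 datasets (8 chromosomes, 10 TFs,
21+21 genes) at 500 replicates; power and planted-SAR recall on 100
datasets at the default sizes (16 chromosomes, 20 TFs, 30+30 genes) at
1,000 replicates; the acceptance script's headline run uses 2,000
replicates and a 60-dataset calibration batch at 300 replicates. These
sizes were chosen so the whole suite completes in minutes on one core
while keeping binomial uncertainty on the calibration/power statements
well inside the asserted bands.

## Known limitations

- The interaction list is taken as the 3D-adjacency ground truth; no
  polymer modelling, no re-calling from raw contact data.
- Flat GO only; no ontology traversal, no enrichment testing.
- The external yeast datasets behind the published genome-scale numbers
  are not packaged; with those files supplied in the documented TSV
  dialects, the same pipeline computes the corresponding full-scale
  quantities.
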