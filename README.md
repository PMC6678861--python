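# sarloc

Most genes whose expression changes when a transcription factor (TF) is
knocked out are *not* bound by that TF. `sarloc` tests a spatial
explanation in budding-yeast-style data: a knockout-affected gene may sit
next to a TF-bound gene in the folded nucleus and be regulated through
the protein complexes assembled there. The package classifies these
**spatially adjacent regulated (SAR) genes**, quantifies their enrichment
with a chromosome-matched permutation test, and runs the downstream
functional and chromatin contrasts. It is written for regulatory
genomicists who have per-TF ChIP binding lists, per-TF knockout
differential-expression lists and a chromosome-conformation-capture
interaction list, and for methodologists who want a fully synthetic,
ground-truthed test bed for this kind of colocalization analysis.

## The statistic

Let each gene map to the kilobase segments within 2.5 kb of its TSS, and
call two genes *colocalized* when two distinct segments, one from each
gene, form an interaction (FDR ≤ 1e-4; intra-chromosomal pairs closer
than 60 kb are discarded). After making each TF's bound set B(t) and
knockout-affected set K(t) disjoint and linearly separated (≥ 3 kb) and
keeping TFs with |B|, |K| > 20, the pooled colocalization frequency is

    F = ( Σ_t |{ k ∈ K(t) : k colocalized with some b ∈ B(t) }| ) / Σ_t |K(t)|

A gene k counted in the numerator is a SAR gene of t. Significance comes
from a chromosome-matched null: every gene of every set is replaced by a
uniform same-chromosome draw (without replacement within a set), both
sides re-drawn each replicate, and

    P = #{ replicates with F_rand > F_obs } / n_reps        (strict ties)

with a conservative (k+1)/(n_reps+1) variant alongside. Downstream, SAR
vs non-SAR pairs are contrasted on GO cellular-component/biological-
process co-membership (flat term sharing), Pearson co-expression,
unbound-motif presence, promoter nucleosome occupancy over [−500, −1],
per-gene binding-TF counts and binding-event affinity — all group
contrasts by two-sided Mann-Whitney U with bootstrapped median CIs.

See `docs/methods.md` for the full procedure, parameter table and the
synthetic generator's design.

## Worked example

Generate a synthetic dataset with a 5× planted excess of (bound, KO)
contacts and run the whole pipeline:

```python
from sarloc import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(sim=SimConfig(seed=1, planted_enrichment=5.0),
                n_reps=2000, n_boot=300, seed=17)
report = run_pipeline(cfg)
s = report.summary
f = s["frequencies"]["ko_vs_bound_inter"]
p = s["permutation"]["perm_inter_ko_vs_bound"]
print(f"inter-chromosomal SAR frequency: {f['numerator']}/{f['denominator']}"
      f" = {100 * f['frequency']:.2f}%")
print(f"null mean {100 * p['null_mean']:.2f}%, empirical P {p['p_label']}")
```

prints

```
inter-chromosomal SAR frequency: 176/600 = 29.33%
null mean 19.21%, empirical P < 0.0005
```

i.e. 29% of (TF, knockout-affected gene) pairs are colocalized with a
bound gene of the same TF, far above the ~19% chromosome-matched
background, and no randomized replicate reached the observed frequency
(P below the 1/n_reps resolution). On a dataset generated with
`planted_enrichment=1.0` the same run is an exact null and P is uniform.

The same pipeline runs from files (`RunConfig(input_dir=...)`, TSV
dialects documented in `sarloc.core_io`) or from the shell:

```bash
sarloc simulate --out data/ --seed 1 --enrichment 5
sarloc run --config run.yaml --out results/
sarloc permute --data data/ --mode inter --n-reps 10000 --seed 17
```

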