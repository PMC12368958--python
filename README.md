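# soilmerge

Demographic and displacement analysis for coalescing soil microbiomes.

When a whole microbial community is transplanted into a resident community
(a *coalescence* or community merger — e.g. a defined synthetic community,
SynCom, mixed into a soil microcosm), two questions drive the analysis:

1. **Which taxa drive community growth and decline over time?**  Amplicon
   sequencing only yields relative abundances r_i, so `soilmerge` scales
   them by an independently measured total community size N (flow-cytometry
   cells g⁻¹, CFU g⁻¹, or DNA-derived genome equivalents) to absolute
   abundances a_i = r_i · N, takes per-genus differences
   Δa = mean_b(a) − mean_a(a) across replicates between sampling days, and
   partitions genera into groups (common to both communities vs exclusive,
   increasing vs decreasing vs opposite) whose summed Δa accounts exactly
   for the total community-size change in each interval.

2. **Which resident taxa are permanently displaced by the transplant?**
   For each replicate pair and day, transplant reads are removed, both
   samples are rarefied to a common depth D = 100 000 reads, and ASVs
   present in both are paired as (x, y) = log₁₀ counts in (control,
   merged).  An OLS line y = β₀ + β₁x fitted to the pooled day-0 pairs
   (before the merger can act) gives the null residual dispersion σ.  A
   paired ASV with |y − (β₀ + β₁x)| > 3σ — outside the two-sided 99.7%
   normal band — is a displacement outlier (enriched if above, depleted if
   below), and Σ|residual| per replicate pair across days measures total
   displacement, compared against within-condition replicate pairings as a
   noise floor.

A bundled generator (`soilmerge.simulate`) emulates the microcosm study
design — two resident origins with high genus- but minimal ASV-overlap, a
21-member transplant, guild-structured bloom/crash/rise trajectories,
multinomial read sampling, noisy size measurements, and injectable
displacement effects with ground truth — so every stage is testable
without sequencing data.

## Worked example

Inject a known 10-fold depletion into ten abundant resident ASVs from day
3 of a merger, then recover it:

```python
import soilmerge as sm
from soilmerge import displacement as dis
from soilmerge.simulate import concat_experiments

config = sm.ScenarioConfig(seed=1)
resident = sm.generate_community(config, "LC")
transplant = sm.generate_community(config, "SynCom")

path = sm.phase2_composition(resident)
abundant = [a for a in path.columns[path.loc[[3, 7]].min(axis=0) > 2e-3]
            if a not in transplant.syncom_members][:10]
merged_config = sm.ScenarioConfig.from_dict({
    **config.to_dict(),
    "displacement_effects": [
        {"asv_ids": abundant, "delta_log10": -1.0, "onset_day": 3}
    ],
})

experiment = concat_experiments([
    sm.dilute_community(resident, config),
    sm.generate_merger(resident, transplant, merged_config),
])
result = dis.run_displacement(
    experiment.counts,
    experiment.metadata,
    comparisons=[
        dis.Comparison("merged_vs_control", "LC", "LC+SynCom", "between"),
        dis.Comparison("within_control", "LC", "LC", "within"),
    ],
    exclude=experiment.syncom_members,
)
```

Output (printed from the fitted result):

```
t=0 baseline: y = 0.095 + 0.939 x, sigma = 0.278 (n = 1039 paired ASVs)
outlier calls: 157; injected ASVs recovered: 10/10, all depleted: True
median summed outlier distance [merged_vs_control]: 19.07
median summed outlier distance [within_control]: 11.12
```

The day-0 regression is close to the identity line with σ ≈ 0.28 log₁₀
units of replicate-plus-counting noise; all ten injected depletions are
called (as depleted) at later days, and the merged-vs-control summed
outlier distance clearly exceeds the within-replicate noise floor.

The same analyses are available from the shell:

```sh
soilmerge simulate --seed 1 --out data/
soilmerge displace --counts data/counts.tsv --meta data/metadata.tsv \
    --taxonomy data/taxonomy.tsv --exclude data/syncom_members.txt \
    --depth 100000 --k-sigma 3 --seed 0 --out outdir/
soilmerge run --config pipeline.yaml   # full simulate→…→metrics pipeline
```

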