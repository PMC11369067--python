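# engraftkit

Quantify donor-microbiota **engraftment** after faecal microbiota
transplantation (FMT) and classify clinical response in ulcerative-colitis
(UC) trials, from species-level metagenomic relative-abundance profiles.

The package targets the two-donor, 24-recipient randomized FMT trial layout:
each donor contributes 13–14 longitudinal stool samples, each recipient has
pre-FMT samples (weeks 0 and 3) and post-FMT samples (weeks 4–8, 10 and 14),
and engraftment is assessed in an *acute* window (weeks 4–7), a *durable*
window (weeks 8–14) and the *overall* window (weeks 4–14). Because trial
metagenomes of this kind are typically not publicly deposited, the package
ships a synthetic cohort generator with known ground truth, so every stage is
testable end to end.

## Method

All profiles are relative abundances with a detection limit τ = 0.1%
(entries below τ are treated as absent). For a recipient *r* with donor *d*:

1. **Donor core.** A species is *core* for *d* if it is detected (≥ τ) in at
   least 6 of the donor's 13–14 samples.
2. **Donor-derived set.** D(r) = core(d) minus every species detected in any
   pre-FMT sample of *r* — species the recipient already carried cannot count
   as engrafted.
3. **Three metrics per window W:**
   - **SEI** (Species Engraftment Index) = median over samples t ∈ W of
     Σ<sub>s ∈ D(r), detected in t</sub> x<sub>ts</sub> — abundance-weighted
     displacement of the recipient community.
   - **SEF** (Species Engraftment Fraction) = |{s ∈ D(r) : s detected in ≥ 1
     sample of W}| / |D(r)| ∈ [0, 1] — diversity of engrafted donor species.
   - **Donor similarity** = A(week 3) / A(W), where A(·) is the median
     Aitchison distance to the donor's samples (per timepoint, then median
     over the window) and week 3 is the pre-FMT baseline after pretreatment
     and lavage. The Aitchison distance is the Euclidean distance between
     centred log-ratio (CLR) vectors, with zeros replaced by τ/2; values > 1
     mean the recipient moved toward its donor.
4. **Total engraftment score** = SEF + a·SEI + b·similarity, with a and b
   chosen per window so the cohort medians of the three terms are equal.

Clinical response uses the Mayo score: at week 10, remission is a partial
Mayo ≤ 2 with no subscore > 2, partial response a decrease ≥ 3 points; at
week 14 remission additionally requires an endoscopic subscore of 0 or 1a,
and partial remission an endoscopic decrease of ≥ 1 step on the ordered
scale 0 < 1a < 1b < 2 < 3. Dropout for progressive disease is treatment
failure. Cohort comparisons use exact Fisher (point-probability two-sided
convention, exact integer arithmetic), exact Wilcoxon rank-sum, two-way
Type II ANOVA, PERMANOVA on Aitchison distances, and complete-linkage
clustering of donor family profiles.

## Worked example

```python
from engraftkit import pipeline, synthetic_cohort as sc
from engraftkit.cohort_stats import fisher_exact_2x2

cfg = sc.SimulationConfig(seed=1)          # 2 donors, 24 recipients
sim = sc.simulate_cohort(cfg)
result = pipeline.score_cohort(sim.profiles, sim.metadata)
print(result.scores[result.scores.window == "overall"].head(4).to_string(index=False))
norm = result.normalizations["overall"]
print(f"scales: sei x {norm.scale_sei:.3f}, similarity x {norm.scale_similarity:.4f}")

res = fisher_exact_2x2(8, 5, 2, 9)         # prior anti-TNF use by arm
print(f"p = {res.p_value:.3f}")
```

prints

```
subject_id  window      sei      sef  similarity  total_score  n_samples
       R01 overall 0.036905 0.326797    1.018101     1.285828          7
       R02 overall 0.046836 0.505376    1.084524     1.553356          7
       R03 overall 0.056918 0.592105    1.047461     1.645237          7
       R04 overall 0.093566 0.763441    1.106958     1.993558          7
scales: sei x 3.506, similarity x 0.8149
p = 0.047
```

Recipients are simulated with increasing ground-truth mixing fractions, and
the total score tracks them: R01 (λ ≈ 0.05) engrafts little — a third of its
donor-derived species appear (SEF 0.33) carrying ~3.7% of its community (SEI
0.037) — while R04 (λ ≈ 0.15) engrafts visibly more on all three metrics.
The Fisher p of 0.047 is the exact two-sided probability for a 2×2 table
with 8/13 vs 2/11 exposed patients per arm.

The same pipeline is available from the shell:

```bash
engraftkit simulate --seed 1 --out-dir synth/
engraftkit score --profiles synth/profiles.tsv --metadata synth/metadata.tsv --out engraftment.tsv
engraftkit classify --mayo synth/mayo.tsv --out responses.tsv
engraftkit compare --scores engraftment.tsv --metadata synth/metadata.tsv --by donor
```

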