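# partnerseq

Life-course analysis of marriage histories: who follows which partnership
trajectory between ages 15 and 50, and how those trajectories — together
with polygenic scores and socioeconomic background — relate to self-rated
health and depressive symptoms after age 50.

The package is aimed at social-science and social-genomics researchers
working with retrospective union histories (e.g. life-history surveys of
older adults). It implements the full pipeline:

1. **Sequence construction** (`partnerseq.sequences`). Per-marriage start
   and end years are expanded into a yearly state sequence over ages 15–50
   on the alphabet {N, M, R, D, W} (not married, married, remarried,
   divorced, widowed). Interior gaps are imputed by last observation carried
   forward, and every sequence is checked against legality rules (e.g.
   M→N is impossible without a recorded dissolution).
2. **Optimal matching** (`partnerseq.om`). The dissimilarity between two
   sequences *x*, *y* is the minimum total edit cost

   *d*(x, y) = min over scripts of Σ substitutions + Σ indels,

   computed by the standard dynamic program with indel cost 1 and
   transition-rate (TRATE) substitution costs
   `sub(a, b) = 2 − p(b|a) − p(a|b)`, where `p(b|a)` is the pooled empirical
   probability of moving from state *a* to state *b* in one year. Frequent
   transitions are cheap; never-observed ones cost the maximum of 2.
3. **Ward clustering and quality indices** (`partnerseq.cluster`).
   Agglomerative Ward linkage on the dissimilarity matrix (ward.D2
   convention, ward.D available), cut into *k* clusters (default 6), with
   ASW (average silhouette width), a pseudo-*R²* and Calinski–Harabasz index
   from the squared-dissimilarity variance decomposition, Hubert's Γ, and
   the Hubert–Levin C index, plus per-cluster summaries (state
   distributions, age at first marriage) used for labeling.
4. **Polygenic scores** (`partnerseq.pgs`).
   `PGS_i = Σ_j W_j · G_ij` over a SNP panel, with negative GWAS weights
   removed by allele flipping and scores standardized within the analyzed
   sample.
5. **Outcome models** (`partnerseq.models`). statsmodels-style model
   objects with `fit()` returning a results object: multinomial logit for
   cluster membership (reference: *married in 20s and continuously
   married*), proportional-odds ordered logit for 5-category self-rated
   health, NB2 negative binomial for the 0–8 CESD symptom count, and
   logistic regression for the inclusion model behind inverse-probability
   weights. All families accept analytic weights; a five-stage specification
   series (clusters / PGSs / both / clusters+SES+controls / everything),
   gender stratification, gender×cluster(×PGS) interactions with predicted
   probability surfaces, and IPW sensitivity weights are built in.
6. **Synthetic cohorts** (`partnerseq.simulate`). A generator that draws
   six archetypal trajectories with noisy timing, class membership from a
   multinomial logit on education, gender, PGSs and cohort, genotypes for a
   scored SNP panel, and outcomes from known-parameter ordered-logit and
   NB2 models — with full ground truth for recovery testing.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from partnerseq import simulate, sequences, om, cluster, models

cohort = simulate.simulate_cohort(simulate.GeneratorConfig(n=500, seed=42))
histories = sequences.histories_from_frames(cohort.persons, cohort.marriages)
seqs, excluded = sequences.build_cohort(histories)
print(f"retained {len(seqs)} sequences, excluded {len(excluded)}")

scheme = om.trate_costs(om.estimate_transition_rates(seqs))
dm = om.pairwise_matrix(seqs, scheme)
labels = cluster.cut_tree(cluster.ward_linkage(dm), 6)
print({k: round(v, 4) for k, v in cluster.quality_indices(dm, labels).to_dict().items()})
print("ARI vs latent classes:",
      round(simulate.cluster_recovery_ari(cohort, labels), 4))

spec = models.ModelSpec(outcome="srh", family="ordered_logit",
                        blocks=models.STAGE_BLOCKS[5])
res = models.fit_model(spec, cohort.data)
print(res.summary().splitlines()[0])
print(res.tidy().set_index("term")
         .loc[["cluster[never_married]", "pgs_wb", "pgs_bmi", "educ_years"]]
         .round(3))
```

prints

```
retained 500 sequences, excluded 0
{'asw': 0.7381, 'r2': 0.935, 'ch': 1420.4144, 'hg': 0.9852, 'hc': 0.0079, 'k': 6, 'n': 500}
ARI vs latent classes: 0.9969
OrderedLogit  n=500  llf=-679.947  llnull=-717.873  pseudo-R2(McFadden)=0.0528  converged=True
                        estimate     se      z      p stars
term
cluster[never_married]    -0.402  0.493 -0.815  0.415
pgs_wb                     0.087  0.080  1.081  0.280
pgs_bmi                   -0.246  0.088 -2.813  0.005    **
educ_years                 0.167  0.038  4.399  0.000   ***
```

Reading the output: all 500 simulated histories yield valid sequences; the
six-cluster Ward solution is sharply separated on this synthetic design
(ASW 0.74, Γ 0.99) and recovers the generating archetypes almost perfectly
(adjusted Rand index 0.997). In the fully adjusted ordered-logit fit, higher
BMI polygenic score and fewer years of education predict worse self-rated
health — matching the coefficients the generator used to draw the data.

The same pipeline is available from the shell (`partnerseq simulate`,
`build-sequences`, `costs`, `distances`, `cluster`, `quality`, `summarize`,
`pgs`, `fit`, `ipw`, `report`); every stage writes plain-text artifacts plus
a JSON manifest with input hashes so runs can be reproduced exactly.

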