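# straintrack

Strain-level retention analysis of low-biomass airway metagenomes from
species-specific marker genes.

Upper-airway samples (nasopharyngeal and oropharyngeal swabs) carry little
bacterial DNA and a lot of host DNA, so strain-resolution tools built for deep
gut metagenomes lose true carriers unless their filtering parameters are
relaxed and the relaxation is validated against bacterial culture.
`straintrack` implements that workflow for longitudinal cohorts: it filters
per-sample consensus marker genes, turns the surviving alignments into
pairwise SNV-rate distances, calls strain retention from intra- versus
inter-subject comparisons, clusters strains on a phylogenetic tree, and
benchmarks species detection against culture as the gold standard. A
synthetic-cohort generator with known strain genealogies makes every step
testable end to end.

It is aimed at microbiome researchers working with longitudinal swab cohorts
who want strain-level carriage statements without isolate sequencing for every
sample.

## The statistics at the core

**Marker filtering.** Each sample contributes one consensus sequence per
species-specific marker gene, with uncovered positions masked `N`. Four knobs
decide what survives: a marker counts as observed in a sample when its breadth
of coverage (non-`N` fraction) is at least `breadth_threshold` percent;
`trim_sequences` bases are cut from both marker ends; a marker is kept when at
least `marker_in_n_samples` percent of samples carry it; a sample is kept —
the species is *detected* — when it retains at least `sample_with_n_markers`
markers. Defaults are 80 / 50 / 80 / 20.

**Distances.** For samples *i*, *j* with concatenated marker alignments, the
SNV rate is

&nbsp;&nbsp;&nbsp;&nbsp;d(i,j) = (# mismatching bases) / (# positions covered in both),

a raw proportion over gap-free columns. Per species, distances are divided by
the median over all pairs, so the normalized distance is 1 at typical
between-subject divergence.

**Retention.** Sample pairs split into intra (same subject, different visits)
and inter comparisons (different subjects, same or different visit).
Normalized distances are binned at width 0.1; an intra pair strictly below a
species-specific threshold (0.2 for *S. pneumoniae* / *M. catarrhalis*, 0.1
for *H. influenzae* / *S. aureus*) counts as a retained strain, and the
retained fraction over intra pairs is the per-species retention estimate.

**Clustering.** Strains are grouped by single-linkage agglomeration on
patristic distances at a 0.01 branch-length threshold, tracked per subject
over time next to MLST sequence types, with agreement quantified by the
adjusted Rand index.

**Benchmarking.** Detection is scored against culture per species:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 = 2TP/(2TP+FP+FN).
Parameter grids are ranked by pooled F1 with ties broken toward the default
parameters under a range-normalized L1 distance.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
two-visit cohort (50 subjects, four species, species-specific retention
probabilities; sequence data lands in `scratch/`, tables in `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_filter_markers.py
python analysis/03_distances_retention.py
python analysis/04_benchmark_grid.py
python analysis/05_cluster_longitudinal.py
```

Step 02 shows why the defaults fail for a species with a small marker
database — *H. influenzae* has only 15 markers, so no sample can ever reach
the default 20-marker minimum, while a relaxed set keeps all 100 samples:

```
      species parameter_set  kept_markers  kept_samples  alignment_length
 H_influenzae       default            15             0                 0
 H_influenzae       relaxed            15           100              4500
```

Step 03 recovers the generator's retention fractions exactly at these
separations (retained drift 0.001 vs replacement divergence 0.05
substitutions/site):

```
      species  threshold  n_intra  n_retained  fraction  true_fraction
 H_influenzae        0.1       50           9      0.18           0.18
M_catarrhalis        0.2       50          20      0.40           0.40
     S_aureus        0.1       50          28      0.56           0.56
 S_pneumoniae        0.2       50          26      0.52           0.52
```

`fraction` is the retained share of intra-subject pairs called from
normalized distances; `true_fraction` is the generator's ground truth.

Step 05 clusters a six-visit *S. aureus* cohort and compares clusters with the
synthetic sequence types: `18 clusters over 60 samples; cluster-vs-ST adjusted
Rand index 1.000`, i.e. the metagenome-derived clustering reproduces the
typing partition perfectly under these conditions.

There is also a CLI for one-off runs, e.g.

```sh
straintrack simulate --seed 2 --outdir demo --subjects 10
straintrack run --seed 7 --outdir demo_run
```

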