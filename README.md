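# somascape

Somatic genomic landscape and tumour-microenvironment (TME) features for
whole-genome tumour cohorts, as a tested, reusable Python pipeline. It is
aimed at cancer-genomics analysts who already have somatic calls in hand
(SNV VCFs, SV BEDPEs, allele-specific copy-number segments, a bulk
expression matrix and a clinical table) and want the downstream feature
layer:

* **Mutational signatures** — 96-trinucleotide-context catalogues, NMF
  extraction, cosine matching against a reference catalogue, and exposure
  estimation by constrained quadratic programming with a prune-and-reassign
  rule: exposures below 10% of a sample's mutations are dropped and the
  mutations refit onto the remaining signatures.
* **Rearrangement signatures** — 32-class SV catalogues
  ({del, dup, inv} × five size bins × clustered/non-clustered, plus
  translocations), where a breakpoint is *clustered* when its fixed 1 Mb
  genome bin holds ≥ 10 of the sample's breakpoints; low-cosine matches are
  reported with a "-like" suffix.
* **Kataegis** — sliding-window exact binomial tests against the
  chromosome-wide mutation rate with BH adjustment; merged significant
  windows become loci when they hold ≥ 6 mutations at mean inter-mutation
  distance ≤ 2 kb; loci are scored and classed APOBEC by their fraction of
  C>T/C>G mutations at TpCpW (TCA/TCT) context.
* **Kataegis–SV co-localization** — pooled 1 Mb bin counts; a bin is
  co-localized when both its kataegis and breakend counts exceed the
  genome-wide means; chromosomes are ranked by combined percent =
  (fraction of samples with an APOBEC locus on the chromosome) ×
  (percent of the chromosome's bins co-localized).
* **Copy number and HRD** — length-weighted ploidy, CNA categories
  (CN 0 homozygous deletion, CN 1 loss, CN ≥ 6 gain/amplification),
  ploidy-corrected gene amplification (CN ≥ 6 below ploidy 2.7, CN ≥ 9 at or
  above), percent genome altered, sub-clonal CNA percentages from
  FDR-significant segments, and the genomic-scar trio LOH/tAI/LST with
  HRD-sum and the HRD call (HRD-sum > 42 and HRDetect probability > 0.7).
* **Complex events** — chromothripsis-like calling from interleaved SV
  clusters (> 10 with CN oscillations > 6 and significant enrichment,
  exponential-spacing and fragment-joins statistics, or > 30 with the
  exponential statistic alone).
* **Immune TME** — ssGSEA scoring of 18 immune cell-type gene sets,
  consensus k-means subtyping (elbow/silhouette/gap/Calinski–Harabasz vote,
  stability over random restarts), hot/suppressed/moderate/cold labels,
  neutrophil/T-cell ratio, cluster-vs-rest differential expression and
  pre-ranked GSEA.
* **Survival** — presence (≥ 15%) and tertile stratification, Kaplan–Meier,
  (weighted) log-rank with inverse-probability weights from stage ×
  treatment strata, BH adjustment, exact two-sided binomial enrichment and
  Pearson correlation.

Because real patient cohorts of this kind sit under controlled access, the
package ships a first-class synthetic cohort generator
(`somascape.simulate`) that plants known signature exposures, kataegis
loci, SV classes, ploidy/sub-clonality, chromothripsis chromosomes, immune
archetypes and cluster-dependent survival hazards — every downstream module
is validated by recovering what was planted.

## Worked example

```python
from somascape.pipeline import run_all
report = run_all("cohort_out", n_samples=60, seed=1)
print(report)
```

writes every result table under `cohort_out/` and prints the recovery
report (numbers from an actual run with seed 1):

```
{'n_samples': 60, 'seed': 1,
 'exposure_mae': 0.0089,            # refit vs planted exposures
 'kataegis_sensitivity': 1.0,       # planted APOBEC loci recovered
 'n_kataegis_loci': 138,
 'coloc_mean_frequency_pct': 2.41,  # genome-wide mean co-localized %
 'hotspot_chrom_rank': 1,           # planted hotspot chr8 ranks first
 'ploidy_mae': 0.0102, 'subclonal_pct_mae': 0.122,
 'n_complex_genomes': 17,
 'complex_sensitivity': 1.0, 'complex_false_rate': 0.0,
 'consensus_k': 4, 'consensus_stability': 0.951,
 'immune_ari': 1.0,                 # called vs planted immune clusters
 'logrank_p_true_clusters': 0.00086,
 'logrank_p_called_clusters': 0.00086}
```

An `exposure_mae` of 0.009 means refit signature exposures sit within one
percentage point of the planted mixtures on average; `immune_ari` of 1.0
means the consensus subtyping reproduced the planted archetype partition
exactly; the log-rank p-values show the survival separation built into the
cluster hazards is detected.

The same stages are available as subcommands of one executable
(`somascape simulate | snv-sig | sv-sig | kataegis | coloc | cna | complex
| immune | survival | run-all`), all thresholds coming from a single YAML
config whose defaults are the published operating points.

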