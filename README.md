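# alkdeep

Ultra-deep targeted-sequencing analysis of ALK kinase-domain hotspot
mutations in neuroblastoma.

Neuroblastoma tumours are frequently driven by activating point mutations
in the ALK receptor tyrosine kinase, concentrated at a handful of hotspot
residues (F1174, F1245, R1275, with rarer events at I1171 and L1240).
Because these mutations can be present in only a subclone of the tumour,
capillary (Sanger) sequencing — with a detection limit around 15–20%
variant allele fraction (VAF) — misses a clinically important minority of
them. `alkdeep` implements the analysis side of an ultra-deep (≥5000×)
amplicon re-sequencing assay of ALK exons 21–25 that resolves mutations
down to a few percent VAF:

* **pileup** — per-position A/C/G/T(+other) counts from aligned reads,
  with phred-quality filtering (default Q30) and coverage validation
  (default 5000×);
* **noise model** — per-(position, alternate-base) background mean and SD
  estimated from germline control samples, regularized by globally
  estimated variance components;
* **caller** — the *k*-standard-deviation rule: a nucleotide frequency is
  classified as a mutation when

  `z = (f_obs − μ_bg) / max(s_bg, floor, s_pred) > k`,  with `k = 5`,

  one test per alternate base per position; calls are annotated to
  amino-acid changes (ALK is on the minus strand, so codons are read
  reverse-complemented), classified clonal/subclonal (VAF < 20%) and
  Sanger-detectable (VAF > 15%);
* **dilution validation** — serial mutant:wild-type dilutions
  (undiluted, 1:10, 1:40) with expected VAF `VAF₀/(1+d)` and a measured
  detection limit;
* **cohort statistics** — mutation spectrum, clonality split,
  Sanger-missed counts, genomic-subgroup associations (Fisher's exact
  test) and Kaplan–Meier / log-rank survival machinery over a packaged
  105-case neuroblastoma cohort table;
* **synthetic data** — a seeded generator reproducing the assay's
  structure (≈0.1% background error with per-sample jitter, 5000–65000×
  depths, spike-ins at 1–60% VAF, purity scaling, dilutions) so the whole
  pipeline is testable without any sequencing data.

## Worked example

```bash
alkdeep simulate --out-dir demo --seed 1 --depth 5000      # 8 controls + 2 tumours
alkdeep noise --out demo/noise.tsv \
    $(for f in demo/control*.tsv; do echo --control $f; done)
alkdeep call --pileup demo/tumour_F1174L.tsv --noise demo/noise.tsv \
    --k 5 --min-depth 5000 --out demo/tumour_F1174L.vcf
```

which prints

```
1 call(s) from 1431 tests (0 positions not assessable) -> demo/tumour_F1174L.vcf
```

and the VCF body

```
chr2  29443695  F1174L  G  C  .  .  DP=5000;ALTC=1249;VAF=0.2498;Z=467.273;AA=F1174L;RES=1174;HOTSPOT=F1174;CLONALITY=clonal;SANGER=yes
```

— the simulated tumour carried an F1174L spike-in at 24.7% VAF; the caller
recovers it at 25.0% (within binomial noise of truth at 5000×), 467
standard deviations above that position's background, classified clonal
(≥20%) and detectable by Sanger sequencing (>15%). The cohort-level
summary of the packaged table:

```bash
alkdeep cohort-stats --report cohort.json
```

reports, among other counts, 16/105 point-mutation-positive cases (15.2%),
11 tumours mutated at F1174 and 3 at F1245, 6/16 subclonal (<20% VAF), 4
cases missed by Sanger sequencing, 4 ALK-amplified cases (20/105 ALK
events in total), a minimum VAF of 2.7%, and 27 11q-deleted cases none of
which carries an ALK mutation.

The same steps are available as a scripted narrative under `analysis/`
(`01_simulate_data.py` → `04_cohort_statistics.py`), each writing its
tables under `results/`.

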