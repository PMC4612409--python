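# amplimeth

Trend-based marker selection and bisulfite amplicon methylation analysis
along the colorectal **normal → adenoma → carcinoma** sequence.

Colorectal cancer develops through an ordered progression in which promoter
DNA hypermethylation can silence tumour-suppressive genes.  A common study
design screens stage-labelled expression matrices for genes whose expression
changes *gradually* along the progression, verifies CpG islands in their
promoters, quantifies promoter methylation by bisulfite amplicon
pyrosequencing, and complements the picture with miRNA qPCR panels and
immunohistochemistry.  `amplimeth` implements that computational chain as a
tested, reusable Python package for epigenomics researchers, with a
synthetic-data module that emulates every input — so the entire pipeline is
exercisable, with known ground truth, without any external download.

## What it computes

* **Trend selection** — per gene, the tie-corrected Kendall rank correlation
  τ_b of log2 expression against the ordinal stage code (0/1/2); two-sided
  pooled-variance Student t-tests for the three pairwise stage comparisons
  with Benjamini–Hochberg adjustment across genes per comparison; logFc as
  the difference of group mean intensities.  A marker satisfies |τ| ≥ 0.5
  and, in ≥ 1 normal-vs-lesion comparison, adjusted p < 0.05 with
  |logFc| > 1.  Genes are binned by the two-comparison Venn logic, and the
  two-condition 5-Aza re-expression screen reuses the same machinery.
* **CpG islands** — sliding-window scan (window 100, shift 1) marking
  windows with GC% > 50 and CpG observed/expected ratio
  (N_CG·L)/(N_C·N_G) > 0.6, merged into spans ≥ 200 nt.
* **Bisulfite alignment** — Smith–Waterman local alignment with Gotoh's
  affine-gap recurrence against both converted template strands (non-CpG
  C→T with CpG C→Y wildcard; complementary strand G→A with CpG G→R), and
  the read-retention rule *score ≥ 80% of the read's maximum attainable
  score* (match × read length).
* **Methylation calling** — per-CpG C/T counts from passing reads,
  assay-level percent summaries, pooled-t group comparisons with
  hyper-/hypomethylation calls vs normal adjacent tissue, and hierarchical
  clustering of the assay × sample matrix.
* **miRNA normalization** — Ct inversion (45 − Ct), interplate-calibrator
  centering, per-sample miR-423-5p reference normalization, group tests,
  and ranking of differential miRNAs by predicted targets in the marker
  set.
* **IHC Quick-score** — percent positive cells × intensity (0–3), group
  means ± SD and monotone-trend flags.

See `docs/methods.md` for the model conventions, defaults and limitations.

## Worked example

Run the numbered drivers (each is a thin script over the library; outputs
land in `results/`):

```bash
python analysis/01_simulate.py          # synthetic inputs + planted truth
python analysis/02_select_trends.py
python analysis/03_cpg_islands.py
python analysis/04_call_methylation.py
python analysis/05_mirna.py
python analysis/06_ihc_qscore.py
```

With the default seed this prints, among other lines:

```
50 markers selected of 1000 genes
planted-truth recovery: sensitivity 1.000, FDR 0.000
sim_promoter: 900 nt, 149 CpG sites, 1 island(s) [(236, 670)]
3600/3600 reads pass the 80% score filter (100.0%)
sim_hyper: NAT 9.1% | AD 35.4% (hypermethylated) | CRC 75.7% (hypermethylated)
sim_flat: NAT 51.9% | AD 49.7% (unchanged) | CRC 49.0% (unchanged)
upregulated (p < 0.01 vs NAT): ['miR-181c', 'miR-21']
NAT: Q-score 248.2 ± 34.3 (n=10)
trend along NAT→AD→CRC: decreasing
```

Reading: all 50 planted trend genes are recovered with no false selections;
the constructed promoter yields one CpG island spanning its GC-rich core;
the assay planted to hypermethylate along the sequence is called
hypermethylated in both lesion groups (9 → 35 → 76 %) while the flat control
assay stays unchanged; both planted miRNAs are detected after normalization;
and the simulated SFRP1-like protein signal decreases monotonically.

The same stages are available as a CLI (`amplimeth simulate`,
`select-trends`, `cpg-islands`, `align`, `call-methylation`,
`compare-methylation`, `cluster`, `mirna`, `qscore`, `run-all`) driven by a
YAML configuration; `run-all` writes a deterministic report bundle
(`summary.json`, per-stage TSVs, `run_log.txt`) for a given seed.

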