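# ptmdyn

Temporal classification and crosstalk analysis of SILAC-quantified
posttranslational modification (PTM) sites in stimulated macrophages.

Innate-immune stimulation (e.g. LPS via TLR4) rewires macrophage signaling
within minutes through acetylation, phosphorylation and ubiquitination.
Three-channel SILAC proteomics captures this as per-site ratios at two
time points — log2(M/L) at 0.5 h and log2(H/L) at 2 h, in three biological
replicates — across three PTM proteomes plus a whole-cell proteome (WCP),
optionally with a proteasome-inhibitor (MG132) arm. `ptmdyn` is for
computational proteomics people who have such site tables (MaxQuant-style)
and want the downstream analysis as a tested, scriptable library:

* **Site processing** — localization-probability filtering (≥ 0.9),
  replicate aggregation on the log2 scale, 2-fold regulation calls
  (|mean log2| ≥ 1 at either time point), pairwise-complete replicate
  correlation QC.
* **Six temporal classes** — *fast* (changed by 0.5 h) vs *slow* (only by
  2 h); fast split into *lasting* vs *transient*; each split into *up* vs
  *down*. Assigned twice: by explicit rules and by fuzzy c-means
  (Bezdek iteration, fuzzifier m = 2) on standardized trajectory shapes
  with sites assigned only at membership > 0.6 — and the two routes
  reconciled.
* **Crosstalk** — synchronous (all regulated sites one speed) vs
  heterochronous proteins, within-protein sequence distances by pair set,
  interaction degree in a confidence-filtered (> 0.8) edge list, and the
  fast×slow co-occurrence matrix across PTM types and the WCP.
* **Ubiquitination outcomes** — chain-linkage abundance (K6…K63) from
  diGly sites folded into the 76-residue ubiquitin moiety
  (((pos − 1) mod 76) + 1), MG132-effect flagging (log2 M/L ≥ 1 in both
  arms), and degradative vs non-degradative calls: non-degradative iff the
  MG132-arm ubiquitinome change and the untreated protein-level change
  agree in sign and magnitude (both |log2| ≥ 1), degradative otherwise —
  the inverse-proportionality signature of proteasomal turnover.
* **Motifs** — iceLogo-style differential flanking-residue statistics on
  −15..+15 windows: per (position, residue) two-proportion z-test of
  regulated vs unregulated sites of the same PTM type, p ≤ 0.05.
* **Synthetic data** — a generator that plants all of the above (temporal
  classes, protein groups, motifs, ubiquitination verdicts, linkage
  fractions, degree structure) with byte-identical regeneration per seed,
  plus per-stage truth evaluation.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
from ptmdyn import RunConfig, run_pipeline, truth_evaluation

result = run_pipeline(
    RunConfig(outdir="scratch/example_full", seed=1, synthetic={"n_proteins": 200})
)
print(result.summary["protein_groups"])
report = truth_evaluation(
    {
        "site_class": {c.key: c.six_class_label for c in result.classifications},
        "protein_group": {s.accession: s.group for s in result.protein_summaries},
        "ub_verdict": {o.key: o.verdict for o in result.ub_outcomes},
    },
    result.truth,
)
for stage, info in report.items():
    print(f"{stage}: accuracy {info['accuracy']:.3f} over {info['n']} items")
```

prints

```
{'unregulated': 167, 'single': 65, 'syn': 10, 'hetero': 9}
site_class: accuracy 0.996 over 746 items
protein_group: accuracy 0.984 over 251 items
ub_verdict: accuracy 0.983 over 60 items
```

i.e. of 251 proteins with quantified PTM sites most carry no regulated
site, 65 carry exactly one, and the multi-regulated remainder split into
synchronous and heterochronous; at the default noise level (sd 0.1 against
the |log2| = 1 threshold) the pipeline recovers 99.6% of planted temporal
classes, 98.4% of protein groups and 98.3% of planted
degradative/non-degradative verdicts. The `examples/` directory has one
short script per capability (temporal classes, crosstalk, ubiquitination,
motifs, full pipeline), each printing the numbers it computes and what
they mean. A thin CLI mirrors the library:
`ptmdyn simulate`, `ptmdyn run --config cfg.yaml`, `ptmdyn evaluate`.

Real data enter as tab-separated site tables (columns `accession`,
`position`, `residue`, `loc_prob`, `log2_ML_rep1..n`, `log2_HL_rep1..n`,
`intensity`, `condition`), a FASTA of protein sequences, and a three-column
interaction edge list; `docs/methods.md` documents the MaxQuant column
mapping.

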