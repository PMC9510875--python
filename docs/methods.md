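# Methods

`ptmdyn` analyzes SILAC time-course PTM proteomics of stimulated
macrophages: three-channel labeling (L = 0 h, M = 0.5 h, H = 2 h) gives
per-site log2(M/L) and log2(H/L) ratios in three biological replicates,
for an acetylome, phosphoproteome and ubiquitinome plus a whole-cell
proteome (WCP), optionally with a paired proteasome-inhibitor (MG132) arm.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not show.

## Site processing and regulation calls

Rows with MaxQuant-style localization probability < 0.9 are removed
(strictly less than; WCP rows carry no localization and always pass).
Replicates are averaged on the log2 scale; a time point quantified in fewer
than `min_replicates = 2` of 3 replicates is marked unquantified rather
than zero-filled. A site is *regulated* at a time point iff
|mean log2 ratio| ≥ log2(fold) with `fold = 2` — the threshold is
inclusive, reading "at least a 2-fold change" literally — and regulated
overall if regulated at either time point. A protein is regulated iff at
least one of its PTM sites is. Averaging is over log2 ratios, not raw
ratios: the geometric-mean convention standard for ratio data.

Replicate QC is the pairwise-complete Pearson correlation matrix between
replicate columns of one channel; pairs sharing fewer than 3 quantified
sites are reported unavailable. Under the additive error model
replicate = signal + noise with Var(signal) = σ_s², Var(noise) = σ_n²,
the expected pairwise correlation is σ_s²/(σ_s² + σ_n²), which the test
suite checks at σ_s = 1, σ_n = 0.5 (r = 0.8).

## Six temporal classes

Regulated sites are classified on three axes:

* **speed** — *fast* if regulated already at 0.5 h, else *slow* (regulated
  only at 2 h);
* **persistence** (fast sites only) — *lasting* if still regulated at 2 h
  with the same sign, else *transient*;
* **direction** — sign of the mean at the defining time point (0.5 h for
  fast, 2 h for slow).

This yields six classes: slow-up, slow-down, fast-lasting-up/down,
fast-transient-up/down. Degenerate inputs are resolved deterministically
and flagged: a fast site whose 2 h change reverses sign is labeled
fast-transient by its 0.5 h direction with `conflict_flag`; a site
quantified at a single time point is labeled from that point alone
(fast-transient-\* from 0.5 h, slow-\* from 2 h) with `conflict_flag` and
is excluded from clustering.

### Fuzzy c-means route

Independently, regulated sites quantified at both time points are clustered
by fuzzy c-means (Bezdek alternating optimization, implemented here, not
wrapped): memberships u_ik = 1 / Σ_j (d_ik/d_ij)^(2/(m−1)), centers
v_k = Σ_i u_ik^m x_i / Σ_i u_ik^m, fuzzifier m = 2, tolerance 1e-6 on the
max center shift, max 300 iterations, k-means++-style seeding from a seeded
generator (deterministic given the seed). Before clustering each site's
trajectory (0, mean_0.5h, mean_2h) is standardized across its three time
points to zero mean and unit sd (the Mfuzz convention), so clustering acts
on trajectory *shape*, not magnitude; a flat trajectory maps to the zero
vector. A site is assigned to its argmax cluster only when the membership
strictly exceeds 0.6, else left unassigned. A point coinciding exactly with
a center receives membership 1 there (the standard zero-distance
tie-break).

Clusters are given six-class names by rule-classifying their centers.
Per-site standardization has no single inverse, so the center is pulled
back to raw ratio space as the membership^m-weighted mean of the member
profiles' raw (0.5 h, 2 h) means — in the noiseless limit this is the
member-mean profile, and labels need not be unique across clusters. A
center whose raw trajectory falls below the fold threshold is reported
unlabeled. The package computes both routes and reports their agreement
rather than privileging either; c is fixed at 6 by design.

## Protein-level crosstalk

Proteins with ≥ 2 regulated sites are *synchronous* (syn) when all
regulated sites share one speed group and *heterochronous* (hetero)
otherwise; only the speed axis is compared, never direction or
persistence. One regulated site → *single*; none → *unregulated*.
`multi_type` flags ≥ 2 distinct PTM types among the regulated sites.

Sequence distances |pos_i − pos_j| are computed over pair sets chosen by
group: all regulated pairs for syn proteins; same-speed ("hetero-s") and
cross-speed ("hetero-h") pairs separately for hetero proteins; all
quantified-site pairs for unregulated proteins. Each protein contributes
the mean of its eligible pairwise distances, and these per-protein means
are pooled into group distributions (the per-protein statistic is a
package choice; a distribution plot does not pin one down). Interaction
degree is the distinct-partner count in the edge list after de-duplication
(unordered pairs collapse to max score) and strict score filtering
(> 0.8, matching a STRING-style confidence cut). The fast/slow
co-occurrence matrix counts, per cell (X, Y), proteins carrying ≥ 1
fast-class site of PTM type X and ≥ 1 slow-class site of type Y; the WCP
enters as a pseudo-type via protein-level fast/slow regulation of the
whole-cell ratios under the same rules.

## Ubiquitination outcomes

**Chain linkages.** DiGly sites on polyubiquitin precursors are folded into
the 76-residue moiety by pos_moiety = ((pos − 1) mod 76) + 1; intensities
are summed per canonical chain-forming lysine (K6, K11, K27, K29, K33,
K48, K63) and normalized to fractions. Ribosomal-fusion precursors map
only positions within the single N-terminal moiety. Intensity landing on a
non-canonical moiety position is routed to an "other" bucket and counted,
never silently dropped. M1 (linear) chains are out of scope: an N-terminal
GG remnant is not observable by the K-ε-GG enrichment workflow.

**MG132 effect.** A site is dramatically affected by MG132 iff
log2(M/L) ≥ 1 in both the untreated and the MG132 run — implemented
one-sided exactly as published, with a two-sided variant behind a flag.
Which SILAC channel carries the compared ratio is an explicit
configuration key (`ub_channel`), not an assumption.

**Degradative vs non-degradative.** For a site with a quantified MG132-arm
ubiquitinome ratio u and untreated WCP ratio w of its protein:
|u| < 1 → unclassified; else *non-degradative* iff sign(w) = sign(u) and
|w| ≥ 1 ("same changes" read as same direction and both substantial);
otherwise *degradative*. The inverse-proportionality hypothesis motivates
the else-branch: degradative ubiquitination drives turnover, so blocking
the proteasome accumulates conjugates while the untreated protein level
falls — and a *stable* protein (|w| < 1) with strongly rising
ubiquitination under MG132 is likewise called degradative, since the
conjugates it accumulates were evidently being removed. A missing WCP
ratio yields unclassified with a `missing_wcp` flag. The call is invariant
to a simultaneous sign flip of both inputs.

## Differential motif statistics

For each quantified site a −15..+15 window (31 residues, site at
position 0) is cut from the protein sequence, padding positions beyond the
termini; padding is excluded from every denominator (the iceLogo
convention). Per (position, residue) cell, the frequency among regulated
sites is compared with unregulated sites *of the same PTM type* by a
two-proportion z-test on the pooled variance (statsmodels'
`proportions_ztest`; a cell with pooled frequency 0 or 1 gets p = 1).
Cells with p ≤ 0.05 are significant; no multiple-testing correction is
applied by default, matching the plain per-cell α, with a
Benjamini–Hochberg switch available. Position 0 is reported but flagged —
its composition is constrained by the modified residue (S/T/Y for
phosphosites, K for acetylation/ubiquitination; mismatches between window
center and recorded residue are counted as validation warnings, not
dropped). Ubiquitin precursors are excluded from the window sets: their
repeated moiety would contribute pseudo-replicated flanks that distort the
background composition.

## Synthetic data: what it emulates and what it does not

The generator plants truth for every downstream stage. Regulated sites
follow the six class templates — (0, ±e), (±e, ±e), (±e, 0) with effect
size e drawn from `effect_log2_range` (default fixed at 2.0, i.e. twice
the regulation threshold on the log2 scale) — plus i.i.d. Gaussian
replicate noise (`noise_sd`, default 0.1; Gaussian on log2 ratios is the
standard SILAC error model). Each replicate is independently missing with
probability 0.1 to exercise the min-replicates logic, and 5% of rows get a
sub-threshold localization probability to exercise filtering. Protein
groups follow a mostly-unregulated mix (67.4% unregulated / 19.3% single /
remainder split syn:hetero ≈ 41:59 — echoing the qualitative structure of
a stimulated-macrophage proteome without claiming its exact percentages);
syn proteins carry clustered same-speed sites (gaps ~ U[5, 30] aa) and
hetero proteins far-apart cross-speed sites (gaps ~ U[100, 300] aa).
A motif residue (default P at +1 by regulated phosphosites) is planted at
40% enrichment over the 5% uniform-sequence background. Degradative and
non-degradative ubiquitination sites (50/50 by default, 60 sites) live on
dedicated proteins with mutually consistent MG132-arm ubiquitinome and
untreated WCP tables. A synthetic polyubiquitin precursor (4 moiety
repeats; a labelled stand-in sequence with lysines at the seven chain
positions) carries GG-site intensities following configurable linkage
fractions, K48-dominant (0.6) then K63 (0.3) by default. Interaction edges
are drawn with planted mean degrees 8/5/3/1 for hetero/syn/single/
unregulated and confidence scores above 0.8, plus 100 sub-threshold decoy
edges. Regeneration with the same seed is byte-identical.

What passing on this data does **not** show: the generator has no
peptide-level structure (no shared/razor peptides, no multiplicity
columns), no intensity-dependent missingness or variance, no ratio
compression or normalization artifacts, uniform random sequences rather
than real proteome composition, and noise-free site positions. Recovery
rates on it are upper bounds on real-data behavior, useful for verifying
the *logic* of the pipeline, not its field performance.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale by choice:
6 × 200 sites for the class-recovery benchmark, 350-protein proteomes for
pipeline-level checks, 100 planted ubiquitination outcomes, 500 windows
per set for the motif null, 2,000 sites for the correlation closed form.
Stochastic checks fix their seeds and use bands derived a priori
(3 binomial standard errors for the motif type-I rate; ±0.03 sampling
error for the correlation closed form). FCM convergence is max center
shift < 1e-6; membership row sums are checked to 1e-9; linkage fractions
sum to 1 within 1e-9.

## Input dialect and MaxQuant mapping

Tables are tab-separated UTF-8 with '.' decimals and columns `accession`,
`position`, `residue`, `loc_prob`, `log2_ML_rep{1..n}`, `log2_HL_rep{1..n}`,
`intensity`, `condition` (+ optional `cell_line`); missing ratios are `NA`
or empty, and positions are 1-based in the FASTA sequence. To convert a
MaxQuant sites table: take `Protein` (leading razor accession),
`Position`, `Amino acid`, `Localization prob`, log2 of the normalized
`Ratio M/L` / `Ratio H/L` per experiment as the replicate columns, and
`Intensity`. MaxQuant's multiplicity (`___1/2/3`) columns are out of
scope: collapse to one row per site (e.g. keep the highest-intensity
multiplicity) before import. Each row must carry a single unambiguous
accession.

## Known limitations

* The pipeline consumes site-level tables; protein inference, ratio
  normalization and peptide evidence are upstream concerns.
* Classification uses hard thresholds; sites near |log2| = 1 flip class
  under small noise, which is why the benchmark's planted effect sits at
  twice the threshold.
* The FCM route fits one model over all PTM types jointly; per-type
  clustering would need stratified calls by the caller.
* Degradative calls assume protein-level changes within the 2 h window are
  dominated by turnover rather than synthesis (short-stimulation premise).
* The co-occurrence matrix counts proteins, not site pairs, so a protein
  with many fast sites of one type still contributes 1 per cell.
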