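# Methods

This note documents the statistical procedures implemented in `xconcord`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic benchmarks do and do not establish.

## Quantification and gating

Transcript expression is RPKM, `10^9·C/(L·N)`: reads `C` on a transcript of
length `L` bp in a library of `N` total aligned reads. The expression gate
is **RPKM ≥ 2**, inclusive — a transcript exactly at the threshold counts as
expressed, since boundary values are treated as signal. Presence/absence
calls use the gate with no pseudocount; fold and log operations add a
pseudocount ε (default **1.0 RPKM**, configurable) so on/off transcripts —
which are reported separately by the presence screen — do not produce
infinite folds.

Size factors are median-of-ratios: sample *j*'s factor is the median over
transcripts of `count_ij / geomean_i`, where the geometric-mean reference
uses only transcripts observed in every sample (the standard convention; a
matrix with no all-positive row is rejected). Base mean is the mean of
size-factor-normalized counts; the expression requirement on base means is
**strictly greater than 10**.

## Differential expression without replicates (fish arm)

The design has one sample per tumor group and a pooled precursor-lesion
sample, so within-condition variance cannot be estimated per condition. All
samples are instead pooled into one blind pseudo-condition under the
assumption that most genes behave the same across conditions; genuine
between-group differences then inflate the fitted variance, which errs on
the conservative side.

The mean–variance relation is `v(m) = m + α·m²` on the normalized-count
scale. α is fitted by method of moments: for each gene with normalized mean
m ≥ 10, the cross-sample variance w of normalized counts has expectation
`m·ξ + α·m²` with `ξ = mean(1/s_j)`, and `m² − w/n` is the unbiased moment
for the squared true mean, so `(w − m·ξ)/(m² − w/n)` estimates α gene-wise.
These ratios are averaged (equivalently, a weighted least-squares regression
of `w − m·ξ` on `m²` with `1/m⁴` weights — the correct weighting since the
sampling variance of w scales with m⁴) and clipped at zero. Unweighted OLS
through the origin is dominated by a handful of high-expression genes under
a log-normal baseline and is several-fold noisier; the weighted form
recovers α within ±0.01 at 2,000 genes in the benchmarks.

The test is conditional: under independent NB models for the two conditions
with common normalized mean `q̂ = K/(S_A+S_B)` (condition totals modeled as
`mean = S·q̂`, `variance = q̂·Σs_j + α·q̂²·Σs_j²`), the p-value sums the
probabilities of all splits of the total K no more likely than the observed
one, divided by the total mass at K. `K = 0` returns p = 1 by convention.
Term probabilities are accumulated in sorted order so the p-value is
bit-identical under exchanging the two conditions. When `v ≤ m` the NB
degenerates to Poisson.

Calling rules: `|log2FC| > 2` (log base 2 throughout; the logFC is computed
on ε-shifted normalized group means, ε = 1 count), maximum group base mean
`> 10`, and `p < 0.05` for grouped contrasts (`fc_and_p` mode). Single-sample
contrasts use the fold-only mode, and a calibration warning is logged when
p-values are requested for them. No multiple-testing correction enters the
calls; a Benjamini–Hochberg q column is emitted for information only.

## Microarray arm (human)

Intensities are quantile-normalized: each sample's sorted vector is replaced
by the across-sample mean of sorted vectors, preserving within-sample ranks;
tied values receive the average of the normalized values over their tied
ranks (deterministic, standard). The moderated t-test shrinks each gene's
pooled two-group variance `s²_g` (d_g = n₁+n₂−2 df) toward a prior:
`s̃² = (d₀s₀² + d_g s²)/(d₀+d_g)`, `t̃ = Δmean/(s̃·√(1/n₁+1/n₂))`, p from a
t distribution on `d₀+d_g` df. The hyperparameters (d₀, s₀²) come from
moment matching on `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`: the excess of
`var(e)` over `ψ′(d_g/2)` identifies `ψ′(d₀/2)` (trigamma inverse by Newton
iteration); a non-positive excess gives `d₀ = ∞` and total shrinkage to s₀².
Calls: linear fold change `> 2` (equivalently `|log2FC| > 1`; the scale was
an open choice and is exposed as a threshold) and `p < 0.05`, both strict.
Probe-level matrices can be collapsed per symbol by maximal mean intensity
(default) or by averaging.

## Isoform-switch statistic

For genes annotated with ≥ 2 transcript isoforms, per-group RPKM profiles
(samples averaged within groups, group order HP, XE, MM, UM) are correlated
— Pearson by default, Spearman via config — against the gene-mean profile
over expressed transcripts. `RC = max(r) − min(r)` lies in [0, 2];
`RC > 1` ⇔ *differential* isoform regulation. The four-way partition is
exhaustive: *not expressed* (no transcript passes the gate anywhere
considered), *single transcript* (exactly one passes), *differential*, *same
direction* (including genes whose RC is undefined because fewer than two
correlations are computable). Zero-variance profiles yield undefined
correlations and are dropped rather than assigned 0. Whether "expressed"
is assessed over all groups or tumor groups only is configurable
(`any_group` default — the underlying exclusion rule is ambiguous about the
precursor lesion); transcripts failing the gate are by default excluded from
both the correlation set and the gene mean, with a flag to keep them in the
mean only.

With only four group points RC is intrinsically noisy: at the study-default
count noise (α = 0.1, moderate expression) the partition is computable but
planted switches are recovered with sensitivity near 0.55 and substantial
false-discovery among *differential* calls. The benchmark regime for the
statistic (`switch_study_config`) therefore uses high expression and small
dispersion so that count noise is at most ~10 % of the group-profile signal,
where sensitivity and specificity both exceed 0.95. Conclusions about real
four-point designs should carry the same caveat.

## Cross-species join and signatures

Fish genes map to at most one human symbol through the ortholog table; one
human symbol may own several fish paralogs (teleost genome duplication).
Symbols are upper-cased at read time on both sides. Paralog collapse
policies: `any_call` (default — a human symbol is "up in fish" if any
paralog is called up and none down; conflicting directions fall back to the
strongest-|logFC| paralog), `max_fold`, `best_p`. Conserved signatures are
the symbols called in the same direction in both species (`common_up`,
`common_down`); the remaining join statuses (`discordant`, `fish_only`,
`human_only`, `neither`) partition the table. Motif overlaps count signature
symbols whose linear fold exceeds the threshold (strict) in the required
direction in **all** supplied tumor-vs-HP contrasts; the zebrafish-style
comparison uses the **any**-contrast quantifier instead.
Over-representation is the upper-tail hypergeometric probability with
expectation `n·K/N`.

## Synthetic-data generator

One master seed drives named substreams (structure, profiles, fish counts,
human arrays), so equal seeds give byte-identical files. Defaults mirror the
study design: four fish groups with one sample each, HP a pool of five
virtual siblings (independent draws summed — pooling raises HP's library
size ~5× and lowers its effective dispersion to α/5), NB dispersion α = 0.1,
log-normal baseline (ln-mean 5, ln-σ 1; median ≈ 150 normalized counts),
transcript lengths uniform on 500–5000 bp, 100 genes planted 8-fold up and
100 down in all tumors with half of each conserved in the human arm
(Δ = 3 log2 units, Gaussian noise σ = 0.5 on 18 + 19 arrays), 100 switch
genes, 10 % paralog pairs, isoform mix 60/30/10 % for 1/2/3 isoforms.

Switch genes get two isoforms with the second an affine decreasing function
of the first (`t₂ = a·t₁ + b`, `a ∈ (−0.7, −0.3)`, b keeping t₂ positive),
which makes the two correlations to the gene mean exactly +1 and −1 — RC = 2
before count noise. Per-(gene,group) biological multipliers
(`2^N(0, σ_g)`) are off by default, matching the plain planted-fold model;
the switch benchmark sets `σ_g = 1` so non-switch genes have structured
profiles against which proportional isoforms correlate.

Two derived configurations are fixed in code: `null_config` (no planted
effects, no pooling, no group variation, one isoform per gene) for
calibration and dispersion recovery — single-isoform because summing
isoforms dilutes the per-transcript dispersion by E[Σf²] ≈ 0.8 and the
recovery experiment targets the dispersion parameter itself; and
`switch_study_config` (α = 0.005, ln-mean 8, group σ = 1) for the
low-noise RC regime described above.

What the generator does **not** emulate: read-level error, mappability and
positional bias, correlated genes, batch effects, probe sequence effects,
annotation errors. Passing benchmarks therefore demonstrate correctness and
calibration of the statistics under their own model assumptions, not
robustness to real-data artifacts.

## Problem sizes and numerics

Benchmarks use 1,600–2,000 genes (5,000 for array calibration), sizes at
which every reported quantity is stable across seeds; the whole acceptance
computation takes seconds. Numerical conventions: p-values clipped into
(0, 1]; NB↔Poisson switch at `v ≤ m(1+10⁻¹²)`; tie tolerance `10⁻¹⁰` on log
probabilities when summing the conditional tail; floats serialized at 12
significant digits so tables round-trip; trigamma inverse by Newton with
closed-form endpoints for extreme arguments.

## Known limitations

* The no-replicate NB test inherits every caveat of blind variance
  estimation: with planted (or real) group structure the fitted α absorbs
  it, making single-sample p-values conservative but not calibrated.
* RC over four group means cannot distinguish isoform switching from
  correlated noise at moderate dispersion (see above).
* The paralog collapse policies are heuristics; with deeply duplicated
  genomes a resolved orthology graph would be preferable.
* The human arm assumes summarized, probe- or gene-level intensities;
  CEL-level preprocessing is out of scope.
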