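# Methods

## Measurement model and normalization

A two-color m6A epitranscriptomic array measures, per probe and sample, two
fluorescence intensities: Cy5 for the immunoprecipitated (m6A-modified) RNA
fraction and Cy3 for the unmodified supernatant. Writing `E` for a gene's
underlying transcript abundance and `f ∈ (0,1)` for its modified fraction,
the idealized signals are `Cy5 ∝ E·f` and `Cy3 ∝ E·(1−f)`, each subject to a
per-sample per-channel multiplicative scale (labeling efficiency, scanner
gain) and multiplicative measurement noise.

Normalization uses the spike-in controls — exogenous RNAs added in equal
amount to both labeling reactions of every sample. For channel `c` of sample
`s`, with `m_{s,c}` the mean log2 spike-in intensity of that channel, each
probe is transformed as

    x̃ = log2(x + pseudocount) − m_{s,c} + G .

`G` is an anchor constant whose default is the grand mean of spike-in log2
intensities over all samples and channels of the run. The anchor is
cosmetic: it keeps normalized values on an intensity-like scale and cancels
in the m6A percentage and every fold change. Because the default anchor is
data-derived, rescaling a whole channel shifts all normalized values by a
common constant while leaving every anchor-free quantity untouched; callers
who need the normalized values themselves to be rescaling-invariant can pass
a fixed `anchor`.

With the spike-ins present in both channels at equal true amounts, `m_{s,c}`
absorbs the channel scale exactly, so all downstream quantities are
invariant to per-sample per-channel multiplicative bias (exactly so at
pseudocount 0; the default pseudocount 1.0 guards zero intensities at the
cost of a negligible bias for intensities ≫ 1).

## Quantification

From normalized linear intensities (`2^x̃`), per gene and sample:

- m6A percentage: `100 · Cy5 / (Cy5 + Cy3)` — the only dimensionless
  percentage constructible from the two channels, adopted as the canonical
  "methylation level";
- expression: the total `Cy5 + Cy3`.

Probes collapse to one representative per gene (Entrez ID): the probe with
the highest mean expression across samples, ties broken by smallest probe
ID. This is deterministic and favors well-measured probes. Probes without a
gene ID are dropped and counted.

## Differential calling without replicates

The design has one pooled array per condition, so there is no
within-condition variance to estimate: no p-values are produced and the fold
change `FC = test/ref` is the sole evidence. Calls are trichotomous per
axis — up/hyper when FC ≥ 1.5, down/hypo when FC ≤ 0.67, otherwise
unchanged. Both cut-offs, and whether the comparison is inclusive, are
configurable; the defaults follow the field's convention of quoting 0.67
(not exactly 1/1.5), which makes up- and down-calls slightly asymmetric — a
documented property, with `down_threshold=1/1.5` available for exact mirror
symmetry. The methylation fold change is computed on the m6A percentage by
default; a `modified_channel` basis (normalized Cy5) is provided because
vendor pipelines differ on this point.

Summary percentages are rounded half-away-from-zero at a caller-chosen
number of decimals, so printed counts reproduce exactly (e.g. 7,605 of
42,655 → 17.8%).

## Joint statistics

- **Cross-tabulation**: each contrast's genes partition into a 3×3 table of
  methylation class × expression class, with per-cell gene lists and
  marginal totals.
- **Reversal screen** over two ordered contrasts A then B (stress effect,
  then intervention effect): `up_then_down = {g : up in A ∧ down in B}` and
  its three analogues, plus the stricter "expression stable but m6A
  reversed" set — expression unchanged in B with methylation classes
  strictly opposite between A and B. The strict definition is used because
  it is exactly testable against planted truth; genes missing from one
  contrast are dropped, not imputed.
- **Clustering** for heatmap row order: agglomerative, Euclidean distance,
  average linkage, via scipy's deterministic implementation (zero-distance
  rows merge first; tie-breaking is scipy's fixed order).

## Enrichment

Classic over-representation: for a query of `n` genes from a universe of
`N`, and a set covering `K` universe genes with overlap `k`, the p-value is
the hypergeometric upper tail `P(X ≥ k)` (one-sided Fisher exact test),
computed with scipy. Set members and queries are intersected with the
universe first; the default universe is all genes surviving probe collapse.
Benjamini–Hochberg adjusted values (statsmodels) are reported alongside raw
p-values; raw p remains primary in this replicate-free setting. GO-graph
decorrelation algorithms are out of scope — sets are treated as flat lists.

## Synthetic data generator

The generator emulates the three-condition pooled design (WT, stressed sham,
stressed+DBS; one array each) on an array of `n_genes` gene probes plus
`n_spikeins` spike-ins. Per gene: baseline abundance `2^Normal(10, 1.5)`
(arbitrary units), modified fraction `Beta(4, 2)` — right-shifted because
brain-tissue m6A levels run high. Planted effects multiply expression or the
modified fraction by `2^±effect_log2fc` (default 2) cumulatively along the
condition chain; effect genes are drawn by seeded permutation,
independently for the expression and methylation axes, with default
per-contrast fractions matching the proportions the study design reports
(first contrast: 5.5%/16.4% up/down, 17.6%/0.2% hyper/hypo; second:
12.6%/4.2% up/down, 1.6%/0.9% hyper/hypo). For hyper-planted genes the
baseline fraction is pre-scaled so the maximal cumulative multiplier keeps
the true fraction ≤ 0.95 — planted fold changes stay exact and the
unmodified channel stays positive. Channel noise is log-normal
(`Normal(0, noise_sd=0.1)` on log2, independent per channel), the standard
two-color error model; per-sample per-channel scale biases default to
seeded draws from `2^Uniform(−0.5, 0.5)` so normalization is exercised.
Spike-in true intensities form a fixed geometric ladder (log2 levels 8–14),
identical across samples and channels. Randomness derives from a single
root seed via numpy `SeedSequence` substreams (gene-level stream + one per
sample), so datasets are byte-reproducible.

What the generator does **not** emulate: probe-level sequence effects,
intensity-dependent (loess-type) dye bias, background/saturation artifacts,
correlated noise between channels, or biological co-regulation among genes.
Passing tests therefore demonstrate correctness of the computational
pipeline under the stated error model, not robustness to every artifact of
real arrays.

## Numerical and design choices

- Pseudocount default 1.0 before any log2; 0 gives exact scale invariance
  when no zeros occur (always true for simulated data).
- Fold-change `epsilon` defaults to 0 — quantified values are already
  pseudocount-guarded upstream.
- Percentage rounding is decimal half-away-from-zero, not banker's
  rounding, to match how such results are conventionally printed.
- Test and acceptance problem sizes: 800-gene noiseless simulations for
  unit/property tests, 5,000 genes for the recovery study, enumeration
  oracle up to universe size 12 — sizes at which exhaustive checks are
  exact and the full suite runs in seconds.
- Degenerate inputs: < 2 spike-ins, zero intensities at pseudocount 0,
  both-channel-zero percentages, non-positive fold changes, empty
  post-filter queries and empty contrast intersections all raise typed
  errors naming the offending field or path.

## Known limitations

Without replicates the fold-change calls have no error control; the planted
recovery rates quantify performance only under the generator's error model.
The probe-to-gene collapse and the universe definition (all collapsed genes
vs expressed-only) materially affect enrichment denominators and are left
configurable because vendor conventions are opaque. The 0.67 vs 1/1.5
asymmetry is preserved deliberately.
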