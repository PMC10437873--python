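# Methods

## Scope and model

`thermenz` analyses *annotation-level* outputs of a metagenomic survey; it
never runs assemblers or annotators. The object of interest is the
secreted fraction of a community's carbon-degrading enzyme repertoire,
profiled under three classification schemes: CAZy families (GH/GT/PL/CE/
AA/CBM prefixes), MEROPS peptidase families (catalytic-type letter +
number, e.g. M23), and EC numbers restricted to class 3 (hydrolases).

### Filtering rules

A gene's annotation enters the analysis only if

1. the gene carries a predicted signal peptide (secreted; all schemes);
2. for CAZy: both HMMER and DIAMOND support the call. A third caller
   counts toward `tool_support` but never satisfies the rule. MEROPS and
   EC calls come from a single annotator and are exempt;
3. for EC: the label starts `3.` (hydrolase). dbcan subfamily suffixes
   (GH13_20) are truncated to the family (GH13) at read time, since the
   substrate map and all downstream analyses operate on families.

### Abundance and normalisation

abundance(family, sample) = Σ over passing genes carrying that family of
the host contig's mean read depth, × 10⁹ / total assembly length.

The depth-per-gigabase scale is a package convention: no absolute unit is
recoverable from "normalised to assembly size" alone, and every
interpreted quantity (necromass fraction, ranks, correlations, ordination)
is invariant to it. Each gene on a contig contributes the contig's mean
depth independently (two genes on one contig contribute twice); a gene
with k family labels contributes to all k families with no fractional
splitting. Mean contig depth is the default coverage input; a per-base
depth table can be aggregated to means through an alternate reader.

The prevalence filter keeps families with abundance > 0 in at least
⌈min_frac · n_samples⌉ samples (default min_frac = 0.75); "present" means
strictly positive. The display transform log10(x + 0.5) is used for
heatmaps and as the default PCA input; correlations always use raw
abundances (Spearman is rank-based, so this choice cannot change ρ — the
test-suite asserts the resulting dendrograms are identical).

### Substrate groups and the necromass fraction

The packaged map assigns families to six substrate groups: chitin,
peptidoglycan, starch/glycogen, trehalose, xylan, cellulose. Supergroups:
cell = chitin ∪ peptidoglycan (microbial necromass), photosynthate =
xylan ∪ cellulose (plant/algal matter). Per sample,

necromass fraction f = cell / (cell + photo),

undefined (NaN, row retained) when both sums are zero. Design points:

- **Within-supergroup dedup.** A family in two member groups of one
  supergroup (GH5 in both xylan and cellulose) counts once there.
- **Cross-supergroup sharing.** GH5/GH7/GH8 sit in chitin *and* in
  xylan/cellulose. The default counts them in both supergroups, because
  the map lists them in both and no exclusion rule is stated; an
  `exclusive` mode (drop shared families from both) is available
  (`dedup=` argument / `--dedup` flag).
- **CAZy only by default.** The cell/photosynthate score sums CAZy
  families; MEROPS peptidoglycan families (M23 …) are profiled separately
  and can be pooled in via the `schemes` argument.
- Fractions are displayed to 2 decimals with round-half-even; all
  comparisons in code use the unrounded values.

### Ordination and tests

- Spearman ρ with average ranks (computed as Pearson on ranks, so a
  constant profile flags only its own pairs as undefined — these are an
  error for clustering, with advice to prevalence-filter first).
- Agglomerative clustering on d = 1 − ρ (not 1 − |ρ|: anti-correlated
  profiles should separate). Linkage is complete by default (configurable
  average/single). Labels are sorted before linkage so the tree is
  invariant to input order; ties break by label order. Trees export to
  Newick.
- PCA: covariance eigenstructure of centered (unscaled) sample vectors of
  log10(x + 0.5) abundances; sign fixed by making each component's
  largest-magnitude loading positive. Transform/centering/scaling are
  exposed as arguments.
- Kruskal–Wallis with tie correction; p from χ² with (groups − 1) d.f.;
  all-identical data returns H = 0, p = 1 rather than 0/0. No
  multiple-testing correction is applied across substrates (raw p-values
  are reported, matching how such screens are usually read with n = 8
  substrates).

### Assay rates

Slurry bookkeeping: 2.75 g wet sediment in 91 mL buffer; each well gets
0.8 mL slurry + 0.2 mL of 200 µM substrate. Sediment mass per well =
2.75 × 0.8/91 ≈ 0.0242 g (slurry volume contribution of the sediment is
neglected — no slurry density is available). Well volume for the mole
conversion is 1.0 mL; the 200 µL withdrawn per timepoint is assumed not to
change concentration.

rate = OLS-slope(fluorescence vs time) / cal.slope × V_well(L) / m_sed(g)

in µmol g_wet⁻¹ h⁻¹, per replicate, then averaged. OLS over all three
timepoints (not an endpoint difference) uses the 1.5 h reading and damps
single-timepoint noise. Adding a constant to all readings cannot change
the rate (intercepts cancel); negative rates are reported, never clipped.
Optional blank series are subtracted before regression. Fluid samples are
refused by default — the slurry protocol is defined for sediments.

## Synthetic-data generator

The generator emulates the *file formats and statistical structure* of a
survey, not sequences: per sample it writes a metadata row, a dbcan-style
overview table, a DRAM-style MEROPS/EC table, a SignalP-style summary, a
GFF3 gene map, a coverage table and assembly stats. All randomness flows
from one `numpy` generator; identical configs give byte-identical files.

Generative model per sample: province ~ categorical (default weights
roughly proportional to the survey's seven provinces); temperature and pH
uniform within province-specific ranges spanning the survey extremes;
fluid vs sediment Bernoulli(0.5). Contig lengths are log-normal
(µ = 8, σ = 1 in log-bp, ≥ 500 bp), depths gamma (shape 2, scale 15), and
genes per contig Poisson(3); all genes on a contig inherit its depth,
matching contig-level coverage. Each gene draws a scheme
(CAZY 0.45 / MEROPS 0.40 / EC 0.15), a secretion flag (p = 0.35), and for
CAZy two-tool support (p = 0.8).

Planted structure:

- **Composition.** Half of CAZy genes are substrate-group genes: cell
  with probability `cell_vs_photo_ratio` (default 0.70, the survey-scale
  value), photosynthate otherwise. The draw uses only supergroup-
  *exclusive* families: GH5/GH7/GH8 would add equal mass to both
  supergroups and make the planted fraction unidentifiable, so they are
  left out of the generator pools (the shared-family scoring paths are
  exercised by constructed matrices in the tests). Non-group genes draw
  from starch/trehalose plus 20 ungrouped background families.
- **Province effect.** In volcanic provinces, cellulose-group families
  are upweighted (default ×3) within the photosynthate draw — changing
  photosynthate *composition*, not the cell:photo balance.
- **Depauperation.** Samples above 80 °C keep each annotation with
  probability `hightemp_depauperation` (default 0.1). The keep decision is
  applied after all of a gene's draws so the random stream is identical
  across settings: lowering the parameter removes genes and can never
  reshuffle or add them (a coupled-monotone construction the tests rely
  on).

The generator records, gene by gene, the normalised cell/photosynthate
mass of exactly the genes that pass the default filters; this planted
truth is what the pipeline must reproduce (and does, exactly, since both
sides see the same genes — the informative check is that the *realized*
study-wide fraction sits near the configured ratio, which at ≥ 5000 genes
per sample it does within ±0.02).

What the generator does *not* emulate: real sequence content, annotation
errors and tool disagreement structure, compositional coupling between
schemes, spatial/geochemical covariates beyond province, temperature and
pH. Passing recovery tests therefore demonstrates correctness of the
bookkeeping and estimators, not robustness to real annotation noise.

Assay plates are simulated from the exact inverse of the rate formula
(linear expected fluorescence plus optional Gaussian noise, floored at 0);
noise-free plates recover the planted rate to machine precision.

## Problem sizes and numerics

Default synthetic studies use 16 single-sample sites with 400 contigs
(~1200 genes) per sample; recovery checks use ~5100 genes per sample over
6 sites, sizes at which the binomial error of the planted fraction is
well inside the ±0.02 recovery band. The Kruskal–Wallis null calibration
uses 1000 simulations of three groups of 10. Degenerate inputs are
handled explicitly: zero-coverage contigs are retained, all-zero samples
keep their columns, undefined fractions and correlations are flagged
rather than coerced, and constant assay series give rate 0.

## Known limitations

- The absolute abundance scale is conventional (depth per Gb); only
  scale-free quantities are comparable across studies.
- The substrate map is a fixed resource; families outside it are simply
  unscored (no inference of new assignments).
- The packaged survey score table is consumed as printed; its sums are
  reproduced from its own rows, not recomputed from raw reads.
- PCA province separation on synthetic data is a qualitative check of the
  planted effect, not a reproduction of any particular survey's
  coordinates.
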