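# Methods

This note documents the models and procedures glycopipe implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices behind the defaults.

## Site catalog

Glycosite localization rests exclusively on ETD spectra, because
electron-transfer dissociation preserves the glycan on its residue while HCD
does not. A peptide-relative position whose ptmRS-style localization
probability strictly exceeds `prob_cutoff` (default **95%**, the
community-standard confidence level) maps to protein coordinate
`pep_start + pos − 1` as an unambiguous site. Glycans a PSM carries but
cannot place (hexnac_count exceeding the number of confident positions)
become ambiguous sites whose coordinate is the span of the peptide's S/T/Y
residues; they are retained in the catalog — site catalogs typically report
~90% of sites as unambiguously assigned and the remainder as ranges — but
excluded from region mapping and patch detection by default, since those
need point coordinates. Duplicate (accession, position) entries merge with
summed PSM support; ambiguous sites merge on (accession, span).

Reporter-ion quantification uses the HCD spectrum acquired on the same
precursor as the highest-scoring ETD PSM of each glycopeptide (ties broken
by input order). "Highest quality" is operationalized as the search-engine
score column as given; no re-scoring is attempted. Glycopeptides without
any ETD PSM are excluded from quantification and signaled, not failed.

Site-level quantification is restricted to single-glycan glycopeptides. A
peptide observed with both one and several glycans is conservatively routed
to the peptide-level (multi-site) table: when the same sequence carries
variable numbers of glycans, reporter signal cannot be attributed to one
site.

## Region mapping

Five categories with a fixed precedence **domain > stem >
functional_region > terminus > linker**; a site matching several predicates
gets the most specific structural claim. The precedence is configurable.

* **domain** — inside an annotated structural-domain interval.
* **stem** — on the extracellular side of a type-I (N-terminal of the TM
  span) or type-II (C-terminal) membrane protein, within `stem_window`
  (default **50 aa**) of the nearest TM boundary residue; the distance is
  reported.
* **functional_region** — inside an annotated functional interval
  (cleavage regions, binding sites and similar).
* **terminus** — among the first `terminus_window` (default **10**)
  residues counted from the mature N-terminus (the residue after
  signal-peptide cleavage, else residue 1) or from the C-terminus.
* **linker** — strictly between two consecutive domains whose gap is
  < `linker_max` (default **100 aa**).

Domain statistics count instances per copy (a protein with three FN-III
domains contributes three), over catalog glycoproteins only. The
glycosylation rate of a domain type is occupied instances / total
instances. Within-domain site positions use the midpoint-offset rule
rel = (pos − start + 0.5)/length binned into ten deciles, which places the
first and last residues symmetrically into bins 1 and 10.

## Glycan patches

A patch is a maximal cluster satisfying: some window of `window` (default
**25**) consecutive residues contains ≥ `min_sites` (default **5**)
unambiguous sites. Implementation: only windows whose left edge sits on a
site are examined (any qualifying window can be slid right onto its first
member without loss); qualifying windows sharing at least one member merge
into one patch. Merging on shared membership rather than window overlap
prevents one dense cluster from being reported as many shifted windows.
Since windows are processed in left-edge order, transitive overlaps are
always adjacent overlaps, so a single pass suffices; the test suite checks
this implementation against an exhaustive enumerate-all-intervals,
union-find oracle. Patch extent is reported first-to-last member site —
window bounds are arbitrary to within an offset. Ranking is by member count
descending, ties by span ascending (denser first), then accession.

## Differential analysis

* **Normalization** — total-intensity: each channel scaled by one factor so
  every channel total equals the grand mean of the input totals. This is
  the standard correction for unequal TMT channel loading; it preserves
  within-channel structure exactly.
* **Protein-abundance correction** — sites are removed when their parent
  protein's abundance (from the non-enriched proteome channels) changed:
  median KO/WT fold change outside (0.5, 2) with BH-adjusted p < 0.05.
  Without this step, a drop in glycopeptide signal is not interpretable as
  a glycosylation change. Sites whose protein was never quantified are kept
  and flagged `protein-unquantified`.
* **Testing** — fold change is the ratio of replicate medians (robust for
  n = 3); significance is a two-sided equal-variance t-test on log2
  intensities (log2 stabilizes multiplicative noise; the median for the
  effect size and the mean inside the test are deliberately separate
  estimators). p-values are BH-adjusted across all sites tested in a
  contrast. Missing channels are excluded pairwise; fewer than two usable
  replicates in either condition makes a site `untested`, never an error.
  Zero-variance groups (exact simulations) resolve by the limit: equal
  means give p = 1, unequal p = 0.
* **Calls** — down: FC < 0.5 and adjusted p < 0.05; up: FC > 2 and
  adjusted p < 0.05. A raw-p mode (`use_raw_p`) thresholds the unadjusted
  p-value instead, for rank-plot-style displays; the adjusted-p rule is the
  default. Missing intensities are never imputed.
* **Isoform specificity** — a site down in exactly one knockout of the
  panel and not down in any other is isoform-specific; down in two or more
  is flagged shared.

## Occupancy

Peak acceptance: |mass error| < **1.5 ppm** and idotp > **0.85** (both
strict, matching the ">−1.5, <1.5" and ">0.85" conventions), |RT delta| <
**5 min**, identification score ≥ **200**; an isotopologue
relative-abundance cutoff (> 20) applies when that value is supplied.
Rejections carry reason codes, and filtering is idempotent.

Per region, charge states are summed within each glycoform, then per
replicate occupancy = ΣA(glycoforms) / (ΣA(glycoforms) + A(non-glyco)).
The record reports the mean and the sample standard deviation (ddof = 1)
over replicates, matching three-technical-replicate reporting such as
0.93 ± 0.01. If the non-glycosylated peptide is absent in *all* replicates
the region is flagged High (occupancy near-complete but not numerically
estimable — absence of detection is not a zero); absence in only some
replicates uses the detected ones and sets a partial-detection flag. The
xTn distribution is each glycoform's share of the glycoform-only total,
pooled over replicates; integer percentages use largest-remainder rounding
so they sum to 100, with unrounded values kept in the machine-readable
output.

Occupancy classes: high (> 0.75, High-flag records included), medium
(0.25–0.75], low [0.001–0.1], below-floor (< 0.001). The 0.1–0.25 interval
belongs to no conventional class and is reported separately as `gap`.

Cross-condition comparison matches records by identical peptide sequence
only, excludes High records (no numeric ratio), and reports an ordinary
least-squares slope, intercept and R²; fewer than three matched pairs is
flagged insufficient rather than fitted.

## Synthetic-data generator

The generator's defaults are the study conditions the analysis assumes:
wild type + nine knockouts (`n_conditions = 10`), **3 replicates** per
condition, multiplicative knockdown `effect_size = 0.1` on a targeted
site's channels, log-normal intensity noise with `cv_noise = 0.2`
(σ = √ln(1 + CV²), median-preserving so the noise-free fold change is exact),
8% of sites with localization probability below the 95% cutoff, and a true
occupancy mixture with mass 0.60 on (0.75, 1], 0.11 on (0.25, 0.75] and
0.29 on [0.001, 0.1] — roughly 60% highly occupied, 11% intermediate and
30% low, the split reported for secreted-protein glycosites. Clustered
sites (patch_fraction, default 0.15) are laid down in runs of ≥ 5 within
25 aa inside planted Ser/Thr-rich stretches; isolated sites are kept more
than 25 aa from every other site so they can never join a patch, making
the patch ground truth exact. One random stream per run is seeded once;
each stage derives its generator from the seed plus a fixed stage offset,
so adding a stage never perturbs another's draws, and all outputs are
bit-identical under a fixed configuration.

What it does *not* emulate: fragment spectra and isotope envelopes (PSMs
are generated at the table level), retention-time structure, interference
and ratio compression in reporter channels, peptide-level missingness
patterns, shared regulation of one site by several isoforms, or any
coupling between a protein's abundance change and its glycopeptide signal
(the abundance filter is exercised by independently labeled proteins).
Passing recovery tests therefore demonstrate the correctness of the
analysis logic under the stated noise model, not robustness to every
artifact of real TMT data.

MS1 decoy peaks violating exactly one peak-acceptance rule are labeled in
the ground truth with the violated filter, so filter tests can assert the
exact accept/reject partition.

## Numerical choices

* Report percentages use one-decimal half-up rounding (`percent_of`);
  banker's rounding would differ at exact .05 boundaries.
* Quant tables round-trip doubles exactly (`repr` on write,
  `float_precision="round_trip"` on read).
* BH adjustment delegates to statsmodels and is cross-checked in the tests
  against the hand-computed step-up recursion.
* Degenerate inputs: empty catalogs, empty acceptance sets, regions without
  glycoforms, all-missing quant rows and sub-3-pair regressions all return
  flagged empty/insufficient results instead of raising.

## Problem sizes

The test and acceptance simulations use 25–150 proteins and 80–1000 sites:
1000 sites for p-value-uniformity and FDR-rate checks (Kolmogorov–Smirnov
at α = 0.01 needs that resolution), 500 regions for occupancy class-mixture
recovery (binomial 3σ bounds), 400 sites / 200 targets for the
isoform-recovery power check, and 300–1000 random instances for the
patch-finder oracle. These sizes give the statistical assertions their
stated resolution while keeping the whole suite around ten seconds.

## Known limitations

* The stem category requires topology annotations; proteins annotated
  `other` never receive stem assignments even if they have a TM feature.
* Ambiguous sites are keyed by their S/T/Y span; two different unlocalized
  glycans on overlapping peptides with the same span are merged.
* The occupancy comparison assumes identical peptide sequences across
  conditions; missed-cleavage variants of the same region are not matched.
* Ionization-efficiency differences between glycoforms are not corrected;
  for single-HexNAc glycoforms the effect on occupancy is considered
  negligible, for elaborated wild-type glycans less so.
* No moderated-variance (limma-style) testing and no cross-plex batch
  correction; contrasts are assumed to come from one multiplexed design.
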