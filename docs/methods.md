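# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic data emulate, and the limits of what the
tests demonstrate.

## Mass and digestion conventions

Monoisotopic residue masses follow the standard table (sourced from
pyteomics); the proton is 1.007276466 Da and water 18.0105646 Da.
Carbamidomethylation of cysteine (+57.021464 Da) is the only default fixed
modification, matching routine alkylation; the residue table and fixed
modifications are overridable. Variable modifications are out of scope:
transition math only needs the fixed-modification mass ladder.

Digestion cuts C-terminal to K/R unless the next residue is proline — the
dominant trypsin convention; the enzyme is configurable (cut-after set,
suppressor set, missed cleavages 0–5, length bounds). Length filtering is
applied after missed-cleavage joining, so a short fragment can still
surface inside a longer joined peptide. Default bounds are 5–50 residues
with 0 missed cleavages for library digestion (the isoform library's
five-residue floor motivates the lower bound); 2 missed cleavages is the
usual search-engine setting and is one flag away. Isoleucine and leucine
are distinct residues by default; an I/L-equating comparison exists for
uniqueness checks because the two are isobaric and often indistinguishable.

## Consensus spectra and transition extraction

Cluster assignments are an input: clustering replicate DDA spectra is a
solved upstream problem and its p-value cutoff is treated as provenance.
Within a cluster, peaks from all members are pooled, sorted, and merged
greedily left-to-right whenever the next peak lies within 0.02 Da of the
running intensity-weighted centroid; merged intensity is the summed
intensity divided by the member count, so a peak present in every member
keeps its average height and singleton clusters pass through unchanged.
The representative retention time is the median member RT (robust to a
single outlier replicate).

One PSM per peptide group (sequence + charge) survives: the minimum
q-value, with ties broken by higher search score and then spectrum id so
output is fully deterministic; groups whose best q-value is not strictly
below 0.10 are dropped. Transition extraction enumerates all y/b ordinals
at fragment charges {1, 2} (charge set configurable — whether the original
extraction considered 2+ fragments is not documented, so both are kept by
default) and matches each theoretical m/z against the consensus peaks
within 1 ppm; the closest peak wins, ties go to the higher intensity. The
emitted row stores the theoretical product m/z (library convention) plus
the matched peak's intensity; all matched transitions are kept unless a
top-N cap is requested. Pseudo-reverse decoy generation is deliberately
not implemented; the `decoy` GTL column is emitted as 0.

## Retention-time calibration

Anchor-peptide selection applies four pure predicates per observation —
|ΔRT| ≤ 600 s (inclusive: "at most" ten minutes), base peak width
< 16.5 s (strict), apex intensity ≥ 1e5 (inclusive), and qualifying
detections in ≥ 20 runs. Counting *qualifying* observations toward the
run threshold (rather than any detection) is the stricter reading and the
default; a flag switches to any-detection counting. Binning splits the
configured gradient span into 20 equal-width, half-open bins on library RT
(last bin closed) and draws at most 100 peptides per bin uniformly with a
fixed seed.

The RT model is an L1-penalized polynomial (default degree 1, up to 3) on
a standardized basis, mapping library RT to observed RT. The penalty is
chosen by 5-fold cross-validation (shuffled folds, seeded) over a
logarithmic grid from 1e-7 to 10, with ties resolved toward the smaller
penalty so exact relationships are never shrunk. The lasso matters when
the basis is over-specified: a cubic fit on affine truth zeroes the excess
terms.

The iteration loop defines "identified" as a feature whose model-corrected
|ΔRT| is within the 600 s window. This isolates the selection logic from
any external peak scorer — the real pipeline's scorer sits outside this
package — so iteration counts here measure alignment quality, not search
sensitivity. Convergence is declared when the identified count changes by
less than 0.5 % between rounds, or after 5 rounds, mirroring the plateau
such loops show in practice. Runs too sparse to refit keep their previous
model. The protein count in the trace uses an optional peptide→protein
map and falls back to counting peptides when no map is supplied.

## Multi-library combination

Precedence is own-library first, then the unique quantifying library,
then the minimum p-value among externals (generalized to any number of
externals; exact p ties break on library id). The chosen library's
per-sample quantities are carried unchanged — reconciling quantities
across libraries is underdetermined and deliberately avoided.
Benjamini–Hochberg is used for q-values on the combined table; it stands
in for the original pipeline's semi-supervised rescoring, which needs real
score distributions, and is documented as such, not as a reproduction.

## Quant matrices and protein rollup

Median scaling divides each sample by its observed median (fixed point:
every scaled column has median 1). Row standardization is log2 → mean
center → divide by sample SD (ddof = 1); constant rows become zeros with a
warning rather than NaNs. The missingness filter keeps rows strictly
below 30 % missing.

Protein rollup reads "subgroup … correlated among them" as *pairwise*:
peptides are nodes, edges require Spearman ρ ≥ 0.7 on at least 6
pairwise-complete samples, and the largest clique of size ≥ 3 is selected
— exact maximal-clique enumeration up to 30 peptides, a degeneracy-ordered
greedy search beyond (cliques above that size are rare in practice; the
greedy path trades optimality for tractability). Ties break to the larger
summed intensity, then lexicographically. Member intensities are summed
over observed values per sample; a sample missing in every member stays
missing. When no clique qualifies the protein is dropped (default) or all
peptides are summed (`sum-all`).

Spearman correlations use average ranks for ties and the t approximation
on n − 2 degrees of freedom for p-values; features with fewer than 3
complete pairs are skipped. The simulated type-I error at n = 20 is
within 2 points of the nominal 5 %.

## Proteogenomic libraries

Variant calls arrive in protein coordinates (codon mapping and effect
prediction are upstream). Filters are inclusive: ≥ 2 supporting reads and
≥ 10 total coverage. SAAV-identifying peptides are the variant digest
minus the parent protein's reference digest (string equality; optional
I/L-collapsed comparison; optional whole-proteome exclusion for stricter
uniqueness). Substitutions that create a K/R produce two specific
peptides, ones that destroy a K/R produce one merged peptide — both
verified against a digest-both oracle. Concatenated FASTA records are
bookkeeping for search engines; the sidecar peptide table carries the real
peptide boundaries so downstream transition building can never invent
junction-spanning peptides.

The isoform library digests every isoform, maps each distinct ≥ 5-residue
peptide to the exact set of isoform ids containing it, and concatenates
each set's peptides into one mock protein (ordered by position in the
lexicographically smallest member isoform, for determinism). Grouping is
a partition of the retained peptides by construction, and tested as such.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of a seed. Residue composition puts K/R at
~11 % combined so tryptic peptides average ~9 residues, matching real
proteomes well enough for digestion statistics. Spectra contain *all*
theoretical y/b peaks with Gaussian m/z jitter (SD 0.3 ppm, matching a
well-calibrated Orbitrap) plus 20 % uniform noise peaks; real spectra have
incomplete fragment ladders, correlated intensities, and isotope
envelopes, so the measured transition recall (≥ 95 %) bounds matching
fidelity, not real-data sensitivity. RT runs use an affine drift (slope
1.05, intercept 180 s over a two-hour gradient, noise SD 6 s) with
violation classes injected so each anchor filter is exercised at its
boundary. Quant matrices use log-normal protein abundance (log2 base
N(20, 2), per-sample SD 1), five true peptides at log2 SD 0.2 with
per-peptide ionization offsets, and two independent decoy peptides per
protein — σ chosen as a typical peptide-level technical CV; missingness is
intensity-threshold censoring (missing not at random, as in MS).
Chromatographic peak shapes, isolation-window effects and instrument
noise physics are not modeled; no in-scope operation consumes them.

Problem sizes in the test and acceptance runs (200 digestion sequences,
150 peptides' spectra, 400-peptide/30-run RT cohorts, 100 proteins × 30
samples, 200 variants, 100 isoform families) were chosen as the smallest
sizes at which the measured rates are stable across seeds.

## Known limitations

- "Identification" in the RT loop is alignment-based, so iteration traces
  are not comparable to scorer-based protein counts from real pipelines.
- BH on combined p-values is a transparent stand-in for semi-supervised
  rescoring and will be conservative relative to it.
- The greedy clique path beyond 30 peptides is not guaranteed optimal.
- Decoy transition generation (library-level FDR) is not implemented.
- mzML input is not implemented; MGF covers the synthetic and typical
  exported-peak-list use cases.
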