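# Methods

## Model and assumptions

`dosetrace` analyses isothermal dose-response curves from thermal proteome
profiling. The unit of analysis is a *trace*: one entity (protein or
phosphosite) × one replicate × one temperature, with one abundance per dose.
Doses sit at ordinal positions 1..n rather than on the concentration axis:
the ladder spans five orders of magnitude plus a zero dose, so log-spacing
is undefined at the vehicle and raw spacing would concentrate all kernel
mass on the two top doses. The ordinal axis gives the bandwidth a uniform
meaning ("how many neighbouring doses inform a fitted point").

The smoother is a Nadaraya–Watson estimator with a Gaussian kernel; the
evaluation point carries its own weight φ(0). Fitted values are therefore
convex combinations of the observations, bounded by min(y) and max(y).
No parametric dose-response model is fitted and no goodness-of-fit gate is
applied: the response summary is the average slope (mean of adjacent fitted
tangents), which on an equally spaced grid telescopes to
(ŷ_n − ŷ_1)/(n − 1).

Assumptions worth stating: abundances are positive (enforced by the
completeness filter); the two replicates share a response shape but not
noise; classification thresholds operate on the *fitted* curve, so the
effective responsiveness of a pattern depends on bandwidth (smoothing
shrinks the range — with b = 1 on nine points a plateau of amplitude A
yields a fitted range of about 0.96 A).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `bandwidth` (b) | kernel width, ordinal units | 1.0 | mild smoothing at unit spacing; smaller values track noise, b → ∞ flattens to the mean |
| `range_t` (T) | min fitted fold-change range to be responsive | 0.3 | fold-change units |
| `up_run_b` (B) | min consecutive upward trends (hyper; both arms of biphasic) | 3 | strict inequality defines a trend; ties break runs |
| `down_run_c` (C) | min consecutive downward trends (hypo) | 5 | |
| `end_factor_e` (E) | biphasic ends must differ ≤ E × fitted range | 0.45 | alternative reading E × T behind `end_rule="threshold"` |
| `hit_threshold` | min slope magnitude for a proteome-impact hit | 0.5 | two-sided by default (`hit_two_sided`) |
| `min_localization` | phosphosite localization-probability floor | 0.5 | boundary kept (≥) |
| `excluded_positions` | outlier dose positions dropped before fitting | ∅ | global per run, an experiment-level artifact control |

T, C, B, E defaults are the published staurosporine settings; the bandwidth
is left user-set and defaults to 1.0.

## Pipeline order and numerical choices

1. localization filter, then collapse of site multiplicity variants to the
   best-localized row (site identity = protein × position × residue);
2. rows → traces; excluded positions are dropped *before* normalization so
   the normalized trace always starts at exactly 1 even when position 1 is
   excluded; surviving positions keep their original ordinal labels;
3. completeness: an entity × temperature group is kept only if every
   retained dose point is strictly positive in both replicates; the two
   temperatures are filtered independently;
4. proteins: peptide rows are channel-wise summed *before* normalization
   (sum-then-normalize weights peptides by abundance; the operations do not
   commute);
5. first-dose normalization, kernel fit, classification, replicate
   reconciliation.

Numerical details: the smoother centres each trace on its first value
before the weighted mean, which makes constant traces exact fixed points in
floating point; equal adjacent fitted values terminate both up- and
down-runs (strict trend reading, documented so users can audit borderline
calls); BIPHASIC is tested before HYPER/HYPO so a rise-and-fall curve with
a small residual slope is not absorbed into a monotone class; category
proportions are returned as exact rationals so they always sum to 1;
result tables are written at 8 significant digits, giving write/read
round-trips within 1e-6 relative error. Degenerate inputs (fewer than
3 points after exclusion, zero first dose, non-finite intensities,
mismatched replicate grids) raise typed errors rather than propagating
NaNs. With more than two replicates the reconciliation raises instead of
guessing a majority rule.

Two wordings of the biphasic rule circulate; both are implemented. The
default requires B trends in both directions and bounds the end difference
by E × fitted range; `biphasic_down_run="C"` and `end_rule="threshold"`
select the stricter variants.

The enrichment test is the upper-tail hypergeometric probability with the
background of all identified proteins; the significance flag uses the raw
p < 0.05 rule, with a Benjamini–Hochberg FDR column emitted alongside for
users who want it. Gene sets are intersected with the background before
testing.

## What the synthetic generator emulates — and what it does not

The generator emits the 9-dose ladder, two replicates, and four response
shapes: rising sigmoid (hyper, amplitude 0.5, midpoint position 5,
steepness 1.2), its mirror (hypo), a Gaussian bell (biphasic, amplitude
0.5, peak 5, width 1.5) and a constant (flat), each multiplied by a
log-normal base intensity and per-point multiplicative log-normal noise
(σ = 0.05 by default). Amplitudes were fixed so noise-free fitted ranges
clear T by ≥ 1.5× for responsive patterns and stay below 0.5 T for flat.
Protein patterns pair temperatures (stabilized: flat at 37 °C, amplitude-6
rise at 52 °C; an abundance shift; a destabilized non-hit; unchanged).
Because first-dose normalization bounds decreasing curves below by zero,
|slope| of a falling nine-point curve cannot exceed ≈ 0.125 — destabilized
proteins are therefore structurally non-hits under the 0.5 threshold, and
the generator labels them so.

Not emulated: missing channels, cross-plex reference-channel scaling, batch
effects, peptide-level variance structure, or correlated noise across
doses. Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic under its stated noise model, not performance on real
mass-spectrometry data with those artefacts.

## Problem sizes

The test suite and the acceptance script use synthetic runs of up to
10,000 sites (2,500 per category) for partition/concordance accounting and
200 sites per category for label-recovery measurements — sizes at which the
recovery estimates are stable to a few percent while the full suite runs in
well under a minute. At zero noise recovery is exact; at σ = 0.05 the
hardest class is biphasic (its end-difference bound is the tightest
constraint), with per-category recovery around 86–90% depending on the
random draw, driven almost entirely by the replicate-concordance rule
demoting borderline biphasic sites to NR.

## Known limitations

- Replicate support is fixed at two, matching the experimental design the
  defaults were derived for.
- The upward-interval metric uses the longest upward run of the mean fitted
  curve; counting all upward intervals is a defensible alternative reading
  and is not currently exposed.
- Hit calling applies the slope threshold to the replicate-mean curve
  statistics without a protein-level concordance requirement.
- No EC50/Tm estimation, imputation, or multi-plex normalization.
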