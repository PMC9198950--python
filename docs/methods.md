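# Methods

`flowscreen` analyzes arrayed RNAi screens read out by flow cytometry of a
fluorescent stemness reporter (ID4-eGFP in cultured mouse spermatogonia).
It covers the whole chain: a generative model of per-well events, quadrant
gating, plate-normalized Z scoring over biological replicates, dual-parameter
hit calling, a pup-versus-adult age comparison (ΔZ), gene-set
over-representation, and the small assay formulas used around such screens.
This note documents the models, their assumptions, the defaults, and the
choices made where the design was genuinely open.

## Generative model of per-well events

Each well's eGFP intensity distribution is a four-component mixture of
log10-normal subpopulations — reporter-negative, Dim, Mid, Bright — with
weights `w_c` (summing to 1), log10 means `mu_c` (strictly increasing) and
SDs `sigma_c`. Log-normal components are the standard phenomenology for
cytometer fluorescence channels and make quadrant gates linear in log space.

Default baseline (a package choice; screens of this design do not publish
their baseline Bright fraction):

| component | weight | mu (log10 a.u.) | sigma |
|-----------|-------:|----------------:|------:|
| negative  | 0.55   | 1.0             | 0.30  |
| Dim       | 0.20   | 2.0             | 0.25  |
| Mid       | 0.15   | 2.6             | 0.22  |
| Bright    | 0.10   | 3.2             | 0.20  |

with default gate boundaries at log10 intensity 1.5 / 2.3 / 2.9. The
components deliberately overlap across boundaries (6–9% leakage between
adjacent strata), as real reporter profiles do.

A knockdown phenotype (`EffectSpec`) acts only on the mixture, never on the
gated readouts: multiplicative factors on the Dim/Mid/Bright weights
(renormalized, so `w'_B = f_B w_B / sum_c f_c w_c`), an additive shift of all
log10 means, and a multiplier on per-event survival probability. Downstream
statistics must therefore recover planted effects through the event level,
which keeps end-to-end checks non-circular. An effect may be restricted to
cultures of one age (`ages` field) and a gene may carry several composable
components (factors multiply, shifts add); this is how age-differential
responses — the object of the ΔZ analysis — are modelled.

Well-to-well and culture-to-culture variation are log-normal random effects
on the component weights: a per-culture, per-component effect (SD 0.10,
shared by every well of a culture) and an independent per-well effect
(SD 0.06). Events per well default to 2000 (a plate cytometer screening
20,000-cell wells records on this order of spermatogonia-gated events);
baseline viability is 0.90, thinned per event. One seeded `numpy` Generator
drives everything, wells visited in sorted (plate, well) order, so identical
(config, plate map, seed) give byte-identical output.

Not modelled: forward/side scatter, doublets, spectral spillover, passage
dynamics, edge effects. Passing tests therefore demonstrate correctness of
the *statistics* under a plausible generative model, not robustness to every
artifact of real plates.

## Screen layout

The library layout mirrors an arrayed 96-well screen: 18 plates x 80 target
wells (one pooled siRNA per transcription factor, 1440 in total) plus four
control wells per plate — one transfection-reagent-only well, two
nontargeted-siRNA wells, one internal positive-control well (Rb1 by
default). Each of the six cultures (three pup, three adult) receives its own
copy of the plates; plate ids are culture-scoped (`pup1-P03`), wells are
keyed `plate_id:well_id`, and culture identity lives in the plate map, not
in file names.

## Gating

Viable events are stratified on log10 intensity by three strictly
increasing boundaries into negative | Dim | Mid | Bright. Intervals are
half-open and lower-closed: an event exactly on a boundary belongs to the
stratum whose lower edge it sits on. Dead events are excluded from all
readouts; viability is reported separately. MFI is the arithmetic mean of
linear intensities over the *whole* viable population (negative events
included), since it is read as a composite of the stem/transitory/progenitor
ratio; a geometric-mean option exists because cytometry practice varies and
the convention is rarely stated. Wells failing QC (default: fewer than 200
events or viable fraction below 0.5) or with zero viable events carry
explicit missing readouts — never silent NaNs or zeros. Gates can also be
calibrated from pooled nontargeted-control events at configured quantiles
(deterministic, order-invariant linear-interpolation quantiles).

## Scoring

Per replicate (culture) and parameter (gated %Bright or MFI):

1. `X = readout / mean(same-plate nontargeted-control readouts)` —
   nontargeted controls average to X = 1 on every plate. QC-failed wells
   emit no readout.
2. `Z = (X - mu) / sigma`, with `mu`, `sigma` the mean and sample SD (n-1)
   of X over all scored targets of the replicate. Library-wide scope is the
   default (one formula per replicate); per-plate scope is available as a
   robustness option. Sample SD is pinned for exactness; at n = 1440 the
   difference from the population SD is negligible.
3. Average Z per target over the pup, adult, or all replicate groups.
4. `ΔZ = |avg Z(pup) - avg Z(adult)|` — absolute by default because the
   age comparison filters symmetrically on magnitude; a signed mode exists.
5. Hits: strict comparison of the selected group average to ±t (default
   t = 1; a value exactly at the threshold is not a hit). The
   dual-parameter rule defaults to the *union* of the %Bright and MFI lists
   (the broadest reading of "alterations in Bright content and MFI");
   intersection and single-parameter rules are exposed. The broadest
   candidate-regulator list unions over both age groups as well — with
   three replicates per group, group averages are the level at which
   screen-scale tail fractions (tens of percent of the library) arise.
6. Prime candidates: union of the top-k and bottom-k targets per parameter
   by all-replicate average Z (default k = 5, at most 4k members); ties at
   rank k break lexicographically on gene symbol.

Per-replicate Z has mean 0 and SD 1 to 1e-9 by construction; relabeling
plates or permuting wells changes nothing. No B-score/median-polish plate
correction, replicate weighting or FDR on Z is applied: the screen design
uses fixed thresholds.

## Default planted-effect landscape

The default full-screen simulation plants a variance-component landscape:
every target g gets a latent log effect on the Bright weight,
`log f_B(g, age) = b_shared(g) + b_age(g)` with
`b_shared ~ N(0, 0.02^2)`, `b_pup ~ N(0, 0^2)`, `b_adult ~ N(0, 0.072^2)`,
realized once per screen so responses are consistent across the replicate
cultures of an age — the structure that makes per-replicate Z-scores
correlate within an age group and gives the ΔZ comparison something to
find. The intensity shift couples MFI to the Bright effect (0.25 log10
units per log10 of the weight factor) plus an independent latent shift
(SD 0.012 log10) so the two parameters are correlated but not redundant.
The variance parameters were derived analytically, once, from the
emulated screen's reported within-age tail structure (roughly 9% of
targets outside |Z| > 1 in pup groups and 19% in adult groups at three
replicates) together with the generator's noise budget. Known limitation:
a Gaussian landscape cannot match those tails and the reported ΔZ summary
statistics simultaneously; the emergent mean ΔZ (~0.73, ~72% below 1)
overshoots the reported ~0.59 / ~84%, i.e. the model understates the
cross-age correlation of real responses.

## Positive-control (Rb1) fixture

`src/flowscreen/data/rb1_effect.yaml` is the committed Rb1 knockdown
phenotype, produced once by `scripts/calibrate_rb1.py` and not regenerated
at run time. The script solves the noise-free mixture closed forms so that
the *emergent* readout changes of an Rb1 well match the validation
experiment: gated %Bright reduced by 32% and MFI by 40% (hard targets,
weight 100), with the companion observation that %Mid and %Dim stay
roughly unchanged entering as soft penalties (weight 1) — the full
four-constraint system is infeasible under the four effect knobs, so the
soft terms select the least-disturbing member of the exact two-constraint
solution manifold. Result: bright weight factor 1.0, mid 0.737, dim 0.777,
intensity shift -0.2217 log10. Simulated head-to-head (4 cultures for
%Bright, 8 for MFI, 4 paired wells per arm), the emergent reductions land
within ~2 points of 32%/40%.

## Null calibration and power harnesses

`null_screen_fixture` is a calibration harness whose contract is that
all-null average Z approximates Normal(0, 1/R). Its design suppresses the
departures a production layout induces: replicates are independent (no
culture effect), plates carry 12 nontargeted control wells (so the
normalization denominator adds negligible plate-shared noise — with only
2 controls per plate the tail fraction is visibly seed-unstable), and
per-well weight noise is reduced to SD 0.03 so near-symmetric
event-sampling noise dominates (log-normal weight noise skews the
normalized ratio right and biases the upper tail). Under this harness the
fraction of 1440 targets with average Z > 1 at R = 3 matches
1 - Phi(sqrt(3)) ≈ 4.2% within one percentage point, the average-Z CDF is
within Kolmogorov–Smirnov distance 0.05 of Normal(0, 1/3), and with three
replicates per age the null mean ΔZ matches the folded-normal value
sqrt(2·(2/3)/π) ≈ 0.651.

The power harness plants 20 targets with Bright weight factor 0.4 in an
otherwise null 1440-target, 6-replicate screen at the *production* noise
defaults; the below-threshold Bright hit list recovers them with
sensitivity ≥ 0.9 (measured: 1.0).

## Enrichment

Over-representation of a hit list against the screened library (never the
genome): one-sided hypergeometric tail `P[X >= k]` on the universe of
library genes annotated to at least one tested set, with the conservative
one-decremented (EASE-style) variant alongside, and Benjamini–Hochberg
control across tested sets (sets smaller than 3 after intersection with
the library are skipped). The descriptive "percent of category"
(100·overlap/set size) is reported per set. An empty hit list yields p = 1
everywhere, not an error. Fuzzy functional clustering and protein-network
retrieval of the platforms this replaces are out of scope; users supply
GMT collections (the analysis driver generates a seeded *synthetic*
collection as a stand-in).

## Auxiliary assay formulas

Signed percent change `100·(treated - control)/control` (prose rendering
"reduced by X%" reports the magnitude); relative expression `2^-ΔΔCt`
assuming 100% amplification efficiency; transplantation stem-cell number
`colonies · 1e5 / cells injected`.

## Problem sizes and numerics

The packaged study designs simulate 1440 targets x 6 cultures x 2000
events/well (~18M events, tens of seconds on one CPU); the validation and
unit fixtures are far smaller. Quantiles use linear interpolation;
boundary ties in gating are resolved lower-closed; hit thresholds are
strict inequalities; all TSV output is written at 6 significant digits;
event CSVs round-trip intensities bit-exactly (`float_precision=
"round_trip"` on read). FCS ingestion is not implemented; CSV event tables
are the canonical format, and externally deposited per-replicate readouts
can enter the Z/ΔZ/hit stages through
`flowscreen.io.read_replicate_readouts` (tidy TSV of plate-normalized X).
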