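# flowscreen

Analysis pipeline for arrayed RNAi screens read out by flow cytometry of a
fluorescent stemness reporter — the design used to screen siRNA pools
against 1440 transcription factors in primary cultures of mouse
spermatogonia carrying an ID4-eGFP reporter, where the ID4-eGFP^Bright
fraction marks the stem-cell-enriched subpopulation.

The package is for screen analysts and stem-cell biologists who need the
screen's statistics as tested, reusable code: it simulates per-well
cytometer events from a four-component log-normal mixture with planted
knockdown effects, gates them into subpopulations, scores every library
target, and runs gene-set enrichment — all deterministic under a seed, with
a ground-truth table for every simulation.

## The statistics at its core

For each biological replicate (primary culture) and each screen parameter
(gated %Bright and MFI, the mean fluorescence of the whole viable
population):

- **Normalization** — every target well is divided by the mean readout of
  its plate's nontargeted-siRNA control wells: `X = readout / control mean`.
- **Z-score** — `Z = (X − μ)/σ`, with μ and σ the mean and sample SD of X
  over all scored targets of the replicate.
- **Average Z** — per-target mean of Z over the replicates of a group
  (3 pup cultures, 3 adult cultures, or all 6).
- **Hit calling** — strict thresholds `Z > t` / `Z < −t` (default t = 1) on
  one or both parameters; prime candidates are the union of the top-5 and
  bottom-5 targets per parameter.
- **Age comparison** — `ΔZ = |avg Z(pup) − avg Z(adult)|`; ΔZ > 2 flags
  strongly age-differential responders.
- **Enrichment** — one-sided hypergeometric tail (with an EASE-style
  conservative variant) of hit lists against the 1440-gene library
  background, Benjamini–Hochberg corrected.

See `docs/methods.md` for the generative model, gating rules, calibration
fixtures and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`. Running them in order:

```text
$ python analysis/01_validate_positive_control.py
Rb1 knockdown reduced gated %Bright by 34.5% (mean of 4 cultures) and MFI
by 39.5% (mean of 8 cultures).
```

The committed Rb1 positive-control phenotype, pushed through event-level
simulation and gating, reproduces the validation experiment's readout
changes (reference: 32% and 40%).

```text
$ python analysis/02_simulate_screen.py
simulated 18,144,000 events in 9072 wells (100.0% QC pass)
$ python analysis/03_score_targets.py
bright_pct: 1440 targets; avg Z over all six replicates in [-1.57, 1.86]
$ python analysis/04_call_hits.py
497 targets with |avg Z| > 1 on either parameter in either age group
50 targets with all-replicate avg Z < -1 (reduced stem-cell readout)
14 prime candidates from the four top/bottom-5 lists: TF0052, ...
$ python analysis/05_compare_ages.py
mean ΔZ over both parameters: 0.73
72% of target/parameter responses were similar at both ages (ΔZ < 1)
bright_pct: 44 targets with strongly age-differential response (ΔZ > 2)
```

A library-scale screen with the default effect landscape yields a broad
candidate list of ~500 genes, a prime candidate set from the four
top/bottom-5 lists, and an age comparison in which most knockdowns act
similarly in pup and adult cultures.

```text
$ python analysis/06_enrichment.py
top set: synthetic_pathway_enriched_1 — 18/30 members hit (60% of
category), p_hyper = 6.03e-13, q_BH = 6.03e-12
$ python analysis/07_pipeline_calibration.py
null screen: 4.58% of 1440 targets with avg Z > 1 (analytic 4.16%)
planted recovery: 20/20 Bright-depleted targets recovered (sensitivity 1.00)
```

The calibration script checks the pipeline against closed forms: on an
all-null screen the fraction of targets past Z = 1 matches the normal tail
1 − Φ(√3), and targets whose Bright compartment is reduced to 40% of
baseline are recovered with full sensitivity.

The same pipeline is available as a CLI
(`flowscreen simulate|gate|score|hits|deltaz|enrich|report`), e.g.:

```sh
flowscreen simulate --seed 3 --plate-map pm.csv \
    --out-events events.csv --out-truth truth.tsv
flowscreen gate --events events.csv --out wells.tsv
flowscreen score --summaries wells.tsv --plate-map pm.csv --out ztable.tsv
```

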