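# autolc

Closed-loop, interpretive method development for liquid-chromatography
(LC and LC–MS) separations — the software side of an "instrument that
optimizes its own gradient".  The package targets separation scientists
and chemometricians who want to study, prototype, or teach automated
method development without a physical instrument: a built-in virtual
LC–MS plays the role of the hardware, so the whole loop runs on a laptop.

## What it does

A **method-development iteration (MDI)** is one experiment: a gradient
program is run, the raw time × m/z data are analyzed, and the next
gradient is chosen.  Two strategies close the loop:

**Retention modeling.**  Three linear scouting gradients of different
slope seed the loop.  Peaks are detected in two stages — on the summed
(total-ion) trace, then iteratively per m/z channel using the
time-averaged mass spectrum (most intense channel first, removed once
described, until 80 % of the spectrum area is accounted for) — and linked
across runs by their m/z signatures ("peak tracking").  For every tracked
analyte the linear-solvent-strength (LSS) law

&nbsp;&nbsp;&nbsp;&nbsp;*k*(φ) = *k*₀ · e^(−*S*·φ)

is fitted to the observed retention times (20 bounded multi-start
least-squares fits, 3000 evaluations each, lowest SSE wins), where φ is
the organic-modifier fraction and *k* the retention factor.  Retention
times under any multisegment gradient then follow from the migration
integral ∫₀^τ dt/k(φ(t)) = t₀, solved in closed form per linear segment;
base peak widths follow a plate-count model *w* = 4 t₀(1 + *k*ₑ)G/√N,
floored at 0.3 min as a safety margin.  Each MDI the optimizer builds a
pool of exactly 2000 candidate gradients (16 parameters each: 5 segments
of isocratic hold + linear ramp with non-decreasing compositions and a
40-min budget), refines each against the resolution score
*O*ᴿˢ = (2(n−1) − ΣRs)/(2(n−1)) with adjacent resolutions capped at 2,
and hands the best 200 to a genetic algorithm that minimizes the
performance score *O*ᵖᵉʳᶠ = 1.00·*O*ᴿˢ + 0.05·*O*ᵗ, where
*O*ᵗ = t_last/t_max discourages needlessly long methods.  The best
gradient becomes the next MDI; full re-detection over all stored runs
("retrack") happens at MDI 4, 9, 14, ….

**Bayesian optimization.**  A model-free alternative needing no tracking:
three-step gradients parameterized by (φ_A, φ_B, t_A, t_B) are proposed
by a Gaussian-process surrogate (Matérn-5/2, expected improvement)
driven directly by a chromatogram-derived score — the number of
connected components (peak clusters at Rs < 1.5 plus separated peaks),
the detected-peak count, or the product of adjacent resolutions.

The **virtual instrument** renders Gaussian peaks from a hidden library
of true (k₀, S, N, abundance, m/z) values onto a time × m/z grid, with
baseline drift, detector noise, and retention/width jitter, and keeps
the ground truth aside for evaluation.

## Worked example

Run the retention-modeling loop on a 15-analyte synthetic sample
(scaled-down optimizer so it finishes in ~30 s):

```
cat > cfg.yaml <<'YAML'
instrument:
  mz_min: 100
  mz_max: 500
rm:
  pool_size: 500
  top_k: 100
  generations: 150
  stage_one_maxfev: 300
  mdi_cap: 10
YAML
autolc rm --sample synthetic:15 --config cfg.yaml --seed 11 --out rm-run
```

which prints

```
8 MDIs; best o_perf 0.0244 at MDI 8 (sum Rs 28.00, 15 peaks)
```

meaning: after three scouting runs and five optimized iterations the
best gradient shows all 15 peaks with every adjacent pair at the capped
resolution of 2 (ΣRs = 14 pairs × 2 = 28, so *O*ᴿˢ = 0), and the
remaining 0.0244 of the performance score is the weighted analysis-time
term.  `rm-run/` holds the per-MDI JSON history (`history.jsonl`), the
MDI trace (`mdi_trace.csv`, achieved and predicted ΣRs per iteration)
the per-MDI peak tables and genetic-algorithm fitness traces, and the
final tracked-analyte and fitted-model tables (`track_table.csv`,
`models.csv`).  The BO strategy runs
the same way:

```
autolc bo --sample synthetic:20 --objective cc --n-mdi 10 --seed 21 --out bo-run
```

reporting `best objective 16 at MDI 10 (16 components, 17 peaks)`.

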