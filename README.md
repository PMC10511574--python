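# refluxsap

Analysis pipeline for ambulatory esophageal pH monitoring: reflux episode
detection, DeMeester composite acid-exposure scoring, windowed symptom–reflux
association (SAP, with SI/SSI companions), synthetic data generators, and
cohort-level surgical-outcome comparisons.

## What it does

* **trace_model** — data types and plain-text I/O for pH recordings
  (CSV `time_s,ph` + annotation CSV for posture/meals), symptom event logs
  (JSON), and patient cohort tables (CSV). Time base is seconds from
  recording start; all intervals are half-open `[start, end)`.
* **acid_exposure** — maximal sub-pH-4 run detection (each sample carries its
  sampling interval), the six classical acid-exposure components
  (%time pH<4 total/upright/supine, episode count, episodes ≥5 min, longest
  episode), the composite score `Σ max(0, (value−mean)/sd + 1)` with
  configurable reference normals, and severity strata
  (normal ≤14.7 < mild ≤20 < moderate ≤50 < severe).
* **symptom_association** — consecutive 2-min windows; a window is
  reflux-positive on ≥5 s of sustained pH<4 inside it or a >1-unit drop
  within 5 s; per-symptom 2×2 window tables; SAP = (1−p)×100 from Fisher's
  exact test, positive at ≥95%; patient-positive if ≥1 symptom positive;
  SI (% of events reflux-associated, positive ≥50%) and SSI (% of episodes
  with a symptom, positive ≥10%). Zero-event symptoms are reported as *not
  assessable*, never as negative.
* **stats_core** — self-contained Fisher's exact 2×2 (point-probability
  two-sided rule), Monte Carlo exact r×c test, Mann–Whitney U, Wilcoxon
  signed-rank and Kruskal–Wallis (tie-corrected, exact enumeration at small
  n), plus a Holm adjuster. Each is checked against a brute-force oracle in
  the test suite.
* **synthetic_data** — seeded generators for 48-h Bravo-style traces
  (6-s sampling) with planted, exactly recoverable reflux episodes; symptom
  logs with window-level coupling ρ to reflux; and surgical cohorts with
  configurable marginals (defaults: n=597, 71.4% female, DeMeester median
  44.1, 72.0% SAP-positive with a 221:164:45 one/two/three-symptom split,
  82% favorable outcome) and a configurable — default null — SAP→outcome
  effect.
* **cohort_analysis** — outcome flags (favorable = satisfied AND PPI-free;
  ≥50% HRQL improvement), SAP-positive vs SAP-negative comparison tables,
  favorable-by-SAP-count analysis, per-symptom-type analyses, and subgroup
  sweeps, all on per-variable complete cases with explicit denominators.

## CLI

A single `refluxsap` entry point (also `python -m refluxsap.cli`):

```bash
refluxsap simulate-trace   --seed 7 --out sim/
refluxsap simulate-symptoms --trace sim/trace.csv --annotations sim/annotations.csv --seed 8 --out sim/
refluxsap simulate-cohort  --seed 9 --n 597 --out sim/
refluxsap score-trace      --trace sim/trace.csv --annotations sim/annotations.csv --out scored/
refluxsap sap              --trace sim/trace.csv --annotations sim/annotations.csv \
                           --symptoms sim/symptoms.json --out sap_report.json
refluxsap analyze-cohort   --cohort sim/cohort.csv --out analysis/
refluxsap end-to-end       --seed 7 --n 100 --out run/
```

Simulation subcommands require `--seed` and are byte-for-byte reproducible.
Every run writes a `provenance.json` sidecar (config echo, seed, version)
next to its outputs; logs go to stderr.

## Conventions worth knowing

* At 6-s sampling a single sub-4 sample covers 6 s and therefore satisfies
  the "≥5 consecutive seconds" window rule on its own; likewise the
  ">1 unit within 5 s" drop rule cannot fire at regular 6-s sampling (both
  are parameters, so finer-sampled traces exercise them).
* Episode merging (`merge_gap_s`) and meal exclusion default to *off*.
* The DeMeester component reference means/SDs are external constants and
  configurable; only the 14.7/20/50 severity boundaries are fixed.
* Note: in the reference cohort's between-group table the "mild objective
  reflux" row (93.5%/90.4%) is inconsistent with the mild stratum as defined
  (7.4% of the cohort); this package always applies the stratum definition.
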