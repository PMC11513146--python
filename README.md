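# ripplemap

Analysis pipeline for paired hippocampal dCA1 / basolateral-amygdala (BLA)
recordings: sharp-wave-ripple detection, ICA cell-assembly extraction with a
Marchenko–Pastur significance count, memory-assembly classification
(RMI/MAI + peri-ripple modulation), memory vs non-memory ripple taxonomy,
lag-shifted Poisson-GLM population decoding, and place-cell spatial
information — plus a synthetic-session generator that plants all of the
above structure with known ground truth.

## Layout

| module | contents |
|---|---|
| `ripplemap.core` | domain types: epochs, spikes, LFP, ripples, assembly patterns, activation traces |
| `ripplemap.synthetic` | seeded generators: LFP with injected ripples, planted BLA assemblies (optionally ripple-yoked at a 35-ms lag, post-training only), GLM-coupled target units, random-walk trajectories with place cells, `make_default_session` |
| `ripplemap.ripples` | 100–250 Hz envelope, offline 5/1-s.d. ripple detection, causal 8-s.d. closed-loop trigger simulation, SWS heuristic |
| `ripplemap.assemblies` | 25-ms binning + z-scoring, MP/Tracy–Widom component counting, FastICA pattern extraction, activation strength (zero-diagonal quadratic or linear), circular-shift surrogates, pattern matching |
| `ripplemap.memory` | peri-event histograms (5-ms bins, 15-ms smoothing), 3.3-z/3-bin modulation rule, RMI/MAI, memory-unit classification, ripple-shuffle permutation test |
| `ripplemap.taxonomy` | memory/non-memory ripple labeling, amplitude/duration comparison, M\|N content scores with split-half controls, selectivity index, population peri-ripple profiles |
| `ripplemap.decoding` | 100-ms window schedule with +35-ms source→target lag, ridge Poisson GLM, train/test split decoding with permutation nulls, top/bottom weight-split decoding |
| `ripplemap.spatial` | 1-cm occupancy/rate maps, spatial information (bits/spike), 0.4-Hz place-cell filter, subgroup comparison |
| `ripplemap.pipeline` / `ripplemap.cli` | `RunConfig` (paper-default constants), full orchestration, flat-file session I/O, `ripplemap` CLI |

## CLI

```bash
ripplemap simulate --seed 1 --out session/          # write a planted synthetic session
ripplemap detect-ripples session/ --out results/
ripplemap run-all session/ --seed 1 --out results/  # full pipeline + manifest
```

A session directory is flat files: `spikes.csv` (unit_id, region, time_s),
`lfp.h5` (dataset `lfp` with `fs` attribute), `epochs.json`, optional
`position.csv` and `truth.json`.

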