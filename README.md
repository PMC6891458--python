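# retinatune

A tunable bioinspired retinal encoding model together with the machinery to
fit it against reference spike recordings:

- **stimulus** — moving-bar and full-field-flash stimuli with physical units
  (16-bit multipage TIFF + JSON sidecar I/O);
- **retina** — the model under study: stage 1 is a weighted
  difference-of-Gaussians / Laplacian-of-Gaussian spatial filter bank sampled
  at the modelled cell's centre, stage 2 is a noisy leaky integrate-and-fire
  spike encoder.  Six parameters (kernel size, leakage, threshold,
  persistence time, refractory period, frequency-modulation factor) form the
  tunable chromosome;
- **baseline** — a simplified human-visual-system filter cascade followed by
  a Poisson spike generator, used as a comparison baseline;
- **metrics** — the four minimised objectives comparing candidate and
  reference rasters: PSTH-KLD, ISIH-KLD, absolute firing-rate difference and
  absolute receptive-field-size difference (reverse correlation);
- **moo** — five population-based multi-objective metaheuristics over the
  mixed-integer chromosome: NSGA-II, SPEA2, NSGA-III, archive-guided particle
  swarm (Clerc constriction) and DE/rand/1/bin with dominance replacement;
- **indicators** — exact hypervolume (recursive dimension sweep), automatic
  reference-point selection, per-generation HV trajectories;
- **npstats** — Kruskal-Wallis, Friedman, pairwise Mann-Whitney U (normal
  approximation) and p-value adjustments (Bonferroni with configurable
  multiplier, Hochberg, Hommel, step-up m/j);
- **runner** — synthetic reference generation (a known "true" chromosome
  stands in for biological recordings), full studies (algorithms x runs),
  HV tables, statistical reports and summary exports.

## CLI

A single entry point with subcommands:

```bash
retinatune gen-stimulus --kind bar --direction 90 --out bar090.tif
retinatune make-reference --out ref/ --seed 0
retinatune simulate --chromosome c.json --stimulus bar090.tif --trials 4 --out raster.csv
retinatune evaluate --reference ref/ --candidate cand/ --out objectives.json
retinatune tune --algorithm mopso --seed 3 --out run3/
retinatune hv --front run3/front.csv --ref auto
retinatune stats --table hv.csv --adjust bonferroni:20,hochberg,hommel,step_up_bh
retinatune report --study study/ --out report/
```

## File formats

- stimuli: multipage 16-bit TIFF + `<name>.tif.json` sidecar
  (`frame_rate_hz`, `pixel_scale_um`, `n_frames`);
- rasters: CSV with columns `cell_id, trial, spike_time_ms, duration_ms`
  (one row per spike; spike-free trials keep one NaN row);
- HV tables: long-form CSV `run, algorithm, hv`;
- fronts / HV curves: CSV; manifests and statistical reports: JSON.
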