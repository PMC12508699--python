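# sptkin

Single-particle-tracking (SPT) analysis of nanoparticle–cell binding
kinetics.

When ligand-functionalized nanostructures (antibody- or aptamer-coated DNA
origami, quantum dots, liposomes, …) are imaged over a live cell at high
frame rate, each particle leaves a trajectory. Freely diffusing particles
move fast (D ≈ 2–3 µm²/s for a ~150 nm object in buffer); receptor-bound
particles are nearly immobile (D ≤ 1 µm²/s). From those trajectories one can
read off not just *how much* binding occurs but *how fast* it forms and
breaks: the number of binding events per unit observation is proportional to
the association rate constant k_on, and the distribution of bound dwell
times is exponential with mean τ_B = 1/k_off.

`sptkin` covers the post-localization half of such an experiment:

- **trackio** — CSV track/localization tables (`track_id,frame,x,y`),
  validated configuration, bit-stable round trips.
- **simulate** — a forward simulator of the full kinetic scheme (free
  diffusion, binding inside a cell region, exponential unbinding,
  short non-specific sticking, localization noise, photobleaching,
  detection dropout) so every analysis stage is testable by parameter
  recovery against known ground truth.
- **linking** — nearest-neighbour trajectory reconstruction as per-frame
  minimum-cost bipartite matching, with gap closing (default max gap 3
  frames), a per-gap distance budget (default 0.8 µm per frame) and an
  ambiguity exclusion radius (default 1.2 µm).
- **diffusion** — time-averaged MSD per track; D = slope/4 of a weighted
  linear fit over the first lags (MSD(τ) = 4Dτ + 4σ²_loc); anomalous
  exponent α classifies motion as confined/Brownian/directed.
- **binding** — bound iff D ≤ 1 µm²/s (inclusive); among bound tracks,
  *specific* iff longer than 100 steps (1 s at 100 fps); binding percentages
  with mean ± SEM over biological replicates.
- **kinetics** — dwell-time histogram fit y = y0 + A·e^(−x/τ_B) (k_off =
  1/τ_B), an independent truncated-exponential MLE oracle, relative k_on as
  specific-event-count fold changes, one-way ANOVA + Dunnett comparisons.
- **cli** — `sptkin simulate | link | analyze` commands over YAML configs
  with structured logs and JSON summaries.

## Worked example

```python
from sptkin import SimConfig, RunConfig, simulate_ground_truth, degrade_to_localizations
from sptkin.linking import LinkParams, link, filter_tracks
from sptkin.diffusion import analyze_tracks
from sptkin.binding import label_tracks, binding_percentage
from sptkin.kinetics import count_specific_events

sim = SimConfig(n_particles=200, seed=7)      # defaults: 2000 frames at 10 ms
tracks, truth = simulate_ground_truth(sim)
locs = degrade_to_localizations(tracks, sim)  # identities stripped, 5% dropout

cfg = RunConfig()                             # tracker filters + thresholds
linked = link(locs, LinkParams.from_run_config(cfg))
kept, counts = filter_tracks(linked, LinkParams.from_run_config(cfg))
table = analyze_tracks(kept, cfg)
labels = label_tracks(kept, list(table["D"]), cfg)

print(f"linked {counts.loaded} tracks, {counts.kept} pass the 30-step filter")
print(f"mean D of free tracks: {table.loc[table['D'] > 1, 'D'].mean():.2f} um^2/s")
print(f"binding percentage:    {binding_percentage(labels):.1f}%")
print(f"specific events (>100 steps): {count_specific_events(labels)}")
```

prints

```
linked 4204 tracks, 1540 pass the 30-step filter
mean D of free tracks: 2.44 um^2/s
binding percentage:    4.9%
specific events (>100 steps): 33
```

Detection dropout and close encounters fragment the 200 true trajectories
into ~4200 track segments, of which 1540 survive the minimum-length filter —
the same funnel a real tracker produces. The free population's mean D
recovers the simulator input (2.5 µm²/s) to within sampling error; the
binding percentage is low here because binding is only permitted inside the
10-µm cell region of a 50×50 µm field. The 33 specific events are the bound
tracks lasting longer than 1 s, the quantity whose between-condition fold
change reads out relative k_on.

The same pipeline runs from the shell:

```sh
sptkin simulate --config sim.yaml --out-tracks tracks.csv \
                --out-locs locs.csv --out-truth truth.csv
sptkin analyze --locs locs.csv --config run.yaml --out-dir results/
```

`results/summary.json` contains the stage counts
(loaded → min-steps filtered → bound → specific), the binding percentage,
the dwell-time fit (τ_B, k_off) when enough specific events exist, and a
hash of the resolved configuration.

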