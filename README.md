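# focidyn

Quantification of DNA double-strand-break (DSB) focus dynamics in live-cell
time-lapse microscopy.

When a cell suffers a DSB, repair proteins such as 53BP1 accumulate at the
lesion into a microscopically resolvable *focus*. How these foci move —
their constrained wandering through the nucleus, their coalescence into
larger repair centres (*fusion*), their eventual resolution
(*disappearance*), and the kinetics with which repair factors are recruited
to laser-drawn damage stripes — carries mechanistic information about the
DNA damage response. `focidyn` turns raw movies (or pre-tracked trajectory
tables) into these quantities, for cell biologists analysing repair-focus
imaging and for anyone needing a verifiable single-particle pipeline with a
built-in, ground-truth-generating simulator.

## What it computes

**Drift-corrected mean-square displacement.** For focus *i* at lag Δt,
positions are referenced to the per-frame *global centre*
(x<sup>GC</sup><sub>t</sub>, y<sup>GC</sup><sub>t</sub>) — the centroid of
all tracked foci in that frame — so rigid nuclear/stage translation cancels
exactly:

```
D_i(Δt)² = [(x_t^i − x_t^GC) − (x_{t−Δt}^i − x_{t−Δt}^GC)]²
         + [(y_t^i − y_t^GC) − (y_{t−Δt}^i − y_{t−Δt}^GC)]²

MSD(Δt) = (1/n) Σ_i D_i(Δt)²
```

averaged over foci and time origins. Model fits: free diffusion
MSD = 4·D·Δt, and confined diffusion MSD = P·(1 − e^(−Δt/τ)) whose plateau
P is the squared confinement scale. Note that referencing n foci to their
own centroid deflates the expected MSD by (1 − 1/n).

**The rest of the pipeline.** Laplacian-of-Gaussian spot detection with
subpixel centroid refinement; greedy nearest-neighbour trajectory linking
with gap closing; per-focus distance travelled over a time window; fusion
and disappearance event scoring with censoring at the movie end;
laser-stripe relative enrichment (mean in-stripe / mean out-of-stripe
intensity) and a two-stage recruitment model
R(t) = 1 + A_fast·(1−e^(−k_fast·t))·e^(−γ·t) + A_slow·(1−e^(−k_slow·t));
pooled-variance Student's t comparisons with the conventional
significance-star mapping.

**The simulator.** `focidyn.synthetic` generates the motion the analysis
assumes — tethered (Ornstein–Uhlenbeck) confined diffusion inside a nuclear
disk, shared per-frame drift, proximity fusions, exponential disappearance
— and renders it as Gaussian-PSF movies with Poisson + read noise, so every
analysis stage can be tested against exact ground truth. See
`docs/methods.md` for the model details.

## Worked example

Simulate the standard mobility protocol (a frame every 30 s for 10 min,
50 foci with diffusivity D = 0.005 µm²/s tethered at R = 0.5 µm) and
recover the motion parameters:

```python
import focidyn as fd

cfg   = fd.SimulationConfig.mobility_protocol(n_foci=50, seed=42)
truth = fd.simulate_trajectories(cfg)

curve = fd.compute_msd(truth.trajectories)          # drift-corrected MSD
fit   = fd.fit_msd_model(curve, model="confined")
dist  = fd.distance_travelled(truth.trajectories, window=600.0)

print(curve.to_frame().head(6))
print(fit.params, fit.stderr)
print(dist.median(), "µm")
```

This prints

```
 lag_s  msd_um2  n_pairs  sem_um2
   0.0 0.000000     1050 0.000000
  30.0 0.339001     1000 0.010795
  60.0 0.447670      950 0.014478
  90.0 0.478817      900 0.016836
 120.0 0.493131      850 0.017166
 150.0 0.494061      800 0.016919
P = 0.491 ± 0.003 µm²   τ = 25.2 ± 1.2 s
median distance travelled = 10.42 µm over 10 min
```

The MSD rises with slope ≈ 4D at short lags and saturates: the fitted
plateau 0.491 µm² matches the simulator's closed-form stationary value
2R²·(1 − 1/n) = 0.49 µm², the relaxation time matches τ = R²/2D = 25 s,
and the implied diffusivity P/4τ = 0.0049 µm²/s is the centroid-deflated
truth D·(1 − 1/50).

The same analysis runs from a shell on rendered movies:

```
focidyn simulate --config sim.yaml --out run/ --render
focidyn detect   --in run/movie.tif  --out run/spots.csv
focidyn track    --in run/spots.csv  --out run/tracks.csv
focidyn msd      --in run/tracks.csv --out run/msd.csv --fit confined
focidyn events   --in run/tracks.csv --out run/events.csv
focidyn stripe   --in stripe.tif --roi 80,0,80,127,12 --out enrich.csv --fit
```

One caveat worth knowing before interpreting real data: when two foci drift
within the optical resolution limit, detection transiently merges them and
the linker can swap identities afterwards, which inflates long-lag MSD on
*detected* (as opposed to ground-truth) tracks. `docs/methods.md` discusses
this and the default lag cutoff.

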