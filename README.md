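# soarharness

Does the way a bio-logging tag is strapped to a bird change how the bird
flies? `soarharness` is an analysis pipeline for quantifying the effect of
tag-harness type — **backpack** (thoracic X-strap, device between the
scapulae) versus **leg-loop** (pelvic harness, device on the lower back) —
on the fine-scale flight performance of large soaring raptors tracked with
high-resolution GPS and tri-axial accelerometry. It is written for movement
ecologists who need the full chain from raw Movebank-style CSV streams to
per-segment flight parameters, session summaries and fitted mixed models,
with every stage testable against synthetic data carrying known injected
effects.

## What the pipeline computes

1. **Behavioural segmentation.** Static acceleration is estimated per axis
   by a centred 0.5 s running mean; the dynamic remainder gives per-sample
   **VeDBA** = √(d²ₓ + d²ᵧ + d²_z), averaged per second. An exact 1-D
   k-means (k = 2) on per-second VeDBA separates *active* (flapping) from
   *passive* flight; a second k-means on 15 s-smoothed GPS vertical speed
   separates *soaring* (climbing) from *gliding*. Crossing the two labels
   yields four classes; runs of ≥ 5 consecutive same-class fixes (at 1 Hz)
   become behavioural segments.
2. **Per-segment flight parameters.** Mean vertical and horizontal speed,
   maximum height a.s.l., mean VeDBA, glide ratio (horizontal distance per
   metre of height drop, gliding only) and **airspeed** from the wind
   triangle: with wind support *ws* and crosswind *cw* relative to the
   travel direction, airspeed = √((v_ground − ws)² + cw²). Segments with
   mean horizontal speed ≤ 4 m/s are discarded; glide-ratio analyses keep
   only segments sinking faster than −0.2 m/s.
3. **Session-level ΔP test.** Per species and parameter *P*, all
   between-harness absolute differences ΔP = |P_i(BP) − P_j(LL)| (groups
   equalised by seeded subsampling) are tested one-sidedly (Wilcoxon
   signed-rank) against the baseline B = mean within-harness absolute
   difference.
4. **Mixed-model battery.** Seven Gaussian LMMs (vertical speed and
   airspeed in soaring and gliding, √glide-ratio, log max height, log
   VeDBA) with harness × species fixed effects, hour of day (centred at
   12:00 UTC) and segment length as covariates, and crossed random
   intercepts for individual and date. The interaction is kept only when a
   likelihood-ratio test on ML refits rejects at α = 0.05; coefficients
   come from the REML fit, with Nakagawa marginal/conditional R².

A synthetic-flight generator (`soarharness.synthetic_flight`) produces GPS
and 25 Hz accelerometry with the same structure — alternating circling
thermal climbs and straight glides, flapping bouts, wind — with harness
effects injectable on climb rate, sink rate and dynamic-acceleration
amplitude, plus a per-second ground-truth channel.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from soarharness import SimConfig, simulate_study, process_study, mixed_models
from soarharness.synthetic_flight import wind_table_for_study

config = SimConfig(n_days=4, session_duration=900, seed=11)   # injects +0.3 m/s
study = simulate_study(config)                                 # leg-loop climb effect
segments, sessions = process_study(
    ((s.gps, s.acc) for s in study.sessions),
    wind=wind_table_for_study(study),
)
print(f"{len(study.sessions)} sessions -> {len(segments)} segments")

spec = mixed_models.default_specs()[0]          # soaring vertical speed
fit = mixed_models.fit_lmm(mixed_models.prepare_model_frame(segments, spec), spec)
print(mixed_models.summary_table(fit))
```

prints

```
59 sessions -> 809 segments
Model: vert_speed_soaring  (response: mean_vert_speed, transform: identity, phase: soaring)
term                                        estimate   (St.Err.)          p
Intercept                                      1.090       0.029  1.85e-309 ***
harness[leg-loop]                              0.294       0.006          0 ***
...
Observations: 426
Marginal R2: 0.84   Conditional R2: 0.87
LRT interaction: chi2=0.75, df=4, p=0.945 (excluded)
LRT harness: chi2=741.22, df=1, p=3.25e-163
```

The intercept recovers the commanded 1.1 m/s climb rate, the
`harness[leg-loop]` estimate recovers the injected +0.3 m/s effect
(0.294 ± 0.006), the spurious interaction is correctly excluded, and the
harness term is overwhelmingly supported. On the same run the log-VeDBA
model estimates −0.095 for leg-loop, i.e. a −9.0 % VeDBA change — matching
the simulated 1.1× dynamic-acceleration penalty of backpacks.

The same pipeline is scriptable from a shell:

```bash
soarharness simulate --config sim.yaml --seed 3 --out data/
soarharness run --gps data/gps --acc data/acc --sessions data/sessions.csv \
                --wind data/wind.csv --out results/
soarharness test-harness-effect --sessions results/sessions_summary.csv
```

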