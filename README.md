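# vsdcontext

Analysis of **long-range contextual interactions** in mesoscopic
voltage-sensitive dye imaging (VSDI) of visual cortex.

When a natural-movie patch drives one cortical location, what does a second,
distant patch do to the local response? With two movies (1, 2) and two
locations (A, B), eight stimulus conditions — four single (A1, B1, A2, B2),
two *coherent* pairs showing the same movie at both locations (A1B1, A2B2)
and two *incoherent* pairs mixing movies (A1B2, A2B1) — plus blank trials
let that question be answered quantitatively. This package implements the
full analysis chain for experimentalists working with such recordings, and a
synthetic generator with known ground truth for validating every step:

1. **Preprocessing** — per-trial divisive prestimulus normalization, blank
   subtraction and blank normalization, trial averaging: evoked ΔF/F.
2. **Spatial modelling** — each condition's time-averaged profile is fitted
   with a constrained superposition of two rotated 2D Gaussians,

   G(x, y) = A·exp(−[(x−μₓ)²/2σₓ² + (y−μ_y)²/2σ_y² + ρ(x−μₓ)(y−μ_y)]),

   all 12 parameters simultaneously, centers box-constrained at the two
   peak-response locations (trust-region-reflective least squares).
3. **Contextual metrics** — per (location, movie) comparison cell:
   total facilitation 100·(A_coh−A_dir)/A_dir, its superadditive component
   100·(A_coh−A_dir−A_ind)/A_dir, the linear remainder 100·A_ind/A_dir,
   coherent-vs-incoherent specificity, and spread changes (σₓ, σ_y, joint
   spread √(σₓσ_y)) — each with percentile-bootstrap CIs (1000 reps,
   α = 0.05) and Wilcoxon sign-rank / sign / paired-t p-values.
4. **Time courses** — top-5th-percentile ROIs from the no-context
   conditions, per-type median traces at 200 Hz with per-bin sign-rank
   tests, and cross-location correlations r_single, r_coherent,
   r_incoherent.

It reads the deposited EVO MAT format ([space, time, condition] with
column-major space) and round-trips its own NPZ/CSV/JSON outputs.
See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
import vsdcontext as v

cfg = v.SyntheticConfig.small(seed=11)          # 32 x 64 px demo grid
result = v.run_synthetic_experiment(cfg)        # generate -> dF/F -> fits -> ROIs

fit = result.fits["A1B1"]
print(f"A1B1 spot A: A={fit.gA.A:.2e} dF/F, center=({fit.gA.mu_x:.1f}, {fit.gA.mu_y:.1f}), "
      f"sigma=({fit.gA.sigma_x:.2f}, {fit.gA.sigma_y:.2f}) px, r_fit={fit.r_fit:.3f}")

fac, spread = v.metrics_across_experiments([result], seed=0)
for name in ("total_fac_pct", "superadd_pct", "linear_pct", "specificity_pct"):
    e = fac.estimates[name]
    print(f"{name}: {e.point:5.1f}% [{e.ci_lo:5.1f}, {e.ci_hi:5.1f}]  p_signrank={e.p_signrank:.3f}")
print(result.correlations.round(3).to_string(index=False))
```

prints

```
A1B1 spot A: A=4.94e-04 dF/F, center=(31.6, 8.0), sigma=(2.52, 2.94) px, r_fit=0.944
total_fac_pct:  44.8% [ 42.0,  48.7]  p_signrank=0.125
superadd_pct:  39.8% [ 33.4,  44.3]  p_signrank=0.125
linear_pct:   5.0% [ -1.4,  10.5]  p_signrank=0.375
specificity_pct:  20.6% [ 19.6,  21.2]  p_signrank=0.125
 movie  r_single  r_coherent  r_incoherent
     1     0.699       0.858         0.288
     2     0.669       0.821         0.188
```

The generator injected a coherent facilitation gain of 1.45 (→ 45 % total
facilitation), an incoherent gain of 1.2 (→ ~21 % specificity) and a 3 %
indirect leak; the fitted dual-Gaussian model recovers them from the raw
trial stacks. One experiment has only 4 comparison cells, so the exact
sign-rank test bottoms out at p = 0.125 — pool several experiments (as the
acceptance script does) for meaningful paired tests. The correlations show
the coherent context raising cross-location trace similarity above the
drive correlation (0.6) while incoherent pairs fall to the lateral-coupling
floor.

The same stages are available as a CLI:

```sh
vsdcontext simulate --out sim/ --seed 3
vsdcontext preprocess --in sim/ --out evoked.npz --ys 32 --xs 64
vsdcontext fit --evoked evoked.npz --out fits.json
vsdcontext metrics --evoked evoked.npz --out metrics.csv
vsdcontext timecourse --evoked evoked.npz --out traces.csv
vsdcontext load --evo experiment.mat --out data/   # deposited EVO files
```

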