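# casig — calcium signature analysis for ecotype discrimination

`casig` is a Python package for analysing NaCl-induced cytosolic calcium
signatures measured by aequorin luminometry in *Arabidopsis thaliana*
seedlings. Salt-responsive accessions such as Col-0 answer a NaCl stimulus
with a **biphasic** [Ca²⁺]_cyt signature — an immediate transient (~20 s)
followed by a second transient between 30 and 120 s — while less responsive
accessions such as C24 show only the initial rise. The package turns raw
photon-count traces (or simulated ones) into two-window amplitude features
and asks, quantitatively, how well those features discriminate the two
genotype classes.

It is aimed at plant stress-signalling groups running whole-seedling
luminometer assays, and at anyone who wants a fully reproducible,
end-to-end reference implementation of this analysis.

## The analysis

1. **Calibration.** Aequorin photon counts are converted to [Ca²⁺]_cyt via
   the empirical rate-constant calibration
   `k_t = counts_t / (remaining_t · Δt)`,
   `pCa = 0.332588 · (−log₁₀ k) + 5.5593`, where `remaining_t` is the
   terminal-discharge yield plus all counts from *t* onward. The inverse map
   is the forward model of the simulator.
2. **Features.** Replicate curves are averaged per condition, then each
   averaged curve is reduced to the within-window ranges
   `A₁ = max − min` on (0, 30] s and `A₂ = max − min` on (30, 120] s;
   the feature vector is `x = (log₁₀ A₁, log₁₀ A₂)`.
3. **Discrimination.** Two-group linear discriminant analysis with pooled
   covariance `S` (divisor `n₁+n₂−2`) and sample linear functions
   `d_g(x) = x̄_gᵀS⁻¹x − ½ x̄_gᵀS⁻¹x̄_g + ln π_g`; the decision statistic is
   `D(x) = d₁(x) − d₂(x)`. Performance is reported as jackknifed
   (leave-one-out) posterior probabilities of each observation's own group.
4. **Synthetic data.** Because raw luminometer data of this kind are rarely
   deposited, the package ships a generator that emulates the experiment:
   alpha-pulse transients, saturating dose response
   `A₁(c) = A_max·c/(c+K)`, seedling-to-seedling amplitude and second-peak
   timing variability, Poisson photon shot noise, and aequorin pool
   consumption. See `docs/methods.md` for every parameter and default.

## Worked example

```python
import casig

report = casig.run_pipeline({"seed": 1}, out_dir="out")
print(report.feature_table.query("stimulus == 'nacl' and concentration_mM == 200")
      [["genotype", "amp1_nM", "amp2_nM"]])
print(report.jackknife_table.loc[5, ["stimulus_mM", "col0_posterior", "c24_posterior"]])
```

prints (seed 1):

```
     genotype     amp1_nM     amp2_nM
5   col0_like  751.976641  572.205508
31   c24_like  820.102876   17.439987
stimulus_mM       200.0
col0_posterior      1.0
c24_posterior       1.0
Name: 5, dtype: object
```

The col0-like curve at 200 mM NaCl has a first-peak amplitude near 800 nM
and a large second amplitude (the delayed transient); the c24-like curve has
a comparable first peak but only a small second-window range left over from
the decay of the initial transient plus shot noise. The jackknifed posterior
probabilities at 200 mM are at the ceiling: held-out observations of either
genotype are assigned to their own group with near certainty.

The same pipeline is available from a shell:

```sh
casig simulate --config cfg.yaml --out out/ --plots
casig analyze --traces out/traces.csv --config cfg.yaml --out reanalysis/
casig report --features out/features.csv --out refit/
```

`cfg.yaml` needs at least `seed: <int>`; every other key
(concentration grid, replicate count, aequorin pool, calibration constants,
LDA priors, per-genotype profile overrides) has a documented default
(`casig.pipeline.DEFAULT_CONFIG`).

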