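# statedyn

Dynamic functional-connectivity (DFC) brain-state analysis for intensive
single-subject fMRI studies of advanced absorptive meditation — and for any
design with many runs of ordered, stage-annotated states plus control runs.

The scientific question the package addresses: do recurring whole-brain
connectivity patterns ("brain states") distinguish deep concentrative
meditation (jhana stages J1–J8, preceded by access concentration and
followed by an afterglow) from non-meditative control tasks, how do those
states wax and wane across the stage sequence, and do they track first-person
experience reports?

The analysis core:

* **Sliding-window connectivity.** For each run with node timecourses
  x₁…x_N (TR = 2.9 s), Fisher-z correlations ẑᵢⱼ = atanh(corr_w(xᵢ, xⱼ))
  are computed in tapered windows of 16 TRs (46.4 s; rectangle ⊛ Gaussian,
  σ = 3 TRs), step 1 TR.
* **Brain states.** Window edge vectors from all runs and conditions are
  pooled and clustered with L1 k-means; the number of states K comes from the
  elbow of the within-cluster dispersion curve; single-run noise states are
  pruned by a roughness rule.
* **Dynamic measures.** Per run and state: fractional occupancy, episode
  count, mean dwell time, switch proportion, and transition matrices;
  meditation runs are contrasted against the averaged control reference with
  one-sample t tests and BH-FDR.
* **Trajectories.** Mixed-effects logistic models of state presence,
  logit P(state s present in run i, stage t) = β₀ + β₁·t + uᵢ,
  uᵢ ~ N(0, σᵤ²), fit by Gauss–Hermite marginal maximum likelihood;
  k-modes clustering of dominant-state trajectories.
* **Neurophenomenology.** Pearson correlations between 1–10 self-report
  ratings and state dynamics, plus canonical correlation analysis with
  Hotelling's trace.

Because real data of this kind are restricted, the package includes a
first-class synthetic-study generator (`statedyn.synthetic`) with planted
covariance-template states, stage-conditioned sticky Markov dynamics, and
ratings statistically coupled to the latent state dynamics — every pipeline
stage is validated against that ground truth. See `docs/methods.md` for the
model and all numerical choices.

## Worked example

```python
from statedyn import (SynthStudyParams, simulate_study, make_taper,
                      windowed_connectivity, pool_windows, estimate_k,
                      fit_states, measures_table, contrast_dynamics)

study = simulate_study(SynthStudyParams(seed=0))      # 27 meditation + 4 control runs
taper = make_taper()                                   # 16-TR tapered Gaussian window
series = [windowed_connectivity(tc, taper) for tc in study.runs]
pooled, prov = pool_windows(series)                    # ~4,950 windows x 1,176 edges

k, curve = estimate_k(pooled, 2, 8, seed=0)            # elbow criterion
model, seqs = fit_states(pooled, prov, k, seed=0,
                         runs_by_id={tc.run_id: tc for tc in study.runs})

meas = measures_table(seqs, model.retained_ids)
med = meas[meas.condition == "meditation"]
ctl = meas[meas.condition != "meditation"]
print(f"selected K = {k}")
print(contrast_dynamics(med, ctl)[["measure", "meditation_mean",
                                   "control_mean", "difference", "p_fdr"]]
      .head(4).to_string(index=False))
```

Output:

```
selected K = 3
          measure  meditation_mean  control_mean  difference        p_fdr
state1_proportion         0.296066      0.000000    0.296066 1.430798e-06
  state1_episodes         1.481481      0.000000    1.481481 5.009168e-07
     state1_dwell        36.541667           NaN         NaN          NaN
state2_proportion         0.240166      0.965232   -0.725066 2.588860e-15
```

The elbow recovers the three planted states. State labels are arbitrary
cluster indices — in this run the fitted "state 2" is the sparse,
control-dominant template (96.5% of control window positions) while fitted
state 1 is meditation-specific (29.6% of meditation positions, entirely
absent from controls, dwell ≈ 37 window positions). Absent states report
dwell as missing, never zero, so the state-1 dwell contrast has no control
reference and is NaN by design. Match labels to templates by centroid
similarity when comparing against ground truth.

The same pipeline runs end to end from the shell:

```bash
statedyn simulate --seed 7 --out study/
statedyn validate study/
statedyn run --study-dir study/ --out out/ --seed 7
statedyn report out/
```

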