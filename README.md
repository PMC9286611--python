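# scrhybrid

Spatially explicit density estimation for animal populations whose members
are identifiable to different degrees — from not at all (camera counts of
unmarked animals) to fully (genotyped scats) — with a hybrid joint model
that combines live-capture marking histories, camera resights and counts,
genetic detections and GPS telemetry in one hierarchical posterior.

The package is aimed at wildlife ecologists estimating carnivore densities
from camera grids, scat-detection-dog surveys and collaring programs, and at
methodologists who want the whole model family testable against simulation.

## Models

All variants share the spatial capture–recapture skeleton: latent activity
centers s_i uniform over a state space of area A, data augmentation
z_i ~ Bernoulli(ψ) for i = 1..M, abundance N = Σ z_i, density D = N/A, and a
half-normal detection kernel

    p_ij = p0 · exp(−d_ij²/(2σ²)),   λ_ij = λ0 · exp(−d_ij²/(2σ²)),

with baseline p0/λ0 and spatial scale σ (a home-range proxy).  Implemented
variants: spatial count (SC), spatial presence–absence (SPA), spatial
mark–resight (SMR), generalized SMR with a binomial SCR submodel for the
physical marking process (gSMR), single-occasion genetic SCR with a
logit-linear survey-effort covariate on p0, gSMR+SCR ("hybrid") with shared
z, s and σ across all streams, and optional GPS-telemetry integration
(fixes ~ Normal₂(s_i, σ²I)) in every variant.  Detection parameters and σ
can vary by sex or by behavioral status (resident/transient).

Inference is by data-augmentation MCMC (Metropolis-within-Gibbs, compiled
with numba), with split-chain R-hat convergence gating, HPDI/BCI/mode
summaries, CV-based precision comparison across models, and augmentation
adequacy checks.  See `docs/methods.md` for the full model and sampler
account.

## Worked example

```python
from scrhybrid import (MCMCConfig, ModelSpec, fit, reference_scenario, simulate)
from scrhybrid.summary import density_summary, summarize

# one synthetic data set from the reference scenario:
# 60 animals (15.0 / 100 km^2) in 400 km^2, sigma = 1500 m
bundle, truth = simulate(reference_scenario(), seed=1)
print(len(truth.marked_ids), "collared,", len(truth.genotyped_ids), "genotyped,",
      int(bundle.counts.n.sum()), "unmarked camera detections")

draws = fit(ModelSpec("hybrid", M=120, use_telemetry=True), bundle,
            MCMCConfig(n_chains=3, n_iter=10000, n_burn=3000, seed=1))
d = density_summary(draws.flat("N"), draws.area_km2)
s = summarize(draws, "sigma")
print(f"D mode {d.mode:.1f}/100 km2  95% BCI ({d.bci95[0]:.1f}, {d.bci95[1]:.1f})  CV {d.cv:.2f}")
print(f"sigma mode {s.mode:.0f} m   95% BCI ({s.bci95[0]:.0f}, {s.bci95[1]:.0f})")
print("max R-hat", round(max(draws.rhat.values()), 3))
```

prints

```
9 collared, 18 genotyped, 37 unmarked camera detections
D mode 11.6/100 km2  95% BCI (8.5, 16.5)  CV 0.17
sigma mode 1504 m   95% BCI (1460, 1548)
max R-hat 1.043
```

The 95% interval covers the generating density (15.0/100 km²) and the
kernel scale is pinned tightly by the 900 GPS fixes; the mode sits below the
truth here because a single replicate's detections underrepresent the
periphery of the state space.

The same workflow is available from the shell:

```sh
scrhybrid simulate --seed 1 --out data/
scrhybrid fit --config run.yaml --variant hybrid --telemetry --out runs/hybrid
scrhybrid compare runs/hybrid runs/scr
```

`run.yaml` names the input CSVs (detectors, photo events, scats + effort,
captures, GPS fixes), the variant, priors, augmentation size M and MCMC
settings; `compare` tabulates posterior modes, percent differences and CVs
across fitted runs.

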