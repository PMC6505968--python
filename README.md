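# brainabc

Likelihood-free Bayesian analysis for systems-level models of brain
haemodynamics and metabolism observed through near-infrared spectroscopy
(NIRS). The package is aimed at researchers who drive mechanistic brain
models with systemic recordings — arterial blood pressure (ABP), arterial
oxygen saturation (SaO2) and CO2 tension (PaCO2) — and want parameter
*distributions*, not point estimates, for outputs such as the tissue
oxygenation index (TOI), haemoglobin concentration changes (ΔHbO2, ΔHHb,
ΔHbT, ΔHbD) and cytochrome-c-oxidase redox changes (ΔCCO).

The workflow has three stages:

1. **Sensitivity screening** — Morris elementary effects over parameter
   ranges of default ±50%, summarising each simulated channel by its scaled
   baseline-to-peak distance

       SBTP(y) = max(|max y − y(0)|, |min y − y(0)|) / (max y₀ − min y₀),

   so that channels spanning tens of percent and tenths of a μM compete
   fairly; parameters are ranked by μ*, the mean absolute elementary effect.
2. **Rejection ABC** — sample θ* from uniform priors, simulate, and keep
   either all draws with summed per-channel NRMSE below a tolerance ε, or
   the fixed fraction with the smallest distances (e.g. 0.01% of 30 million
   draws ⇒ a 3000-sample posterior), where
   NRMSE(x₁, x₂) = RMSE(x₁, x₂)/(max x₁ − min x₁).
3. **Posterior checks** — a posterior predictive band from 25 resampled
   draws (pointwise median and 95% credible interval), autocorrelation and
   residual/Q-Q comparisons per channel, and per-parameter information gain
   KL(posterior ‖ prior) in nats.

Two models ship with the package: a closed-form toy model
y = a·x·sin(x) + b + ε used to motivate the SBTP statistic, and
`minibrain`, a compact four-state surrogate of brain circulation, oxygen
transport and mitochondrial metabolism with the standard parameter set
(σ_coll, R_auto, R_autc, n_h, r_t, mu_max, n_m, r_m, P_v, phi, Xtot, K_σ,
p_tot, k_aut, v_cn, σ_e0, k2_n). Its vessel wall balances distending
pressure against elastic tension and a bell-shaped active muscular tension
T_m = T_max·exp(−|(r − r_m)/(r_t − r_m)|^{n_m}); lowering r_t widens the
bell (a stiffened vessel) and is the single change defining the bundled
"impaired" state. See `docs/methods.md` for the full model description and
the calibration rationale.

## Worked example

Fit three parameters of the surrogate to a synthetic healthy hypoxia
challenge (SaO2 ramped 97 → 65 → 97%, ABP and PaCO2 held at 100/40 mmHg)
and inspect the posterior:

```python
from brainabc.models import get_model
from brainabc.protocols import ProtocolSpec, gen_hypoxia_protocol
from brainabc.rejection import PriorSet, fit

inputs, outputs = gen_hypoxia_protocol(ProtocolSpec(state="healthy"))
observed = inputs.with_channels(outputs.channels)

priors = PriorSet({"r_t": (0.009, 0.027), "R_auto": (0.75, 2.25),
                   "Xtot": (4.55, 13.65)})
post = fit(get_model("minibrain"), observed, priors,
           ["TOI", "DHbO2", "DHHb", "DCCO"], n=20_000, seed=11, rate=0.005)
print(post.n_accepted, post.median(), post.distance_min, post.distance_max)
```

Output:

```
100 {'r_t': 0.01813, 'R_auto': 1.540, 'Xtot': 9.04} 0.0096 0.0601
```

100 of 20 000 draws are accepted (rate 0.5%); the posterior median recovers
the generating values r_t = 0.018 cm, R_auto = 1.5 and Xtot = 9.1 mM, and
the accepted summed-NRMSE distances span 0.0096–0.060. Refitting data
generated in the impaired state returns a median r_t of ≈ 0.0132 cm with an
interquartile range disjoint from the healthy one — the two physiological
states are distinguishable from their posteriors alone.

The same pipeline is scriptable from the shell:

```bash
brainabc gen-data --state healthy --seed 3 --out-prefix demo
brainabc sense --inputs demo_inputs.csv --parameters all --seed 4 --out sense.csv
brainabc fit --observed observed.csv --priors priors.yaml \
             --channels TOI,DHbO2,DHHb,DCCO --n 100000 --rate 0.001 \
             --seed 5 --out posterior.csv
brainabc check --posterior posterior.csv --observed observed.csv \
               --priors priors.yaml --channels TOI,DHbO2 --seed 6 --out report.json
```

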