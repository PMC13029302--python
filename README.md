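# qbdopt

Response-surface modelling and multi-objective optimization for
Quality-by-Design (QbD) pharmaceutical formulation development.

The package grew out of a concrete problem: optimizing a clonazepam-loaded
solid self-emulsifying drug delivery system (S-SEDDS), where a liquid
lipid/surfactant pre-concentrate is adsorbed onto a porous lactose/Aerosil
carrier. Four factors — drug concentration (F1), adsorbent ratio (F2),
SEDDS percentage (F3) and blending method (F4) — drive three competing
critical quality attributes:

- **z1** — angle of repose (deg), a powder-flowability proxy, *minimize*;
- **z2** — blending efficiency, the CV of drug content across aliquots, *minimize*;
- **z3** — drug recovery (% of theoretical load), *maximize*.

No single setting satisfies all three: raising the SEDDS fraction boosts
recovery but degrades flow and blend homogeneity. `qbdopt` implements the
full decision pipeline:

1. **Design + model.** A 27-run, 4-factor Box–Behnken design (24 edge runs
   + 3 centre replicates) on the coded cube, with bespoke polynomial term
   sets fitted by OLS: `ResponseSurfaceModel(table, response, terms).fit()`
   returns a results object with coefficients, standard errors, t/p values,
   R², adjusted R² and MSE. The 27-run study ships as a bundled CSV.
2. **Desirability.** Each response *z_i* maps to d_i ∈ [0,1] via one-sided
   Derringer ramps raised to a stringency exponent *s*
   (STB: d = ((U−z)/(U−T))^s on [T,U]; LTB: d = ((z−L)/(T−L))^s on [L,T]),
   aggregated as D = (∏ d_i^{w_i})^{1/∑w_i} and maximized over the mixed
   factor domain; a sweep over *s* probes the robustness of the optimum.
3. **Weighted goal programming (WGP).** A payoff matrix of single-response
   optima fixes the ideal/anti-ideal points; aspiration levels T_i and
   reciprocal-priority weights w_i define the achievement function
   G = ∑ (w_i/T_i)·(unwanted deviation), with deviation pairs
   n_i = max(T_i−z_i, 0), p_i = max(z_i−T_i, 0); minimizing G yields an
   explicit, deviation-quantified compromise.
4. **Design space.** Overlay feasibility masks (e.g. z1 ≤ 40°, z2 ≤ 0.12,
   z3 ≥ 90 %) over any 2-D slice of the domain, with optimizer solutions
   marked in or out of the admissible region.

Both optimizers run on a deterministic mixed-domain solver (exact
enumeration of the discrete levels × seeded grid + Nelder–Mead polish on
the continuous square), cross-checked against an exhaustive grid oracle.
Quality metrics (angle of repose from cone geometry, CV, recovery, and the
Ph.Eur. 2.9.6 content-uniformity acceptance value AV = |M−X| + k·s) and a
synthetic-study generator with known polynomial ground truths round out
the toolkit.

## Worked example

```python
import qbdopt as q

study = q.clz_sedds_study()                      # bundled 27-run BBD
fit = q.fit_ols(study, "z3", q.cr_terms())       # drug-recovery surface
print(fit.params.round(2))
# 1       76.40
# F1       7.02
# F3      34.59
# F4      -3.45
# F1^2    -1.66
# F3^2    -1.67
```

The intercept (76.4 %) is the predicted recovery at the centre point; the
large positive F3 coefficient (+34.6 per coded unit) makes the SEDDS
fraction the dominant driver of recovery.

```python
domain = q.MixedDomain.from_space(q.clz_sedds_space())
models = q.published_models()                    # as-published equations

res = q.optimize_wgp(models, q.clz_sedds_goals(), domain,
                     space=q.clz_sedds_space())
print(res.report().round(3), f"\nG = {res.achievement:.5f}")
#           optimal_value    n      p
# response
# z1               41.675  0.0  6.675
# z2                0.120  0.0  0.000
# z3               98.451  0.0  8.451
# G = 0.03814
```

The blending and recovery aspirations (z2 ≤ 0.12, z3 ≥ 90) are met — the
recovery over-achievement p3 = 8.45 is a *wanted* deviation and costs
nothing — and the entire compromise is absorbed by a quantified violation
of the flowability goal (p1 = 6.68 above the 35° aspiration). The
deviation report makes the trade-off explicit instead of hiding it in a
composite score.

A `qbdopt` command-line tool exposes the same pipeline
(`fit`, `optimize`, `payoff`, `overlay`, `simulate`, `qc`), e.g.

```bash
qbdopt fit --response z3 --terms cr --out-model cr.json
qbdopt optimize --mode wgp --models as-published --out results/wgp
```

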