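# funnelmorph

Geometric-morphometric analysis of **developmental funneling**: do the shape
effects of discrete developmental perturbations (a bigger brain, a shorter
chondrocranium, an overall change in growth) line up with the axes along
which normal cranial shape varies?

The package is built for landmark-based craniofacial data — e.g. 3D
coordinates of homologous skull landmarks in mice or humans — and implements
the full chain:

1. **Generalized Procrustes Analysis (GPA).** Configurations are centered,
   scaled to unit centroid size and iteratively rotated to a consensus;
   aligned shapes are projected orthogonally onto the tangent space at the
   consensus, where ordinary multivariate statistics apply.
2. **Size predictors.** Brain size as the cube root of endocranial volume
   (mm), chondrocranial length as the hormion–opisthocranion distance (mm),
   overall size as the natural-log centroid size.
3. **Pooled-within-sex shape regression.** With tangent coordinates
   `Y` (n × kd) and predictor `x`, both centered by sex means, the model is
   `Ỹᵢ = x̃ᵢ β + εᵢ` with one coefficient vector
   `β = Σᵢ x̃ᵢ Ỹᵢ / Σᵢ x̃ᵢ²`. Reported: percent of total shape variance
   explained `100·Σ‖x̃ᵢβ‖²/Σ‖Ỹᵢ‖²`, projection scores
   `⟨Yᵢ − consensus, β/‖β‖⟩`, and a within-sex permutation p-value.
4. **Mutant contrasts.** After a joint superimposition, a mutation's average
   effect is `alt mean − ref mean`; its size is the Procrustes distance
   `‖Δ‖`, tested by permuting group labels.
5. **The funneling comparison.** The regression predicts the shape change
   for the mutant's measured predictor shift (`|Δx|·‖β‖` Procrustes units);
   the report gives observed vs predicted distance, their ratio, and the
   angle between the mutation's effect vector and the regression vector in
   the shared shape space.
6. **Thin-plate spline deformation grids** (kernel `U(r) = r² log r`) and
   wireframes for visualizing effect vectors and regression extremes in a
   chosen projection plane, with an explicit magnification factor.
7. **A synthetic-data generator** that draws landmark populations with
   exactly this generative structure (template shape, linear latent effects,
   sexual dimorphism, isotropic landmark noise, nuisance similarity
   transforms), so every stage is testable against known truth.

## Worked example

```python
import numpy as np
import funnelmorph as fm

# a wildtype-like population (n=48) plus a growth-deficient mutant group
# (n=11) whose overall size is 14.5% smaller
spec = fm.mouse_study_spec(seed=1, n=48)
delta = float(np.log(1 - 0.145))               # on the log-centroid-size scale
pair = fm.simulate_mutant_pair(spec, n_mutant=11,
                               predictor="log_centroid_size", delta=delta)
pair = fm.measure_predictors(pair)

res = fm.gpa(pair)                             # joint superimposition
meta = pair.metadata
wt = (meta["group"] == "wildtype").to_numpy()

model = fm.pooled_within_regression(
    res.aligned[wt], meta.loc[wt, "overall_size"].to_numpy(),
    meta.loc[wt, "sex"].to_numpy(), n_perm=4999, seed=2,
    predictor_name="overall_size")
con = fm.group_contrast(res, meta["group"].to_numpy(),
                        "wildtype", "mutant", n_perm=4999, seed=3)
shift = fm.predictor_shift(meta, "overall_size", "wildtype", "mutant")
print(f"variance explained {model.percent_var:.2f}%  p={model.p_value:.4f}")
print(f"observed distance  {con.distance:.4f}  p={con.p_value:.4f}")
print(f"predicted distance {fm.predicted_shape_change(model, shift):.4f}")
```

```
variance explained 12.89%  p=0.0002
observed distance  0.0378  p=0.0002
predicted distance 0.0453
```

Reading: overall size (allometry) explains ~13% of normal shape variance in
this sample, highly significant under 4999 within-sex permutations.  The
mutant group sits 0.038 Procrustes units from the wildtype mean — close to
the 0.045 units the normal allometric regression predicts for its measured
size shift.  An observed/predicted ratio near 1 is the funneling signature:
the mutation's shape effect runs along the normal covariation axis.

The same pipeline is available from the shell:

```bash
funnelmorph simulate --config analysis.yaml --out data/
funnelmorph analyze  --config analysis.yaml --out results/
```

where `analysis.yaml` declares either input files (TPS or CSV landmarks plus
a metadata CSV) or a simulation spec, the predictors, the contrasts and the
permutation/seed settings; `results/report.json` records every statistic
with seeds and conventions.

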