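# epistrat

Quantitative analysis of **3D cell-division orientation and daughter fate in
stratifying epithelia**, built for the developing mouse epidermis and any
tissue where a basal progenitor layer divides both within and out of the
epithelial plane.

During epidermal stratification, basal progenitors divide either parallel to
the basement membrane (self-renewal: two basal daughters) or obliquely /
perpendicularly (stratification: one daughter moves suprabasally and
differentiates). `epistrat` turns tracked nuclear centroids and segmented
cell shapes into the quantities this biology is measured with:

- **Division elevation** between telophase daughter centroids,
  Θ = arcsin(|Δz| / ‖Δ‖) ∈ [0°, 90°], classified as planar (Θ ≤ 20°),
  oblique (20° < Θ ≤ 70°) or perpendicular (70° < Θ ≤ 90°).
- **Positional fate** over a 1.5 h post-division tracking window: symmetric
  (both daughters basal) vs asymmetric (exactly one daughter suprabasal),
  with a persistence rule that guards against single-frame z jitter.
- **Interphase morphometrics**: cross-sectional area, apical–basal height,
  longest planar axis, height:width (H:W) ratio, elongation nematic,
  polygon (neighbour-number) class, packing density, mitotic index, tissue
  thickness — and the per-division alignment between the division axis and
  the interphase long axis (Hertwig's rule in 3D).
- **Junctional planar-cell-polarity** as a nematic order parameter,
  z = Σ I·e^(2iφ) / Σ I per cell, averaged over the tissue and rendered as
  rose plots.
- **A restricted-range two-sample Kuiper test** for angle distributions on
  [0°, 90°]: V = D⁺ + D⁻ with D⁺ = max(F̂₁ − F̂₂), D⁻ = max(F̂₂ − F̂₁) over
  pooled breakpoints, with exact-by-construction permutation inference
  (default) or the classical asymptotic tail.

Because raw microscopy is rarely shareable, the package includes a
**synthetic basal-layer generator** (`epistrat.synthetic`): centroidal
Voronoi cell packing, heights, nuclear tracks with divisions and fates,
and polarized edge-intensity fields — all with known ground truth, so every
analysis stage is validated by parameter recovery.

## Worked example

```python
from epistrat import SimulationConfig, analyze_tracks, kuiper_two_sample, simulate
from epistrat.division import category_proportions

wt = SimulationConfig(angle_mixture=(0.51, 0.29, 0.20), n_divisions=150,
                      field_width=200, field_height=200, n_frames=16, seed=1)
mut = wt.replace(angle_mixture=(0.27, 0.39, 0.34), seed=2)

events = {}
for name, cfg in (("wildtype", wt), ("crowded", mut)):
    ds = simulate(cfg)                       # tracks, divisions, shapes, edges
    ev = analyze_tracks(ds.tracks, basal_threshold=cfg.basal_threshold)
    events[name] = ev
    props = category_proportions(ev["angle_deg"].to_numpy())
    print(f"{name}: n={len(ev)} divisions, "
          + ", ".join(f"{k} {100*v:.1f}%" for k, v in props.items()))

res = kuiper_two_sample(events["wildtype"]["angle_deg"], events["crowded"]["angle_deg"],
                        method="permutation", n_permutations=10_000, seed=0)
print(f"Kuiper V = {res.V:.3f}, permutation p = {res.p_value:.4f} "
      f"(n1={res.n1}, n2={res.n2})")
```

prints

```
wildtype: n=150 divisions, planar 48.0%, oblique 30.7%, perpendicular 21.3%
crowded: n=150 divisions, planar 27.3%, oblique 36.7%, perpendicular 36.0%
Kuiper V = 0.247, permutation p = 0.0028 (n1=150, n2=150)
```

The two conditions were generated with 51% vs 27% planar divisions; the
pipeline measures each division's elevation from the emitted daughter
tracks, recovers the category proportions to within binomial noise, and the
Kuiper permutation test detects the distributional difference at n = 150
per group.

A command-line interface mirrors the library:

```bash
epistrat simulate --out sim/ --seed 9
epistrat angles  --tracks sim/tracks.csv --threshold-um 10 --out events.csv
epistrat compare --a wt_events.csv --b mut_events.csv --reps 10000 --seed 7
epistrat polarity --edges sim/edges.csv --bin 15
epistrat report  --config pipeline.yaml --out out/
```

## Layout

| module | contents |
| --- | --- |
| `epistrat.division` | angles, categories, fates, histograms, track analysis |
| `epistrat.geometry` | morphometrics, density, thickness, Hertwig alignment |
| `epistrat.kuiper` | restricted-range Kuiper test, Welch-t convenience wrapper |
| `epistrat.polarity` | nematic polarity per cell and per tissue, rose binning |
| `epistrat.synthetic` | ground-truthed generator (packing, tracks, edges) |
| `epistrat.io` / `epistrat.pipeline` / `epistrat.cli` | formats, orchestration, CLI |

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
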