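# rootpore

Tools for studying how wheat roots interact with vertical macropores in
loose versus compacted subsoil, in the repacked-column mesocosm design used
for X-ray CT root phenotyping.

Deep rooting in compacted subsoil often depends on roots finding and
following existing pore networks rather than penetrating the bulk soil.
The experimental unit emulated here is a 64 mm × 170 mm soil column whose
bottom 55 mm is packed at 1.2 g cm⁻³ (loose) or 1.6 g cm⁻³ (compacted) and
pierced by nine vertical artificial macropores (0.8 mm diameter, 45 mm
long, 10 mm of soil above them); wheat seedlings of two near-isogenic lines
(*Rht-B1a* tall, *Rht-B1c* dwarf) are planted 20 mm deep, and root–pore
interactions are scored from CT scans at 45 μm resolution.

`rootpore` implements the whole analysis loop as reproducible code:

- **geometry** — root centerlines as 3D polylines, pores as cylinders,
  total-least-squares direction fits, surface-to-surface distances;
- **column** — parametric mesocosm construction and voxelization into
  labeled or grayscale phantom volumes;
- **simulate** — an event-driven stochastic generator of root systems whose
  interaction behavior follows packaged per-treatment/per-genotype
  probability profiles, with a ground-truth log per interaction;
- **segment** — seeded region growing, 3D skeletonization, centerline and
  pore-cylinder recovery from volumes;
- **interactions** — the classification rules: an *interaction* is a root
  meeting a pore with ≤ 1 voxel surface separation; *colonize* means > 15 mm
  of root inside the pore after contact (else *cross*); *changed trajectory*
  means the directions fitted over 20 mm of root before and after the
  interaction differ by > 3°, with colonization counting as a change by
  definition;
- **stats** — Shapiro–Wilk, randomized-block ANOVA (`RandomizedBlockAnova`
  model with a statsmodels-style `fit()`/results/`summary()`), least
  significant difference at α = 0.05, and genotype-combined percentages.

## Worked example

```python
import rootpore as rp

spec = rp.ColumnSpec(subsoil_bulk_density_g_cm3=1.6)   # compacted subsoil
pores = rp.build_pores(spec)                            # 9 pores, jig layout
profile = rp.DEFAULT_PROFILES[("compact_1.6", "combined")]

roots, truth = rp.simulate_column(spec, pores, profile, seed=13,
                                  column_id="C000")
events = rp.classify_events(roots, pores, voxel_size_um=45.0)
print(rp.events_to_frame(events)[
    ["root_id", "pore_id", "contact_arclength_mm", "inside_length_mm",
     "classification", "trajectory", "deflection_deg"]
].round(2).to_string(index=False))
```

prints

```
root_id pore_id  contact_arclength_mm  inside_length_mm classification trajectory  deflection_deg
C000_R0      P1                117.24              3.10          cross  unchanged            0.11
C000_R1      P0                105.00             44.47       colonize    changed             NaN
C000_R2      P8                105.33             44.47       colonize    changed             NaN
```

Three interactions were generated for this column.  Root `R0` touched pore
`P1` 117 mm along its length, ran only 3.1 mm inside (a chord through the
pore), and left with its course deflected 0.11° — a *cross* with *no
trajectory change*.  Roots `R1` and `R2` entered pore mouths and followed
the pore axes ~44.5 mm to the column base: *colonizations*, which count as
trajectory changes by definition (their deflection is not measured, hence
`NaN`).

The same pipeline runs from the shell:

```sh
rootpore simulate --seed 0 --out sim/          # 40-column experiment
rootpore analyze --centerlines sim/centerlines.csv --pores sim/pores.csv --out ana/
rootpore stats --events ana/events.csv --columns ana/columns.csv \
               --manifest sim/manifest.json --out report.json
```

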