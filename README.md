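# aeropheno

Aerial multi-sensor phenotyping of field trials: co-register RGB,
blue+near-infrared (B+NIR) and thermal imagery via circular fiducial
markers, segment plants from soil with a blue-band NDVI, extract per-plot
traits, and compute the trial statistics a breeder needs to choose plot
sizes and compare genotypes.

## Who this is for

Field phenotyping groups that fly a camera array (a consumer RGB camera, a
modified two-channel B+NIR "vegetation" camera, and a thermal camera) over
replicated small-plot trials — here a maize split-plot design with 16
genotypes, one- to four-row plots (4 m long, 0.75 m row spacing) and four
replicate blocks — and need a tested, reproducible route from raw 16-bit
TIFF frames to a per-plot trait table and trial-level statistics. Because
no public imagery accompanies this kind of campaign, the package ships a
seeded synthetic scene generator that renders the whole trial with known
ground truth, which doubles as the validation harness.

## The method

**Co-registration.** Round dark metal plates (Ø 0.7 m) on poles around the
field are detected per sensor (blue channel for the optical cameras; the
plates run warm, so bright polarity in the thermal channel) by quantile
thresholding, connected components, and circularity/solidity filters, with
sub-pixel centres from intensity-weighted centroids. Cross-sensor marker
positions can be refined by normalized cross-correlation (NCC) with the
B+NIR marker regions as templates. A projective transform (homography,
fitted by normalized DLT plus geometric least squares) maps each sensor
into a common area-of-interest (AoI) frame with bicubic interpolation;
thermal frames are up-scaled to the optical resolution first.

**Segmentation.** The vegetation index is a blue-band NDVI,

    NDVI = (NIR − B) / (NIR + B),

computed per pixel from the B+NIR camera. Plant pixels satisfy
`NDVI > 0.1` (one threshold for the whole season; it keeps green *and*
senescent tissue, while 0.2 would drop most senescent material) **and**
exceed a per-campaign grey-intensity threshold that removes deep shade.
An HSB (hue/saturation/brightness) interval segmentation is provided for
plain RGB imagery.

**Per-plot traits.** With the plot map rasterized onto the AoI grid, each
plot yields: canopy cover `CC` (plant-pixel fraction), `NDVI_Plot` (median
over all pixels), `NDVI_Plant` (median over plant pixels), the skewness of
the NDVI histogram (population third moment; positive `NDVI_Plot` skewness
flags sparse canopies), the canopy temperature `T_C` (median thermal
signal, unsegmented — the thermal pixel is too coarse to separate plant
from soil), and `dT = T_C − T_A` against the weather-station air
temperature (negative = transpiration cooling).

**Trial statistics.** Within each (campaign × plot-size) stratum the data
form a balanced genotype × block table, so repeatability is estimated by
exact ANOVA variance components with blocks fixed and genotypes random:

    h² = σ²_gen / (σ²_gen + σ²_ε / r),   r = number of blocks (4)

plus Pearson correlations with the usual significance codes
(`***` p<0.001, `**` p<0.01, `*` p<0.05) and Tukey HSD genotype
comparisons at α = 0.05 with compact letter displays. Weather support:
thermal time `TT = Σ max(0, (T_max+T_min)/2 − 8 °C)`, saturation vapour
pressure `SVP(Pa) = 610.7·10^(7.5T/(237.3+T))`, `VPD = (100−rH)/100·SVP`,
and a linear LAI-from-specific-leaf-weight calibration.

## Worked example

Render one mid-season campaign (727 °C d, flowering; all three sensors) of
the synthetic trial at the native ground pixels (0.025 m optical /
0.1 m thermal), run the full pipeline in memory and estimate repeatability:

```python
from aeropheno.scene import (SceneConfig, generate_design, default_profiles,
                             simulate_traits, render_scene, DEFAULT_CAMPAIGNS)
from aeropheno.pipeline import run_campaign
from aeropheno.plot_traits import records_to_frame, seasonal_table
from aeropheno.field_stats import repeatability_profile

cfg = SceneConfig(seed=42, ground_pixel={"BNIR": 0.025, "RGB": 0.0275, "IR": 0.1})
design = generate_design(cfg)
truth = simulate_traits(design, default_profiles(cfg), DEFAULT_CAMPAIGNS, seed=42)
camp = DEFAULT_CAMPAIGNS[3]                      # 727 °C d, with thermal
bundle = render_scene(design, truth, camp, cfg)
records, reg, ndvi, mask, labels = run_campaign(bundle)

df = records_to_frame(records)
print(df[["plot_id", "cc", "ndvi_plot", "ndvi_plant", "t_c", "dt"]].head(3))

table = seasonal_table(records, bundle.plot_map, {camp.id: camp.degree_days})
print(repeatability_profile(table, "cc")[["rows_per_plot", "h2"]])
```

prints (first plots of block 1, four-row strip):

```
  plot_id    cc  ndvi_plot  ndvi_plant    t_c     dt
b1_r4_g03 0.873      0.705       0.713 23.093 -1.307
b1_r4_g00 0.966      0.652       0.653 22.568 -1.832
b1_r4_g05 0.973      0.687       0.689 22.826 -1.574

rows_per_plot     h2
            1 0.8810
            2 0.8745
            3 0.9257
            4 0.9494
```

Reading the numbers: canopies at flowering are nearly closed (`cc`
0.87–0.97), plant NDVI sits near its seasonal plateau (~0.65–0.71), and
plots run 1.3–1.8 °C cooler than the air — transpiration cooling.
Repeatability of canopy cover rises with plot size (0.88 → 0.95 from
one-row to four-row plots), the criterion used to choose how much field
space a genotype deserves. Against the generator's ground truth the
recovered CC is within ±0.02 and `NDVI_Plant` within ±0.006 per plot.

The same stages run file-to-file from a shell:

```bash
aeropheno simulate --seed 42 --out fixtures/ --campaigns c4
aeropheno run --config fixtures/run.json       # register → segment → extract → stats
aeropheno geometry --altitude 300              # Table-style optics summary
```

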