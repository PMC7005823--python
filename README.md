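# phenoprobe

Phenotype profiling for fluorescent-probe imaging screens.

A probe-panel screen images a panel of fluorescent chemical probes (one
per well — lipid stains, organelle markers, ion and stress indicators)
across two experimental conditions, typically a gene knockout (KO) versus
its wild-type parent (WT), with 12 two-channel images (DNA + probe) per
probe.  The analysis question: **which probes reveal a phenotype
difference between the two conditions?**  Probes that do point directly at
the cellular processes the perturbed gene touches.

`phenoprobe` answers it with segmentation-free, whole-image profiling:

1. **Feature bank** — 923 named morphological features per probe-channel
   image, computed on a grid of image transforms (Fourier, wavelet,
   Chebyshev, edge, compound paths) × feature families (pixel statistics,
   multiscale histograms, Haralick and Tamura textures, Gabor energies,
   Zernike moment magnitudes, Chebyshev coefficient histograms, Radon
   statistics, object statistics, comb moments).  No segmentation, no
   per-phenotype tuning.
2. **Feature reduction** — drop low-variance, highly correlated
   (|r| > 0.95, greedy) and collinear (VIF > 10, iterative) features,
   with full per-feature provenance.
3. **Embedding** — one global 2-D t-SNE of the whole screen (z-scored
   features, PCA init, fixed seed).
4. **Ranking** — per probe, the two-cluster Dunn index

       D = min ‖x_KO − x_WT‖ / max(diam KO, diam WT)

   of its KO vs WT images in the global embedding; probes sorted by
   descending D.  Under two treatment arms (e.g. DMSO vs an mTOR
   inhibitor), both arms share one joint embedding and
   `fold_change = D_treated / D_control` per probe.

A classical segmentation-based comparator (nuclei → Distance-N cell
expansion → 237 per-object measurements → per-image means) is included;
it is sensitive to absolute intensity and reproduces the known
false-positive failure mode on unstained probes carrying low-intensity
fluorescent artifacts.

Because public screen images are rarely available, the package ships a
first-class synthetic screen generator: deterministic two-channel TIFF
screens with per-probe staining styles, Poisson-Gaussian noise, known
true-positive probes (KO-side puncta accumulation) and a ground-truth
table, so the whole pipeline is testable end to end.

## Worked example

Simulate a small screen (8 probes, 2 true positives) and rank its probes.
With 12 images per probe, the t-SNE perplexity should be on the order of
the per-condition cluster size (the default 30 suits full-size screens):

```sh
phenoprobe simulate --probes 8 --true-positives 2 --out screen/ --seed 0
phenoprobe extract  --images screen/ --plate-map screen/plate_map.csv --out features.csv
phenoprobe reduce   --features features.csv --out reduced.csv
phenoprobe rank     --reduced reduced.csv --plate-map screen/plate_map.csv \
                    --out ranking.csv --seed 0 --perplexity 5
```

which prints

```
wrote 96 images for 8 probes to screen
wrote 96 x 923 feature matrix
retained 89 of 923 features (provenance: reduced.provenance.csv)
ranked 8 probes; top: NBD cholesterol (Dunn 0.276)
```

and `ranking.csv` starts

```
probe_sku,probe_name,category,dunn_index,rank
N1148,NBD cholesterol,Lipid metabolism and trafficking,0.2759470250566525,1
D3922,BODIPY 493,Lipid metabolism and trafficking,0.18299170514647545,2
D3822,BODIPY FL C12,Lipid metabolism and trafficking,0.15357189067545268,3
...
```

The two simulated true positives (N1148 and D3922 — the probes whose KO
images gained ~25 bright puncta) take ranks 1–2: their KO and WT images
separate in the embedding, while null probes' KO and WT images intermix.
`reduced.provenance.csv` records why each of the 834 dropped features was
removed.

The same workflow in Python:

```python
import phenoprobe as pp
from phenoprobe.pipeline import rank_screen

config = pp.default_screen_config(seed=1)   # 44 probes, 8 true positives
screen_dir, layout = pp.generate_screen(config, "screen44/")
result = rank_screen(screen_dir, mode="charm", seed=1)
print(result["ranking"].head(15))
```

On the default 44-probe screen all 8 true-positive probes land in the
top 15 of the Dunn ranking (ranks 1–8 at seed 1).

## Layout

```
src/phenoprobe/
  screen_model.py            plate maps, probe panel, rankings, CSV I/O
  synthetic_screen.py        deterministic two-channel screen generator
  charm_features.py          923-feature whole-image bank
  segmentation_features.py   nuclei / Distance-N / 237 per-object comparator
  feature_reduction.py       variance, correlation, VIF filters
  embedding_ranking.py       t-SNE, Dunn index, ranking, fold change
  pipeline.py                end-to-end orchestration and plots
  cli.py                     `phenoprobe` command group
docs/methods.md              model, assumptions, parameters, limitations
```
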