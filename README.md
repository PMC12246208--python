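# thoraxgm

Geometric morphometrics of the human ribcage: reconstruction of
incomplete 3D landmark configurations and group comparison, exercised
end-to-end on synthetic thorax data.

Paleoanthropologists who want to place a partially preserved fossil thorax
in the shape and size space of a recent comparative sample face two
problems: most fossil ribcages are incomplete, and the comparative
statistics (centroid size contrasts, shape ordination) require complete,
comparable configurations. This package implements a full landmark-level
workflow for that situation:

1. **Vertebral restoration** by the *vector-of-change* (metamer increment)
   method: the mean 3D displacement between successive thoracic vertebral
   levels, learned from complete control spines, is added to (caudal) or
   subtracted from (cranial) the nearest preserved level.
2. **Kyphosis estimation** by the *TVBHD* method: anterior (A) and
   posterior (P) vertebral body heights are measured from T1 to T12 and
   the ratio ΣA/ΣP enters a linear regression giving the thoracic
   kyphosis angle. The regression coefficients are protocol-specific and
   must be supplied explicitly.
3. **Spine assembly**: vertebral centroids are placed on a circular arc in
   the midsagittal plane whose polyline turning angle equals the kyphosis
   angle — a landmark-level simplification of mesh-based facet
   articulation.
4. **Two-block PLS completion**: on a complete reference sample, the
   full-ribcage block and the partial block (restricted to the fossil's
   preserved points) are each superimposed by GPA in *form space*
   (translation and rotation removed, size in mm retained); the leading
   singular pair (u₁, v₁) of the centered cross-covariance between the
   blocks defines the first latent variable. A fossil aligned to the
   partial-block consensus with score t = ⟨x − x̄, u₁⟩ is completed as
   ŷ = ȳ + β t v₁, with β the least-squares slope of full-block on
   partial-block scores. Preserved material is then spliced back over the
   prediction, so no observed point is ever silently replaced.
5. **Group statistics**: centroid size
   CS = √Σᵢ‖xᵢ − x̄‖² per specimen, permutation tests (default 10,000
   permutations) on |mean difference| with p = (#{perm ≥ obs} + 1)/(n + 1),
   UPGMA clustering of resampling-averaged group-mean distances (Newick
   output), and covariance PCA in shape space with PC-score permutation
   tests. Configurations are symmetrized and ribs 11–12 removed before
   superimposition.

Because real costovertebral scan data must be requested from housing
institutions, the package ships a synthetic thorax generator
(`thoraxgm.synthetic`) that reproduces the statistical structure the
analysis assumes — a 526-point template (12 vertebrae × 4 body corners,
24 ribs × 19 points, 22 sternal points), climate groups (cold ≤ 7 °C,
temperate ≤ 23 °C, warm > 23 °C) with configurable size and
width/depth-ratio effects, bilateral symmetry with a separate
fluctuating-asymmetry field, and built-in preservation masks emulating
the costovertebral preservation states of four well-known fossil/mummy
individuals (complete column, Ötzi-like, Nazlet-Khater-2-like with
vertebrae T1–T5, Ohalo-II-like with ribs 1, 7, 9–12 and vertebrae T1,
T2, T3, T8).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1; outputs under `results/analysis/`):

```bash
python analysis/01_simulate.py     # 59-specimen reference + 2 masked fossils
python analysis/02_reconstruct.py  # metamer + kyphotic arc + PLS completion
python analysis/03_analyze.py      # permutation tests, UPGMA, PCA
python analysis/04_validate.py     # calibration / recovery experiments
```

`02_reconstruct.py` prints, per fossil, how much was observed vs
estimated and the intermediate quantities:

```
ohalo_2: observed 244 points, estimated 282; kyphosis 39.0 deg, PLS score -45.5
nazlet_khater_2: observed 400 points, estimated 126; kyphosis 39.0 deg, PLS score -92.7
```

and `03_analyze.py` reports the group comparison:

```
                 group  n     mean_cs      sd_cs
                  cold 12 2490.689120 159.804988
fossil_nazlet_khater_2  1 2246.245711        NaN
        fossil_ohalo_2  1 2277.510350        NaN
             temperate 29 2395.327937 133.786720
                  warm 18 2157.764272 117.004716
...
                  cold                   warm     332.924848 0.000100           10000
...
shape-space PCA: PC1 67.4% of variance, PC2 16.9%
```

The simulated sample was configured with a monotone cold > temperate >
warm centroid-size gradient; the analysis recovers that ordering, finds
the cold–warm and temperate–warm contrasts significant (p = 1/10001 is
the smallest attainable p at 10,000 permutations), and the two
reconstructed "fossils" — drawn from the temperate and warm groups, then
masked and completed — join the warm cluster in the UPGMA dendrogram.
`04_validate.py` shows that on a noise-free single-factor sample the PLS
completion recovers a held-out masked specimen to ~1e-17 of its centroid
size, and that with measurement noise it beats mean substitution in
20/20 paired replicates (2.3 mm vs 5.2 mm RMS).

The same pipeline is scriptable via the CLI
(`thoraxgm simulate|reconstruct|analyze -c config.yaml`) with a mandatory
seed and a run manifest for bit-identical reproduction.

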