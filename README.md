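# tilestats

Tessellation-based quantification of spatial inhomogeneity in fluorescence
microscopy images of membrane proteins and lipids.

Molecules on the cell surface arrange themselves randomly, in nano- and
micro-scale clusters, or along polarised gradients, and those arrangements
change with signalling, endocytosis and drug treatment. `tilestats` measures
the *degree of inhomogeneity* of such arrangements directly from a
single-channel image — widefield, TIRF, SIM, or a rendered localization
dataset — without requiring knowledge of cluster shape, number, or the
polarity axis.

## How it works

The fluorescent signal is treated as a marked point process. The image is
thresholded; the plane is partitioned into one tile per detected object by
a skeleton-by-influence-zones tessellation (tile boundaries run half way
between neighbouring object *borders*, so object extent is respected);
each tile's area A is corrected by its integrated intensity I through a
correction factor C — the intensity of one detectable fluorescent entity —
by splitting the tile into n = ⌊I/C⌋ equal areas, which restores the
contribution of emitters blurred together by the point-spread function.
The corrected tile areas x are then fitted by the Inverse-Gamma density

    H(x; α, β) = β^α / Γ(α) · x^(−α−1) · exp(−β/x),

whose shape α and scale β are characteristic of the underlying pattern:
both decrease as patterns become more inhomogeneous (random → clustered →
polarised) and increase far above the random values for regular,
equally-dispersed patterns. The fitted (α, β), at the measured area
density ρ = N_A / image area, is compared with simulation-built reference
graphs; the Euclidean deviation from the random reference — normalised so
the random-to-polar-clusters interval equals 1 — is the inhomogeneity
measure, and the nearest reference point classifies the pattern. A
sliding-circle variant produces per-tile local classification maps.

The package includes the full forward simulator (ground-truth point
patterns imaged through a Gaussian PSF with Poisson noise and Gaussian
background) used to build reference graphs and validate the analysis.
See `docs/methods.md` for the complete model description and the design
choices.

## Worked example

Simulate two widefield images of 500 emitters arranged in 240-nm clusters,
build a small widefield reference graph, and analyse:

```
$ tilestats simulate --kind clustered --n 500 --cluster-d 240 \
      --out demo --seed 7 --replicates 2
$ tilestats build-ref --densities 1,3,5 --n-images 10 --out demo/ref.json --seed 0
$ tilestats analyze demo/clustered_000.tif demo/clustered_001.tif \
      --correction quartile1 --ref demo/ref.json --out demo/results
clustered_000.tif: alpha=3.438 beta=2.4619 r2=0.942 rho=1.02 inhomogeneity=0.651
clustered_001.tif: alpha=3.031 beta=1.5598 r2=0.802 rho=1.34 inhomogeneity=0.923
```

The same analysis on images of randomly placed emitters sits at the random
reference point:

```
$ tilestats analyze demo/random_000.tif demo/random_001.tif \
      --correction quartile1 --ref demo/ref.json --out demo/results_rand
random_000.tif: alpha=6.263 beta=1.0442 r2=0.958 rho=4.95 inhomogeneity=-0.074
random_001.tif: alpha=5.943 beta=0.9902 r2=0.827 rho=4.96 inhomogeneity=0.018
```

Reading the numbers: `alpha`/`beta` are the Inverse-Gamma parameters of the
corrected tile-area histogram, `r2` the histogram-fit quality (fits below
0.45 are discarded), `rho` the corrected-area density in areas/µm², and
`inhomogeneity` the signed, normalised deviation from the random reference
— ≈0 for random arrangements, increasingly positive towards clustered and
polarised ones, negative for more-regular-than-random patterns. The
clustered images score 0.65–0.92 while the random ones sit at −0.07–0.02.
Per-image tile tables, a summary CSV and an aggregate JSON (with the full
configuration and its hash) are written to the output directory.

Other entry points: `tilestats local` (sliding-circle classification maps,
magenta = random, green = clusters, red = polar), `tilestats score-pdfs`
(rank candidate densities for the tile-area histogram by r²), and the
Python API (`tilestats.analyze_image`, `tilestats.simulate_and_analyze`,
`tilestats.build_reference_graph`, `tilestats.classify_local`).

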