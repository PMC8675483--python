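# myofuse

Quantification of skeletal-muscle cell cultures from two-channel
fluorescence microscopy: total nuclei and nuclei density (a proxy for cell
viability/growth), and the **myotube fusion index** (the readout of myoblast
differentiation). Input is a DAPI (nuclei) channel plus a myosin-heavy-chain
(MYH) channel marking differentiated cells, as a calibrated multi-page TIFF;
a built-in synthetic scene generator provides ground truth for validation.

Intended for muscle-biology labs quantifying C2C12 (or similar) myotube
cultures, and for anyone who wants the classic threshold → median filter →
fill holes → watershed → size-binned particle analysis as a scriptable
library instead of an interactive macro.

## Method

**Nuclei counting.** The DAPI channel is brightness-multiplied (saturating,
default ×1), binarized with an automatic iterative-intermeans (IsoData)
threshold on a 256-bin histogram, cleaned with a radius-1 binary median
filter, hole-filled, and split with a distance-transform watershed so
touching nuclei separate. Particles are measured and partitioned by area *A*:

- debris: *A* < 50 µm² (ignored),
- singleton nuclei: 50 µm² ≤ *A* ≤ 250 µm² (counted directly),
- nuclear clumps: *A* > 250 µm².

Each clump contributes `max(1, round(A / mode))` nuclei, where `mode` is the
modal singleton area on 1-µm² bins. Then

```
total = n_singles + Σ_clumps round(A_clump / mode)
density = total / image area (mm²)
```

**Fusion index.** The MYH channel is Gaussian-blurred (σ = 2 px),
thresholded, median-filtered and hole-filled to give the myotube mask, which
is subtracted from the watershed-split DAPI segmentation. The surviving
("outside") nuclei are counted with the same two-bin scheme, using the
outside image's own modal area. With *T* total nuclei, *O* outside nuclei
and *S* nuclei in MYH-positive cells with only 1–2 nuclei (which, by the
strict criterion, are not myotubes — *S* is counted by the user, or
optionally estimated automatically):

```
fusion index (%) = (T − O − S) / T × 100
```

## Worked example

```
$ myofuse simulate --kind fusion --n-singles 40 --myotubes 5,4,3 \
      --small-cells 1,2 --seed 3 --out demo --name scene
wrote scene.tif (truth: total 55, outside 40, small 3, fusion index 21.8%)

$ myofuse fusion demo/scene.tif --small 3 --out demo --name result
wrote fusion results for 1 image(s) under demo
```

`demo/result.csv` then contains (abridged):

```
field,value
n_outside_singles,40
outside_total,40
total_nuclei,55
small_myh_nuclei,3
fusion_index_pct,21.81818182
```

reading: the scene holds 55 nuclei in total; 40 lie outside MYH-positive
cells and 3 sit in MYH-positive cells with fewer than three nuclei, so
(55 − 40 − 3)/55 × 100 ≈ 21.8% of nuclei reside in true myotubes.
`demo/result.png` shows the merged channels with nuclei outlines (blue) and
the myotube mask outline (yellow). `myofuse viability` reports the
nuclei-count side alone, `myofuse compare` computes the Pearson correlation
between two per-image result tables.

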