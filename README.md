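# segcond

Putative transcriptional condensates (PTCs) are genomic regions where
multiple enhancer elements coalesce in 3D nuclear space, forming the
membraneless bodies (phase-separated assemblies of transcription factors,
co-factors and PolII) that drive high-level lineage gene expression.
`segcond` predicts such regions by integrating 1D regulatory genomics
tracks (ATAC-seq, histone-mark and TF ChIP-seq coverage) with normalized
chromatin-contact scores from Hi-C, in three stages:

1. **Segmentation.** Coverage tracks are binned on a fixed 5-kb grid,
   depth-normalized, log10 + Z-score transformed and reduced to one
   dimension by PCA (PC1 acts as a joint activity coordinate). Treating
   chromosomal position as pseudo-time, segment boundaries are multiple
   structural breaks of a piecewise-constant mean model: for each break
   count *m* the break positions minimize the residual sum of squares
   exactly (dynamic programming), and *m* is selected by
   BIC(m) = n·ln(RSS/n) + (2m+2)·ln n, subject to a minimum segment size
   (5% of the 1000-bin window, i.e. 250 kb). Chromosomes are scanned in
   overlapping 1000-bin windows stepped by 500, and window-level
   boundaries are merged.
2. **Annotation.** A bin is an *enhancer bin* when both the H3K27ac and
   accessibility tracks have Z ≥ 1. For every segment, an equally sized
   interval is re-placed uniformly across the genome 1000 times; a
   zero-inflated negative binomial (ZINB) fitted to the shuffled counts
   gives P(X ≥ observed), and segments with p < 0.05 and
   log2((obs+1)/(exp+1)) > 0 are *enhancer-enriched*. (On simulated
   backgrounds the ZINB beats NB, Normal and Tobit-Normal alternatives by
   AIC, which is why it is the default.)
3. **Hi-C integration.** Per-contact normalized scores (a SHAMAN-style
   track, or the built-in distance-decay fallback) are pooled per
   intra-/inter-segment pair by the median, for segments within 2 Mb. A
   score cutoff is estimated by permutation (maximize true minus shuffled
   pairs passing), the matrix is binarized, and PTCs are the connected
   components of the resulting graph over enhancer-enriched segments
   (singletons qualify via their intra-segment score).

Downstream helpers classify segments into Condensate / Enhancer / Active
/ Repressed categories and select candidate genes that sit inside
condition-specific PTCs, are expressed (TPM > 0) and have a marked,
accessible promoter (±5 kb).

The package is aimed at regulatory-genomics analysts with binned coverage
(bedGraph/TSV) and a per-contact Hi-C score track; everything is also
scriptable from Python.

## Worked example

The bundled generator plants a ground truth — stepped regional signal,
enhancer-dense regions, and three 3D hubs of 2–3 regions on a 15-Mb
two-chromosome toy genome — so the full pipeline runs in seconds:

```python
from segcond import fixtures, run_pipeline

spec = fixtures.default_fixture_spec(seed=1)
matrix = fixtures.generate_tracks(spec)        # 3000 bins x 4 tracks
contacts = fixtures.generate_contacts(spec)    # scored contact point list
res = run_pipeline(matrix, contacts, seed=1)

print(f"{res.pca.variance_explained_pct:.2f}%")   # 77.85%
print(len(res.segments))                          # 16
print((res.annotations.label == "enhancer_enriched").sum())  # 7
print(res.cutoff)                                 # 19.0
print(len(res.ptcs))                              # 3
```

PC1 captures 77.85% of the track variance; segmentation recovers the 16
planted segments; the 7 enhancer-dense segments are called enriched; the
permutation-estimated score cutoff (19) falls in the gap between the
background score tail (~N(0,1)) and the hub scores (~N(20,1)); and the 3
connected components recovered match the planted hubs exactly
(`fixtures.hub_recovery` reports Jaccard 1.0 for each).

The same steps are available as a CLI:

```sh
segcond simulate --seed 1 --out-dir fx/
segcond binmat --tracks fx/H3K27ac.bedGraph ... --chrom-sizes fx/chrom.sizes -o mat.tsv
segcond segment --matrix mat.tsv -o segments.bed
segcond annotate --matrix mat.tsv --segments segments.bed --seed 1 -o annot.tsv
segcond cutoff --contacts fx/contacts.tsv --segments segments.bed --chrom-sizes fx/chrom.sizes
segcond ptc --contacts fx/contacts.tsv --segments segments.bed --annot annot.tsv \
    --chrom-sizes fx/chrom.sizes --cutoff 19 -o ptcs.tsv
```

## Acceptance script

`scripts/acceptance.py` regenerates the default planted fixture from the
given seed, runs the complete pipeline (segmentation → ZINB annotation →
cutoff estimation → PTC calling), prints the recovered quantities (PC1
variance, segment/enrichment counts, estimated cutoff, PTC count and
hub-recovery tally) and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical model, parameter defaults and
the limits of what the synthetic fixtures establish.
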