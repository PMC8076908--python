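# cba-align

Cluster-guided batch alignment (CBA) for single-cell RNA-seq: integrate two
scRNA-seq batches measured with different protocols while *preserving* the
cluster structure each batch carries on its own.

Most integration methods match individual cells across batches and tend to
"over-align" — merging biologically distinct subpopulations that exist in
only one batch. CBA instead clusters each batch independently (Louvain on a
kNN graph of PCA features), matches clusters across batches by their
log-mean cosine distance

    U[i, j] = log10( mean_{p in i, q in j} d_cos(c_p, c_q) ),   match(i) = argmin_j U[i, j]

and trains a paired autoencoder on cross-batch cell pairs whose composite
loss

    L = L_r + L_s + L_c + L_p

combines reconstruction (`L_r`), a structure-preserving pull between
same-batch same-cluster cells (`L_s`), a cluster-preserving pull between
cross-batch cells of *matched* clusters weighted by their similarity
(`L_c`), and a softmax cluster-prediction term (`L_p`). The autoencoder
bottleneck is the aligned embedding. Batch-2 clusters that match no batch-1
cluster stay unmatched, so a cell type missing from one batch is not forced
onto anything.

Written for computational biologists who need a transparent, dependency-light
reference implementation: the network is plain NumPy (hand-verified
gradients), clustering and metrics use igraph/scikit-learn/scanpy, and a
negative-binomial synthetic-data generator makes every stage testable
without downloads.

## Worked example

```python
import numpy as np
import cba

# two synthetic batches: 4 shared cell populations, moderate batch effect
cfg = cba.scenario_presets()["pancreas-like"]
b1, b2, truth = cba.generate(cfg)

out = cba.align(b1, b2, cba.PipelineConfig(seed=0))
emb, tags = out.result.embedding, out.batch_tags

truth_all = np.concatenate([truth.clusters1, truth.clusters2])
labels = cba.louvain_cluster(emb, seed=0)
print("clusters found:", labels.max() + 1)
print("ARI vs ground truth:", round(cba.ari(labels, truth_all), 3))
print("kBET rejection aligned:  ",
      round(cba.kbet_rejection(emb, tags, k=25), 3))
print("kBET rejection unaligned:",
      round(cba.kbet_rejection(out.unaligned_embedding, tags, k=25), 3))
```

Output:

```
clusters found: 4
ARI vs ground truth: 0.987
kBET rejection aligned:   0.458
kBET rejection unaligned: 0.65
```

The aligned embedding recovers the four planted populations almost exactly
(ARI 0.99), and batch mixing improves: the kBET rejection rate — the
fraction of cells whose local neighborhood batch composition significantly
deviates from the global proportions — drops from 0.65 to 0.46. CBA mixes
batches conservatively by design; it keeps per-batch cluster structure
intact rather than maximizing mixing.

The same pipeline runs from the shell:

```bash
cba simulate --preset subcluster --seed 7 --out sim/
cba align --batch1 sim/batch1/matrix.mtx --batch2 sim/batch2/matrix.mtx --out aligned/
cba evaluate --embedding aligned/embedding.csv --labels aligned/clusters.csv --out report.json
```

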