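# morphembed

Self-supervised graph-transformer embeddings of single-neuron morphology.

Digitally reconstructed neurons (SWC files: one typed 3-D point with radius
and parent link per line) are hard to compare directly — reconstructions
are noisy, vary in node count by orders of magnitude, and labels (cell
type, brain region, disease condition) are scarce.  `morphembed` turns each
reconstruction into a fixed-length vector that can be probed with nothing
more than a k-nearest-neighbor classifier, for neuroanatomists and
computational biologists who want to classify, retrieve, or atlas neurons
without training a supervised model per dataset.

## The model

A neuron is a rooted tree G = {V, A} with node features
x = (x, y, z, r, one-hot type).  The encoder is a graph transformer:
features pass a two-layer MLP, eigenvectors of the normalized graph
Laplacian L = I − D^(−1/2) A D^(−1/2) are projected and added as positional
encodings, a learnable [CLS] token is prepended, and each layer applies
gated graph attention

    Attention(Q, K, V, A) = softmax(λ QKᵀ/√d_k + γ A) V,   [λ, γ] = exp(W₂ x)

which interpolates per token between vanilla dot-product attention and
adjacency-driven message passing.  The final-layer [CLS] row is the neuron
embedding.

Pre-training is teacher–student self-distillation: each neuron is
augmented (coordinate noise, random rotation, terminal-branch deletion,
subgraph sampling — all connectivity-preserving), the teacher encodes the
augmented view, the student encodes a masked or cropped version of the
same view, and the student is trained with a consistency loss (centered,
temperature-sharpened teacher targets), a masked-node feature
reconstruction loss, and a KoLeo spreading regularizer.  The teacher is an
exponential moving average of the student and never receives gradients.
Fine-tuning either updates everything or only small bottleneck adapters
beside each sublayer, leaving the pre-trained backbone bit-identical.

Everything — including the reverse-mode autodiff the training runs on —
is plain numpy/scipy; see `docs/methods.md` for the full model and the
design decisions.

## Worked example

```python
import morphembed as me
from morphembed.augment import AugmentationConfig
from morphembed.pretrain import PretrainConfig, pretrain
from morphembed.finetune_eval import embed_dataset, condition_benchmark

specs = me.example_class_specs()
trees, labels = me.generate_dataset([specs["tufted"], specs["sparse"]],
                                    n_per_class=30, seed=1)
pruned = [me.prune_axon(me.center_tree(t)) for t in trees]

enc = me.EncoderConfig(n_layers=2, d_model=64, n_heads=4, d_k=16,
                       n_eigvecs=8, mlp_hidden=128)
state, log = pretrain(pruned, PretrainConfig(steps=100, batch_size=8, seed=1),
                      enc, AugmentationConfig(seed=1))
emb = embed_dataset(pruned, state.encoder_checkpoint("teacher"),
                    labels=labels, prune=False)
report = condition_benchmark(emb, n_seeds=5, split=0.7, k=5, seed=0)
print(f"total loss: step 1 {log[0].total:.3f} -> step 100 {log[-1].total:.3f}")
print(f"frozen 5-NN accuracy: {report.mean:.3f} +/- {report.sd:.3f} "
      f"({report.n_seeds} stratified 7:3 splits)")
```

prints

```
total loss: step 1 2.359 -> step 100 1.525
frozen 5-NN accuracy: 0.978 +/- 0.027 (5 stratified 7:3 splits)
```

Sixty synthetic neurons from two morphologically distinct classes (densely
vs sparsely branching) are pre-trained for 100 steps; the total
self-distillation loss falls, and a 5-NN probe on the frozen CLS
embeddings — stratified 7:3 splits, SMOTE-style rebalancing, five seeds —
already separates the classes almost perfectly without ever seeing a label
during training.

The same pipeline is available from a shell:

```
morphembed simulate   --out raw --n 50 --seed 1
morphembed preprocess --in-dir raw --out-dir prep
morphembed pretrain   --data prep --out model --config run.yaml
morphembed embed      --ckpt model --data prep --out emb.tsv
morphembed knn        --embeddings emb.tsv --k 5 --seeds 5
morphembed finetune   --ckpt model --data prep --mode adapter
morphembed morphometrics --in-dir raw --out morpho.tsv
```

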