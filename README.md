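# textcam

Explainable text classification by treating documents as images: each
document is laid out as a fixed 25×25 token grid, every token is replaced by
its skip-gram word vector so that embedding dimensions become image
channels, a channel-adapted 18-layer residual network classifies the
resulting D×25×25 array, and Grad-CAM maps the model's evidence back onto
individual tokens as heatmaps and highlighted text.

Everything runs on CPU with no deep-learning framework: the package ships a
small numpy reverse-mode autodiff engine (convolutions, batch norm,
pooling, residual blocks), a skip-gram/hierarchical-softmax embedding
trainer, and a Grad-CAM implementation validated against finite-difference
oracles.

## Components

| module | purpose |
| --- | --- |
| `textcam.preprocess` | tokenization, 25×25 token-grid formatting with `#` pads, CSV corpus IO |
| `textcam.embedding` | skip-gram / hierarchical-softmax training, zero-vector pad/OOV rule, channels-first grid embedding, word2vec text format |
| `textcam.model` | ResNet-18 with configurable input channels/head, transfer-learning surgery, LeNet-style 1D CNN baseline, SGD training with best-checkpoint selection |
| `textcam.explain` | Grad-CAM (per-channel α weights from logit gradients), token attribution, PNG heatmaps, HTML highlighting |
| `textcam.evaluation` | confusion matrix, support-weighted precision/recall/F1, tf-idf Naive Bayes baseline |
| `textcam.synthdata` | seeded keyword-planted corpus generator with ground-truth keyword positions and a localization score |
| `textcam.cli` | `textcam` command with `synth / preprocess / embed / train / eval / explain / run` subcommands |
| `textcam.nn` | the autograd engine and layers backing the classifiers |

## CLI

Generate a corpus, run the pipeline, and explain a document:

```bash
textcam synth --spec spec.yaml --out corpus.csv --truth truth.json
textcam run --config run.yaml --out-dir out/
textcam explain --checkpoint out/checkpoint.npz --embedding out/embedding.txt \
    --corpus corpus.csv --doc-id 0-7 --out-dir out/
```

`run.yaml` example:

```yaml
corpus: corpus.csv
seed: 1
embedding: {vector_size: 100, window: 100, min_count: 1, epochs: 5}
model: {backbone: resnet18, pretrained: false}
training: {learning_rate: 0.1, weight_decay: 0.0005, batch_size: 128,
           epochs: 25, val_fraction: 0.2}
explain_ids: ["0-7"]
```

The run writes `embedding.txt`, `checkpoint.npz`, `metrics.{json,csv}`,
`history.csv`, `summary.json`, and `cam_<id>.{png,html,json}` per explained
document. With `pretrained: true`, supply donor weights via
`model.pretrained_weights: <checkpoint>` (interior weights are transplanted;
the input convolution and head stay freshly initialized).

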