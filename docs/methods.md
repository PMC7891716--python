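# Methods

## Model and assumptions

The package implements a stacked variational autoencoder for joint
classification and topic discovery over short documents. The generative
assumptions are:

* a document's bag of words follows a multinomial whose log-probabilities
  are an affine map of a latent topic vector, softmax-normalised over the
  vocabulary (the neural variational document model family);
* the category label is a function of the same latent vector, so whatever
  structure the classifier exploits is expressible as topics;
* conditioning a second latent space on the predicted label yields topics
  that are *aware* of the classification, and the per-class decoder R_ct
  ties one topic to each class.

Both variational posteriors are diagonal Gaussians with N(0, I) priors, so
their KL terms are closed form. Expectations over latent draws are plain
Monte-Carlo averages of reparameterised samples (z = μ + σ⊙ε); because the
predicted label ŷ is a deterministic function of z, expectations over ŷ
collapse onto the z-sample average and no label sampling occurs.

The document representation h is produced by a self-contained reference
encoder: one leaky-rectifier layer over the L1-normalised count vector.
The encoder contract is a plain callable mapping a document to a fixed-width
vector, so a pretrained contextual encoder can be slotted in where
available; everything downstream is agnostic to the choice.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `vocab_size` | 2000 | most-frequent-token cap after normalisation |
| `d_z`, `d_zs` | 50 | width of the two latent topic spaces |
| `d_h` | 64 | reference-encoder output width |
| `lambda_cls` | \|V\|/\|y\| | classifier weight in the loss |
| `n_samples_train` / `n_samples_test` | 10 / 1 | latent draws per document |
| `batch_size` | 32 | minibatch size |
| `lr` | 1e-3 | step size; first-order adaptive-moment optimiser, default moments |
| `epochs` / `patience` | 50 / 5 | cap and early stopping on validation loss |
| leaky slope | 0.01 | negative-side slope of all rectifiers |

Prediction always uses the posterior mean μ of q(z|x) — no sampling — so
predictions are deterministic.

## Numerical choices

* σ is parameterised through the log-variance (σ = exp(logvar/2)), with
  logvar clamped to [−10, 10]; an unconstrained linear output for σ cannot
  guarantee positivity.
* The vocabulary softmax is a plain softmax over affine logits; log-softmax
  is computed with max-subtraction for stability.
* Decoder biases b, b_ct, b_s are separate parameters; nothing motivates
  sharing them.
* Topic-word ranking uses the raw decoder weight, excluding the bias: the
  bias is token-global, so including it would add the same background
  ranking to every row.
* Frequency ties at the vocabulary cut, confidence ties in label merging,
  and weight ties in topic ranking all break lexicographically, making every
  pipeline stage deterministic.
* Weight matrices initialise from a normal with Glorot-style scale
  √(2/(fan_in+fan_out)); biases start at zero. A single integer seed derives
  independent streams for initialisation, minibatch order, latent noise,
  fold splitting and synthetic generation.
* Empty documents (all tokens out of vocabulary) are rejected by the
  encoder, excluded (and counted) by perplexity, and flagged per record by
  batch prediction.
* Gradients come from a small reverse-mode tape over numpy arrays written
  for this package; it implements exactly the primitives the network needs
  and is pinned by finite-difference tests at 1e-4 relative tolerance.

## Training procedures

Supervised training minimises the mean per-document loss by minibatch
gradient steps. Unlabelled adaptation freezes every M1 parameter
(encoder, posterior maps, decoder R, classifier) bit-for-bit and trains the
class-decoder path (R_ct) plus all M2 parameters on
−log p(x_bow|ŷ,z_s) − log p(ŷ|z_s) + KL(q(z_s)‖p) − log p(x_bow|ŷ), with ŷ
taken from the frozen classifier. Training R_ct during adaptation is the
default (it refreshes the class-associated topic tables on new data) and is
switchable off. Because the prediction path is entirely inside the frozen
set, classification outputs are provably unchanged by adaptation; the test
suite asserts byte identity of the frozen arrays.

## Perplexity

Perplexity is reported through the variational bound of the document model:
exp(−(1/D) Σ_d ELBO_d / N_d), with ELBO_d the sample-averaged
reconstruction log-likelihood minus the closed-form KL and N_d the
in-vocabulary token count. Length normalisation sits inside the
per-document average (per-document normalisation); a corpus-level per-token
variant would weight long documents more. Numbers are therefore comparable
across runs of this package, not across implementations that normalise
differently. A uniform decoder with zero KL scores exactly |V|.

## Annotation curation

Pairwise agreement averages over all unordered annotation pairs on the same
document. Cohen's kappa is computed on pooled pairs with a fixed slot
convention (record order within a document fills slot 1 then slot 2), which
makes the marginals well defined despite anonymous pairing. Annotator
quality is the leave-one-out agreement change — score = agreement(without) −
agreement(all) — so larger means more harmful and "remove the worst n"
removes the top-scoring annotators. Merging applies strict majority first,
then highest confidence, then lexicographic order; filtering keeps records
with confidence ≥ the annotator's threshold (default 6).

## What the synthetic generator does and does not emulate

`generate_corpus` plants an exclusive token signature per class and draws
each token from the signature with probability `separation`, else from the
shared background — a mixture-of-signatures model, not a hierarchical topic
model. Defaults mirror the target study's scale: 10 classes, 1,300
documents of 15–30 content tokens, 2,000-token vocabulary; the annotator
pool defaults to 27 annotators, mostly single-coverage, with correct
annotations drawing confidence 6–9 and wrong ones 2–5.

The generator produces no grammar, no polysemy, no topic correlation, no
class overlap and no annotator drift. Passing recovery tests therefore
demonstrates that the estimation machinery recovers planted structure under
the stated noise, not that real-corpus accuracy figures transfer: on real
fact-check corpora, class boundaries are far fuzzier and headline accuracy
is correspondingly lower.

Two consequences worth knowing when reading the reported numbers:

* **Null control.** With `separation = 0` the label carries no signal, and
  the classifier converges to predicting the empirically largest class of
  the training folds. Cross-validated accuracy then tracks the corpus's
  empirical majority share, which on a finite uniform draw of 500 documents
  over 10 classes sits slightly above 1/10 (typically 0.11–0.15), not at
  1/10 exactly.
* **Recovery tests** use a deliberately smaller instance than the package
  defaults — 500 documents, 300-token vocabulary, 30 epochs without early
  stopping — chosen as the smallest configuration where recovery is
  comfortably saturated; at that scale 5-fold cross-validation completes in
  about a minute on one core.

## Open design points, resolved

* The exact stop-list and token normalisation behind the vocabulary cap are
  unstated in the source setting; this package lowercases, strips
  non-alphanumerics, drops single-character tokens and the standard English
  stop-list (scikit-learn's), all configurable at tokenisation.
* Whether the adaptation phase also trains the class decoder is ambiguous in
  the source description (two passages disagree); both behaviours are
  implemented, with R_ct training on by default.
* In training mode the ŷ fed to M2 is the per-sample ŷ(z_i), not the
  sample average.
* Fold standard deviations are population (divide by k), the common
  convention when reporting k-fold spreads.

## Known limitations

* The reference encoder is bag-of-words; without a contextual encoder the
  model cannot exploit word order, and absolute classification numbers on
  real corpora will differ from encoder-augmented variants.
* Training is single-threaded numpy; fine for corpora in the thousands of
  documents, not designed for millions.
* Perplexity is a bound-based proxy and only comparable within this
  implementation's normalisation convention.
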