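# corticograph

Sequential decoding and quality scoring of upper-limb movements from
synchronized EEG–EMG recordings, using channel graphs and a Graph
Isomorphism Network (GIN).

## The problem

In motor rehabilitation after stroke, it is not enough to know *which*
movement a patient attempted (push vs pull) — clinicians also want to know
*how well* each movement was executed. This package implements a
sequential-learning pipeline that does both. Each 3 s trial of 32-channel
EEG (500 Hz) and 8-channel forearm/upper-arm EMG (1000 Hz, downsampled to
500 Hz) is cut into six 0.5 s **sub-actions**. Every sub-action becomes a
40-node **channel graph**:

- **Nodes** carry a length-7 spectral feature: the fraction of multitaper
  PSD power in five bands — δ (2–4 Hz), θ (4–8), α (8–15), β (15–30),
  low-γ (30–40) — plus the total in-band power and the electrode index as
  a location code.
- **Edges** are the strongest quarter of pairwise **standardized
  permutation mutual information** (SPMI) values. With ordinal patterns of
  embedding dimension *n* = 5 and lag τ = 1,

  ```
  SPMI(X, Y) = (PE_X + PE_Y − PE_{X,Y}) / PE_{X,Y}  ∈ [0, 1]
  ```

  where PE is the permutation entropy of the Bandt–Pompe pattern
  distribution. Keeping the top 25 % of the 780 channel pairs gives
  exactly 195 edges per 40-node graph. EEG–EMG edges act as a
  corticomuscular-coupling measure; all pair types are treated identically
  so a general GNN can consume the graph.

A **GIN** classifies each graph into one of 12 sub-action classes
(2 movements × 6 positions):

```
x'_i = MLP((1 + ε) · x_i + Σ_{j∈N(i)} x_j),      h_G = CONCAT_k( Σ_v h_v^(k) W_k )
```

with sum aggregation, a learnable ε per layer, 2-layer MLPs
(Linear→BatchNorm→ReLU→Linear, 64 hidden channels), and a readout that
concatenates sum-pooled embeddings from every depth k = 0…K. Training uses
Adam (lr 0.005, 300 epochs, batch 128) on the sum of the 12-way sub-action
cross-entropy and the 2-way movement cross-entropy (movement probabilities
marginalized from the 12-way softmax). The network is implemented directly
in NumPy (forward, backprop and Adam), with SciPy sparse block-diagonal
adjacency for mini-batching.

Finally a **time-based ensemble** turns the predicted sequence
M[0..5] into a movement label and a quality score:

```
score(G, M) = (1/n) Σ_i similarity(G[i], M[i]),
similarity(a, b) = 0 if different movements, else 1 − |pos_a − pos_b| / n
```

The candidate movement whose canonical sequence [(m,0)…(m,5)] scores
highest wins; the winning score (reported 0–100) quantifies movement
quality. Per-segment predictions are bucketed into *close*
(|Δposition| ≤ 3), *far* (> 3) and *wrong* (other movement), and group
differences (patients vs healthy controls) are tested with an
independent-samples t-test.

Because the reference recordings are an external dataset, the package
ships a first-class **synthetic generator** that plants exactly the
structure the pipeline consumes: class- and segment-dependent band-power
signatures, and a shared β-band drive linking sensorimotor EEG channels to
task muscles (see `docs/methods.md`).

## Worked example

```python
from corticograph import (GeneratorProfile, GINClassifier, GINConfig,
                          generate_dataset, split_train_test)
from corticograph.pipeline import evaluate_model, trials_to_graphs

trials = generate_dataset(n_per_class=10, subjects=["S01", "S02"], seed=42)
train_trials, test_trials = split_train_test(trials, ratio=(4, 1), seed=42)

graphs_train = trials_to_graphs(train_trials)   # 6 graphs per trial
graphs_test = trials_to_graphs(test_trials)

model = GINClassifier(GINConfig(epochs=60, seed=0)).fit(
    [g for t in graphs_train for g in t])
report = evaluate_model(model, graphs_test)
```

prints (via the fields of `report`):

```
test trials:          8
movement accuracy:    1.000
sub-action accuracy:  1.000
position accuracy:    1.000
mean movement score:  1.000
first trial: true=pull predicted=pull score=100/100 close=1.00 far=0.00 wrong=0.00
```

On this clean low-noise profile the planted spectral signatures are fully
recoverable: every held-out trial's movement, and even the position of
every 0.5 s sub-action, is decoded correctly, so each trial receives a
quality score of 100/100. Degraded (patient-like) profiles produce lower
scores and more *far*/*wrong* segments — see
`tests/test_acceptance.py::test_patient_profile_scores_lower_than_healthy`.

The same pipeline is scriptable end to end:

```bash
corticograph --config config.yaml --run-dir runs/demo all
```

which chains `simulate → preprocess → graphs → train → evaluate → assess`,
writing versioned artifacts and a JSON manifest per stage.

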