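"""End-to-end pipeline on synthetic sequences: embed, train, predict.

Generates random protein sequences whose synthetic-backend embeddings
carry a hidden class signal (each sequence's pooled vector sits near one
of ten class centers), trains the GRU + attention classifier on 80% of
them, and reports held-out performance against the hidden ground truth.
"""

import numpy as np

from deepsub import DeepSubConfig, train
from deepsub.embedding import embed_sequence, pool
from deepsub.evaluation import evaluate, split
from deepsub.fixtures import FixtureSpec, make_synthetic_sequences
from deepsub.model import predict_batch

spec = FixtureSpec(n_per_class=15, width=64, noise_sd=0.05, seed=42)
records, hidden, backend = make_synthetic_sequences(spec)
print(f"{len(records)} sequences, 10 classes, embedding width {spec.width}")

X = np.vstack([pool(embed_sequence(seq, backend)).x for _, seq in records])
y = np.asarray([hidden[acc] for acc, _ in records])

config = DeepSubConfig(input_width=64, gru_hidden=32, attention_heads=8,
                       dropout=0.5, epochs=200, batch_size=1024, seed=0)
(Xtr, ytr), (Xte, yte) = split((X, y), ratio=0.8, seed=0)
model = train((Xtr, ytr), config)
print(f"trained {config.epochs} epochs; loss {model.history[0]:.3f} -> {model.history[-1]:.4f}")

report = evaluate(model, Xte, yte)
correct = int(np.sum(predict_batch(Xte, model) == yte))
print(f"held-out: {correct}/{len(yte)} correct, mACC={report.mACC:.3f}, mF1={report.mF1:.3f}")
print()
print("mACC is the macro-averaged one-vs-rest accuracy over the ten NS")
print("classes; 1.0 means every held-out sequence's subunit count was")
print("recovered from its embedding alone.")
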