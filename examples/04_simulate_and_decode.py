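"""Simulate annotated sequences and decode them back.

Draws sequences from the plant-and-recover setting (1 kb, one CRM each),
runs the scan -> posterior-Viterbi pipeline with the generating model, and
scores the predictions at nucleotide level.
"""

import warnings

from crmseg.evaluate import pooled_metrics
from crmseg.harness import plant_dataset, plant_model
from crmseg.pipeline import predict_sequence, score_against_truth

warnings.simplefilter("ignore")

model = plant_model()
sims = plant_dataset(model, 5, seed=11, length=1000)
preds = [predict_sequence(model, s.name, s.sequence) for s in sims]

for s, p in zip(sims, preds):
    true = [(c.start, c.end) for c in s.truth_crms]
    found = [(c.start, c.end) for c in p.crms]
    print(f"{s.name}: true CRM {true}  predicted {found}")

counts = score_against_truth(
    preds,
    {s.name: [(c.start, c.end) for c in s.truth_crms] for s in sims},
    {s.name: len(s.sequence) for s in sims},
)
df = pooled_metrics(counts, [s.name for s in sims])
print(df.round(3).to_string())
# the pooled row sums TP/TN/FP/FN over sequences before computing CC and F1
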