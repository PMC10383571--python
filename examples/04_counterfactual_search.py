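"""Find counterfactual analogues that flip an ST_A prediction to DT.

Analogues are built from substituents frequently observed in the active
classes; candidates whose argmax class becomes DT qualify as
counterfactuals.  The qualified edits typically introduce the motif the
base compound lacks — the structural 'gain of function'.
"""

import numpy as np

from chemlens import BenchmarkSpec, ClassLabel, generate_benchmark, find_counterfactuals
from chemlens.counterfactuals import substituents_from_actives, transform_analogues
from chemlens.fingerprints import fingerprint_matrix
from chemlens.model import run_trials

dataset = generate_benchmark(BenchmarkSpec(n_per_class=40, seed=0))
X, fps = fingerprint_matrix(dataset.entries)
y = np.asarray(dataset.labels_as_codes())
trial = run_trials(X, y, n_trials=1, base_seed=0, grid=None)[0]

pred = trial.model.predict_codes(X[trial.split.test_indices])
base_idx = next(int(i) for i, p in zip(trial.split.test_indices, pred)
                if y[i] == ClassLabel.ST_A.code and p == ClassLabel.ST_A.code)
base = dataset.entries[base_idx]

library = substituents_from_actives(
    [e for e in dataset.entries if e.label is not ClassLabel.R], top_k=10)
candidates = transform_analogues(base, fragment_library=library, seed=7, max_candidates=500)
records = find_counterfactuals(trial.model, base, ClassLabel.DT, candidates,
                               base_fp=fps[base_idx])
qualified = [r for r in records if r.qualified]

print(f"base {base.source_id}: {base.canonical_key}")
print(f"base P(DT) = {records[0].base_probabilities[ClassLabel.DT]:.3f}")
print(f"{len(records)} candidates, {len(qualified)} qualified counterfactuals")
for r in qualified[:3]:
    print(f"  CF P(DT) = {r.probabilities[ClassLabel.DT]:.3f}  "
          f"similarity {r.similarity:.2f}  {r.candidate.canonical_key}")
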