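"""Learn a Bayesian network by simulated annealing and query it exactly.

Samples 5,000 rows from a known chain A -> B -> C, learns the structure
back with SA over single-edge moves (BIC score), fits CPTs with Laplace
smoothing and computes a marginal conditional table by exact enumeration.
"""

import numpy as np

from tempmort import bn

states = {"A": ["0", "1"], "B": ["0", "1"], "C": ["0", "1"]}
truth = bn.BnModel(
    bn.Dag(states, [("A", "B"), ("B", "C")]),
    {"A": bn.Cpt("A", (), [[0.5, 0.5]]),
     "B": bn.Cpt("B", ("A",), [[0.9, 0.1], [0.1, 0.9]]),
     "C": bn.Cpt("C", ("B",), [[0.85, 0.15], [0.2, 0.8]])})

data = bn.sample(truth, 5000, np.random.default_rng(0))
learned = bn.sa_search(data, bn.SaSchedule(seed=0), states=states)
print(f"true edges:    {truth.dag.edges}")
print(f"learned edges: {learned.edges}")
print(f"markov equivalent to truth: {bn.markov_equivalent(learned, truth.dag)}")
# chains A->B->C and C->B->A encode the same independences, so recovery up
# to the Markov-equivalence class is the best any score-based method can do

model = bn.fit_cpts(learned, data, smoothing=1.0)
mc = bn.marginal_cpt(model, "C", "A")
print("\nP(C | A) by exact enumeration of the learned joint:")
print(mc.round(3))

state, post = bn.predict(model, "C", {"A": "1"})
print(f"\npredict C given A=1: {state} (posterior {post.round(3).to_dict()})")
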