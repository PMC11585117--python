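"""Two-step biomarker discovery: Integrated Gradients + kernel derivatives.

After fitting the deep kernel-fusion model, step 1 ranks each omic's kernel
principal components by Integrated-Gradients attribution of the predicted
class logit; step 2 ranks the original features by the norm of the partial
derivatives of the selected components' projection functions (KPCA-IG),
weighted by the step-1 attributions.  On synthetic data the planted
informative features are known, so recovery can be scored exactly.
"""

import dataclasses

import numpy as np

import mokl
from mokl.deep import DeepMKLClassifier, DeepMKLConfig
from mokl.interpret import rank_features, report_biomarkers

spec = dataclasses.replace(mokl.preset("A", seed=0), n=300)
blocks, labels, truth = mokl.generate(spec)
y = labels.encoded()

cfg = DeepMKLConfig(hidden=[32, 32, 16], head_hidden=16,
                    fusion="weighted_sum", dropout=0.3, lr=1e-3,
                    epochs=100, seed=0, sigma=0.01, n_components=8)
clf = DeepMKLClassifier(cfg).fit(blocks, y)

rankings = rank_features(clf.model_, clf.embeddings_, blocks,
                         clf.embedders_, k=3)
table = report_biomarkers(rankings, (10, 5, 5))
print(table.head(12).to_string(index=False))

planted = set(truth["blocks"]["block1"]["informative_ids"])
top = {f for f, _ in rankings[0].top(len(planted))}
print(f"\nplanted informative features recovered: "
      f"{len(top & planted)}/{len(planted)}")
print("the top-ranked block1 features should be exactly the planted "
      "informative ones;\nblock2/block3 are pure noise, so their rankings "
      "carry no signal.")
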