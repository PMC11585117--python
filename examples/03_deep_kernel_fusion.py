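"""Deep kernel fusion on a nonlinear (radial) class geometry.

Each class lies on a concentric shell, so no linear classifier can separate
them while a Gaussian kernel can.  Each omic is embedded by kernel PCA and
the embeddings are fused by a multi-modal network with learnable fusion
scalars; a linear-kernel SVM on concatenated features is the baseline.
"""

import numpy as np

import mokl
from mokl.deep import DeepMKLClassifier, DeepMKLConfig, tune_deep_mkl

blocks, labels, _ = mokl.generate(mokl.preset("B", seed=0))
y = labels.encoded()
tr, te = mokl.stratified_split(y, 0.3, 0)
trb = [b.values[tr] for b in blocks]
teb = [b.values[te] for b in blocks]

base = DeepMKLConfig(hidden=[32, 32, 16], head_hidden=16,
                     fusion="weighted_sum", dropout=0.3, lr=1e-3,
                     epochs=100, seed=0, n_components=8)
cfg = tune_deep_mkl(trb, y[tr], {"sigma": [0.01, 0.05, 0.1]},
                    budget=3, folds=3, seed=0, base=base)
print(f"tuned sigma={cfg.sigma} (CV accuracy {cfg.cv_accuracy:.3f})")

deep = DeepMKLClassifier(cfg).fit(trb, y[tr])
deep_acc = np.mean(deep.predict(teb) == y[te])
lin = mokl.MKLClassifier("concat", kernel="linear", cost=1.0).fit(trb, y[tr])
lin_acc = np.mean(lin.predict(teb) == y[te])

print(f"deep kernel fusion test accuracy:   {deep_acc:.3f}")
print(f"linear concatenation test accuracy: {lin_acc:.3f}")
print(f"learned fusion scalars: {np.round(deep.model_.net.fusion_scalars, 3)}")
print("\nthe linear baseline sits near chance (0.5) because the classes "
      "differ only\nin radius; the kernel embedding makes them separable.")
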