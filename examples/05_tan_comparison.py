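"""Compare the naive Bayes classifier with a tree-augmented network.

A TAN relaxes the conditional-independence assumption: features may depend
on one other feature through a Chow-Liu tree learned from class-conditional
mutual information.  On data generated with independent symptoms (the NBC's
own assumption) the two models should agree closely.
"""

import numpy as np

from mps2screen import (
    ase_sse,
    build_tan,
    build_training_set,
    confusion,
    fit_nbc,
    generate_negative_cohort,
    generate_positive_cohort,
    metrics,
    posterior_frame,
    tan_posterior_frame,
)

train = build_training_set(
    generate_negative_cohort(971, seed=101, id_prefix="NEG"),
    generate_positive_cohort(73, seed=202, id_prefix="POS"),
)

nbc = fit_nbc(train, alpha=1.0)
tan = build_tan(train, alpha=1.0)
print(f"TAN tree: {len(tan.edges)} feature-feature arcs, root {tan.root!r}")

for name, post in (("NBC", posterior_frame(nbc, train.X)),
                   ("TAN", tan_posterior_frame(tan, train.X))):
    rep = metrics(confusion(train.y, post["map_class"].to_numpy()))
    ase, sse = ase_sse(post[["p_negative", "p_positive"]].to_numpy(), train.y)
    print(f"{name}: accuracy {rep.accuracy:.4f}, kappa {rep.kappa:.3f}, "
          f"ASE {ase:.4f}")

diff = np.abs(
    posterior_frame(nbc, train.X)["p_positive"].to_numpy()
    - tan_posterior_frame(tan, train.X)["p_positive"].to_numpy()
)
print(f"max |NBC - TAN| posterior difference: {diff.max():.4f}")
# Because the synthetic symptoms are independent given the class, the tree
# arcs carry little information and the two posteriors nearly coincide.
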