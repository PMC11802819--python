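"""Run the six feature pipelines on one training split.

Fits every pipeline on the training rows of a within-subject split and
prints the resulting feature widths, plus the top CSP eigenvalue per class
pair - eigenvalues far from 0.5 mean the pair is spatially separable.
"""

from bruteeg import SynthConfig, csp_fit, generate, split_subject_dependent
from bruteeg.features import ALL_ORDER, FeaturePipeline

ds = generate(SynthConfig(
    n_subjects=2, n_channels=8, sfreq=128.0, epoch_seconds=0.5,
    trials_per_class_range=(20, 24), seed=3,
))
split = split_subject_dependent(ds, subject=1, seed=0)
train = ds.select(split.train)

for method in ALL_ORDER + ("all",):
    fm = FeaturePipeline(method).fit(train).transform(train)
    print(f"{method:>8}: {fm.n_features:4d} features")
# 'all' concatenates the six other pipelines column-wise, in that order.

print("\ntop CSP eigenvalue per class pair (0.5 = inseparable, 1.0 = perfectly separable):")
for bank in csp_fit(train, "pairwise"):
    lam = max(bank.eigenvalues[0], 1 - bank.eigenvalues[-1])
    print(f"  classes {bank.contrast}: {lam:.3f}")
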