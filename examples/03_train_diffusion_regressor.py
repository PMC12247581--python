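"""Train one dual-guidance diffusion model on median-slice phantoms.

A small run (300 training phantoms, 6 epochs) that still learns the
image -> age mapping clearly; the full desk study in
`diffage.experiments.run_desk_experiment` uses 2000/200/200.
"""

import numpy as np

from diffage.experiments import DeskProfile, build_slice_dataset, train_slice_model

profile = DeskProfile(n_train=300, n_val=60, n_test=60, max_epochs=6)
train_slices, train_ages = build_slice_dataset(profile.n_train, seed=11, profile=profile)
val_slices, val_ages = build_slice_dataset(profile.n_val, seed=12, profile=profile)
test_slices, test_ages = build_slice_dataset(profile.n_test, seed=13, profile=profile)

model = train_slice_model((train_slices[50.0], train_ages),
                          (val_slices[50.0], val_ages), seed=0, profile=profile)
pred = model.predict(test_slices[50.0], n_draws=8, rng_seed=99)

mae = np.abs(pred - test_ages).mean()
baseline = np.abs(test_ages - train_ages.mean()).mean()
print(f"held-out MAE        : {mae:.2f} years")
print(f"mean-predictor MAE  : {baseline:.2f} years")
print(f"correlation r       : {np.corrcoef(pred, test_ages)[0, 1]:.3f}")

# The model should beat the predict-the-mean baseline by a wide margin:
# the reverse diffusion chains, conditioned on the image embedding and the
# global/local priors, concentrate near the true (normalized) age.
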