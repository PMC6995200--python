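"""Decompose a Ks distribution into event peaks and date the events.

The intra-target Ks distribution is tri-modal: one peak per
polyploidization.  After locating the peaks, lineage rate differences are
corrected against the shared hexaploidy and the two younger events are
dated on the 115-130 Mya calibration window.
"""
import numpy as np

from paleoploidy import correction_coefficient, date_event, fit_mixture

# synthetic intra-target Ks sample: three events at the published peaks
rng = np.random.default_rng(3)
values = np.concatenate([
    rng.normal(0.551, 0.06, 2000),   # younger tetraploidization
    rng.normal(0.944, 0.176, 2000),  # older tetraploidization
    rng.normal(1.390, 0.099, 2000),  # shared hexaploidy
])

mix = fit_mixture(values, seed=3)
print(f"fitted {mix.k} components:")
for c in mix.components:
    print(f"  mu={c.mu:.3f}  sigma={c.sigma:.3f}  weight={c.weight:.2f}")

ech_target = mix.components[-1].mu
rc = correction_coefficient(ech_target, 1.053)  # reference hexaploidy peak
print(f"\nrelative rate vs reference: {rc.r * 100:.2f}%  (lambda = {rc.lambda_i:.4f})")

for label, idx in (("younger", 0), ("older", 1)):
    ev = date_event(mix.components[idx].mu, ech_target, 115, 130)
    print(f"{label} tetraploidization: {ev.age_low}-{ev.age_high} Mya")

# Expected output: ~32% faster than the reference; ages near 46-52 Mya and
# 78-88 Mya.  The Ks-peak ratio is invariant under the rate correction, so
# dating from raw or corrected peaks is identical.
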