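# caslquant

Quantitative pseudo-continuous arterial spin labelling (pCASL) perfusion
analysis for small-animal brain MRI, plus a fluorescence vessel-morphometry
pipeline — built for researchers who need the full quantification chain
(T1 mapping → ΔS extraction → absolute CBF → cerebrovascular reactivity →
group statistics) as tested, reusable code, with synthetic ground-truth
generators so every stage can be validated without animal data.

## The model

pCASL magnetically inverts arterial blood water in the neck and uses it as
an endogenous tracer. The perfusion-weighted signal is the difference ΔS
between interleaved control and label images, extracted by **surround
subtraction** (each label frame paired with the mean of its flanking
controls, suppressing slow drifts). Absolute cerebral blood flow follows
the one-compartment kinetic model (Buxton):

```
        λ · ΔS · exp(PLD_eff / T1_blood)
CBF = ────────────────────────────────────── · 6000   [ml/100 g/min]
       2 α · T1′ · S_control · (1 − e^(−τ/T1′))
```

with λ the blood–brain partition coefficient (0.89 ml/g), α the labelling
efficiency measured from a downstream vessel scan, τ the labelling
duration, T1′ the tissue T1 fitted voxelwise from an inversion-recovery
series `S(TI) = A + B·exp(−TI/T1)`, and T1_blood = 1700 ms at 7 T. In a
multi-slice readout each slice sees its own effective post-labelling
delay,

```
PLD_eff(slice) = PLD + 7 ms + (slice − 1) · (TR − τ − PLD) / n_slices
```

(the 7 ms is a fat-suppression gradient before the first slice).
Cerebrovascular reactivity under a CO₂ challenge is the percent CBF
change, `%ΔCBF = (CBF_challenge − CBF_baseline)/CBF_baseline × 100`.
Group comparisons use voxelwise or region-wise two-sample t-tests with
Benjamini–Hochberg FDR control and a cluster-extent filter (k ≥ 10);
robust screening uses median ± 3 × MAD limits. The vessel pipeline
measures projected vessel area and skeleton main-axis length (longest
geodesic path) from maximum-projected, background-subtracted,
tubeness-enhanced microscopy images.

## Worked example

Simulate a 120-frame (60 control / 60 label) session on the built-in
12-region phantom with 1 % Gaussian noise, quantify CBF, and check CVR
recovery through the full chain:

```python
import caslquant as cq

params  = cq.AcquisitionParams(alpha=0.86)          # τ=3000, PLD=200, TR=3450 ms
phantom = cq.default_phantom()                      # CBF 30–250 ml/100g/min
effect  = cq.EffectSpec(challenge_factor=1.3, noise_sigma=0.01)

series = cq.forward_asl(phantom, params, effect=effect, n_pairs=60, seed=5)
dss    = cq.surround_subtract(series)
t1_map = cq.QuantMap(phantom.t1_map, phantom.geometry, phantom.brain_mask)
cbf, mask = cq.quantify_cbf(dss, t1_map, params)
mean_map, n = cq.condition_mean(cbf, dss.conditions)["baseline"]

for r in (1, 6, 12):
    sel = phantom.labels == r
    print(f"region {r:2d}: true {phantom.cbf[r]:5.0f}  "
          f"recovered {mean_map[sel].mean():6.1f} ml/100g/min")

rep = cq.cvr_recovery_check(phantom, params, effect, n_pairs=60, seed=5)
print(f"CVR ground truth {rep['ground_truth_cvr']:.1f}%, "
      f"max regional error {rep['max_regional_error']:.2f} points")
```

prints

```
region  1: true   250  recovered  249.6 ml/100g/min
region  6: true   150  recovered  149.7 ml/100g/min
region 12: true    30  recovered   29.8 ml/100g/min
CVR ground truth 30.0%, max regional error 0.89 points
```

i.e. regional CBF is recovered to well under 1 % at this noise level, and
the injected 30 % reactivity comes back within a point after
quantification, averaging, smoothing and the CVR ratio. Noise-free, the
round trip is exact to < 1e-6 relative (see `tests/test_acceptance.py`).

A CLI mirrors the library (`caslquant simulate-asl | fit-t1 |
quantify-cbf | cvr | stats | vessels`), each subcommand taking `--config`
and `--seed`.

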