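# attndecode

Single-trial EEG decoding of covert visuospatial attention.

When attention is covertly shifted to one visual hemifield, alpha-band
(8–14 Hz) power over parieto-occipital cortex increases ipsilaterally
and decreases contralaterally. This lateralization is strong enough to
decode the attended side (left vs. right) from single 1.5 s EEG epochs
— the basis of gaze-independent brain–computer interfaces. `attndecode`
implements the full analysis chain for a Posner-style cueing experiment
in which a central random-dot stimulus cues attention either reliably
(*predictive* cues, coherent motion) or not at all (*ambiguous* cues,
zero coherence), and the decoder trained on predictive trials is
transferred to ambiguous ones. Because no public recordings accompany
the design, the package ships a synthetic session generator with
planted ground truth (source topographies, modulation depth, behavioral
error rates, EOG artifacts), so every stage is testable end to end.

The pipeline:

1. **Simulate** (`attndecode.synth`) — 8 blocks × 52 trials, 75%/25%
   predictive/ambiguous, Von Mises dot-direction cues (κ = coherence;
   ambiguous cues resampled until the resultant vector norm < 0.05), a
   two-level behavioral model (10%/50% spatial error rates → 20%
   overall), and a two-source alpha forward model with 1/f sensor noise
   at 1024 Hz over a 64-channel 10-20 montage plus bipolar hEOG/vEOG.
2. **Preprocess** (`attndecode.preprocess`) — common average reference,
   zero-phase order-4 Butterworth band-pass 8–14 Hz, 1.5 s pre-target
   epochs (T = 1536 samples at 1024 Hz), EOG rejection at 100 μV
   (vertical) / 40 μV (horizontal), labels from the subject's report of
   the attended side.
3. **Spatial filtering** (`attndecode.csp`) — common spatial patterns:
   per-trial OAS-shrunk covariances averaged per class, generalized
   eigendecomposition Σ_r W = λ Σ_l W, features log10(var(WᵀX)),
   patterns A = (Wᵀ)⁻¹; CSP-L1/CSP-R1 are the patterns of the extreme
   eigenvalues.
4. **Decode** (`attndecode.decode`) — linear hinge-loss SVM with
   recursive feature elimination over a log-spaced C grid, selected by
   cross-validated hinge loss; predictive→ambiguous transfer and
   leakage-free within-condition 10-fold CV; EOG mean features as a
   chance-level control.
5. **Statistics** (`attndecode.stats`) — exact binomial significance of
   k/n accuracy, Spearman pattern correlations (n = 64), pooled-variance
   t-tests on standardized features, report tables.

## Worked example

```python
import numpy as np
from attndecode import (SessionConfig, generate_session, preprocess_session,
                        DecodingConfig, decode_transfer, decode_within,
                        split_by_condition, fit_csp, class_covariances,
                        discriminant_pair, spearman_correlation)

config = SessionConfig()                      # 8 blocks x 52 trials, 1024 Hz
session = generate_session(config, seed=0)
epochs = preprocess_session(session)          # CAR, 8-14 Hz, epoch, reject, label
print(f"epochs kept: {epochs.n_trials} (rejected {epochs.n_rejected})")

predictive, ambiguous = split_by_condition(epochs)
decoding = DecodingConfig.fast(seed=0)        # reduced C grid / RFE step

transfer = decode_transfer(predictive, ambiguous, decoding)
print(f"transfer  accuracy {transfer.accuracy:.3f} "
      f"({transfer.k_correct}/{transfer.n_trials}), p = {transfer.p_value:.2e}")

within = decode_within(predictive, decoding)
print(f"within    accuracy {within.accuracy:.3f} "
      f"({within.k_correct}/{within.n_trials}), p = {within.p_value:.2e}")

control = decode_transfer(predictive, ambiguous, decoding, feature_kind="eog")
print(f"EOG ctrl  accuracy {control.accuracy:.3f}, p = {control.p_value:.2f}")

bank = fit_csp(*class_covariances(predictive))
l1, r1 = discriminant_pair(bank)
r = spearman_correlation(l1, session.planted.mixing_left)
print(f"CSP-L1 vs planted left topography: |r| = {abs(r.sign_aligned_r):.3f}")
```

Output (~1 min on one CPU):

```
epochs kept: 410 (rejected 6)
transfer  accuracy 0.794 (81/102), p = 8.55e-10
within    accuracy 0.792 (244/308), p = 3.28e-26
EOG ctrl  accuracy 0.441, p = 0.90
CSP-L1 vs planted left topography: |r| = 0.993
```

Reading the numbers: of 416 generated trials, 6 carried planted EOG
artifacts and were rejected. The decoder trained on predictive trials
classifies the attended side of ambiguous trials at 79% — far above the
exact binomial chance threshold for n = 102 (p ≈ 1e-9) — and
within-condition cross-validation on predictive trials performs almost
identically, the cross-condition stability the transfer design is
meant to demonstrate. EOG mean features decode at chance (eye movements
carry no class information in this model), and the most discriminative
left-attention pattern rank-correlates at 0.99 with the planted source
topography.

The same pipeline is scriptable from the shell:

```bash
attndecode run --seed 1 --out runs/demo          # simulate -> ... -> report
attndecode simulate --seed 1 --out runs/session
attndecode preprocess --in runs/session --out runs/epochs
attndecode decode --epochs runs/epochs --mode transfer --out runs/decoding
attndecode report --results runs/decoding --out runs/report
```

`run` writes every intermediate artifact plus a `manifest.json` with the
config hash, derived seeds, and trial counts before/after rejection;
identical config + seed reproduce identical outputs.

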