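# mseeg — microstate-segmented PLI analysis of multichannel EEG

`mseeg` is a quantitative-EEG toolkit for functional brain-network analysis
of resting-state recordings, aimed at studies of cognitive decline (e.g.
separating patients with early Alzheimer's disease from patients with
stable mild cognitive impairment).  It implements, as a tested and reusable
library plus CLI:

* **Preprocessing** — EDF / delimited-matrix input, zero-phase Butterworth
  band-pass filtering, average referencing, artifact-scored clean-segment
  selection (25–200 s segments concatenated to ≥ 180 s), fixed 4-s
  epoching, and a 22-region scalp parcellation (11 per hemisphere).
* **Spectral analysis** — Thomson multitaper power spectra, median over 12
  epochs, relative band power per region in five bands (delta 1–4, theta
  4–8, alpha1 8–10, alpha2 10–13, beta 13–30 Hz; normalized by 1–30 Hz
  power), logit transform, and peak/median frequency at parieto-occipital
  electrodes.
* **Microstate segmentation** — global field power
  GFP_t = √(Σᵢ uᵢ²/n), polarity-invariant (modified) k-means clustering of
  GFP-peak topographies with squared spatial correlation, cluster-count
  selection over k = 2–20 by the Krzanowski–Lai criterion, and competitive
  per-sample labelling with 12-ms temporal smoothing.
* **Connectivity** — the phase lag index
  PLI = (1/k)|Σᵢ sign[sin(ΔΦᵢ)]|, estimated both the standard way (12
  epochs × 4 s, averaged) and as the **microstate-segmented PLI (msPLI)**:
  Hilbert phases of the full-length band-filtered recording are indexed by
  the microstate label vector, stitched per class into 4 periods of 4000
  phase differences, and averaged (4 × 5 = 20 matrices per subject).
  Matrices reduce to the 22-region scheme by electrode-pair averaging.
* **Graph metrics** — weighted degree, clustering coefficient Cw, harmonic
  path length Lw, eccentricity/radius/diameter on 1/W edge lengths, degree
  diversity Kw = ⟨degree²⟩/⟨degree⟩, degree correlation Rw, and gamma/lambda
  normalization against 50 edge-reshuffled surrogate networks iterated
  five times.
* **Statistics** — permutation ANOVA/t tests (10,000 permutations) with
  max-statistic family-wise correction, feature–domain-score permutation
  correlations, a backward-elimination logistic score, and ROC evaluation
  with the maximal-Youden operating point.

Because clinical EEG cohorts are not public, the package ships a
first-class synthetic-data generator (`mseeg.synthgen`) producing
multichannel EEG with a known microstate sequence, known band-limited
phase-lagged coupling (optionally confined to specific microstate
classes), 1/f background noise, and known group effects — so every stage
is validated end-to-end against ground truth.

## Worked example

```python
import numpy as np
from mseeg import preproc, fit_microstates, mspli, pli_standard
from mseeg.synthgen import SynthConfig, CouplingSpec, generate_recording

# 3 minutes of 16-channel EEG; theta coupling between channels 2 and 9
# that is only active while microstate class 2 is occupied.
cfg = SynthConfig(
    n_channels=16, duration=180.0, sampling_rate=1000.0, seed=7,
    coupling_specs=(CouplingSpec(pair=(2, 9), band="theta",
                                 phase_lag=np.pi / 2, strength=1.0,
                                 active_states=(2,)),),
)
rec, truth = generate_recording(cfg)

model = fit_microstates(preproc.average_reference(rec), k=5, seed=0)
class_mats, subject = mspli(rec, model.labels, "theta")
global_pli = pli_standard(preproc.make_epochs(rec), "theta")

link = [cm.weights[2, 9] for cm in class_mats]
print("per-class msPLI on the planted link:", np.round(link, 3))
print("global PLI on the planted link:     ", round(global_pli.weights[2, 9], 3))
```

Output:

```
per-class msPLI on the planted link: [0.345 0.835 0.353 0.236 0.166]
global PLI on the planted link:      0.361
```

The planted link stands out in exactly one fitted microstate class (0.835
— fitted class indices are arbitrary, and this class is the one matching
planted state 2), while the standard whole-recording PLI dilutes the same
link to near the narrowband noise floor (0.361).  This is the contrast
that motivates microstate segmentation.

The same pipeline is available from the shell:

```bash
mseeg synth generate --config cfg.yaml --out subjects/
mseeg microstate fit --in subjects/subject_000.edf --k auto --out model.json
mseeg connectivity mspli --in subjects/subject_000.edf --labels model.json \
      --band theta --out mspli.tsv
mseeg graph metrics --in mspli.tsv --out metrics.json
```

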