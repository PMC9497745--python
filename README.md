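# entrofuse

Entropy-feature fusion and BiLSTM sequence classification for
cross-subject EEG emotion recognition.

## What this package is for

Emotion states (positive / neutral / negative, elicited by film clips)
leave statistical fingerprints in lateral-temporal EEG: gamma-band power is
highest during positive and lowest during neutral viewing, and the signal's
irregularity rises with emotional engagement. Single features capture these
fingerprints only partially, so this package computes five complementary
windowed entropy features, fuses them, and classifies every one-second
window of a subject's session with a bidirectional LSTM — training on one
group of subjects and testing on unseen subjects.

The pipeline, end to end:

1. **Preprocessing** — select the twelve lateral-temporal electrodes (FT7,
   T7, TP7, P7, C5, CP5 and right homologs), downsample to 256 Hz, keep
   clip-only segments, notch 50 Hz, split each channel into
   delta/theta/alpha/beta/gamma with a 5-level db6 wavelet decomposition,
   and correct artifacts per band by halving every wavelet coefficient
   whose magnitude exceeds T_j = mean(C_j) + 2·std(C_j).
2. **Features** — per channel, band and non-overlapping 1 s window:
   five-scale multiscale sample entropy (MSE), approximate entropy (AE),
   fuzzy entropy (FE), Rényi entropy (RE, q = 2) and differential entropy
   (DE = ½·ln 2πeσ²). A 12-channel subject yields a 300 × N MSE matrix and
   60 × N matrices for each single entropy.
3. **Fusion & split** — per-subject min–max normalisation to [−1, 1],
   row-wise feature fusion (540 rows for all five), and a random
   subject-wise train/test split.
4. **Classifier** — sequence-to-sequence LSTM / BiLSTM (pure NumPy, Adam,
   full BPTT) mapping each window's feature vector to an emotion label;
   accuracy is the unweighted mean over test subjects.

Real recordings can be supplied as EDF or delimited matrices; a bundled
synthetic generator emulates the film-clip protocol (5 s hint, 2 min clip,
45 s interval; 15 or 21 label-balanced clips; emotion-dependent band power
and complexity; blink/movement artifacts) so everything runs with no
external data. See `docs/methods.md` for the models and conventions.

## Worked example

```python
import numpy as np
from entrofuse import (SynthConfig, generate_protocol, generate_subject,
                       preprocess_subject, extract_features, EntropyParams,
                       threshold_level)
from entrofuse.pipeline import prepare_cohort, run_scaled_benchmark

# Eq.-style artifact threshold on a toy coefficient level
t_j, corrected = threshold_level(np.array([0.0] * 9 + [10.0]))
print(t_j, corrected[-1])            # 7.324555320336759 5.0

# one synthetic subject: 15 two-minute clips, 12 channels at 1000 Hz
protocol = generate_protocol(15, seed=1)
rec = generate_subject(protocol, SynthConfig(n_subjects=1, seed=1), 1)
banded = preprocess_subject(rec, protocol)
mse = extract_features(banded, EntropyParams(), feature_set=("mse",))
de = extract_features(banded, EntropyParams(), feature_set=("de",))
print(mse.values.shape, de.values.shape)   # (300, 1800) (60, 1800)

# scaled cross-subject benchmark: 20 synthetic subjects, 15 train / 5 test
table, _ = run_scaled_benchmark(seed=1)
print(table.round(3))
```

The benchmark prints the 2 × 6 accuracy table (architectures × feature
sets). On the default synthetic cohort with seed 1:

```
           ae     fe     re     de    mse    all
lstm    0.773  0.564  0.861  0.539  0.733  0.937
bilstm  0.761  0.571  0.861  0.605  0.757  0.949
```

Read it as: each cell is the mean test-subject window accuracy (chance is
1/3). The fused column ("all") beats the best single feature, and the
BiLSTM row matches or beats the LSTM row in most columns — the two
orderings the fusion approach is designed to produce. Absolute values
describe the synthetic cohort only.

The same pipeline is scriptable from the shell:

```bash
entrofuse simulate --subjects 5 --clips 15 --seed 1 --out cohort/
entrofuse preprocess --in cohort/S00 --protocol cohort/protocol.tsv --out banded/
entrofuse extract --in banded/ --features mse,de --out features/
entrofuse benchmark --seed 1 --out table.tsv
```

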