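# eegstress

Detection of acute mental stress from multi-channel EEG. The package
implements a complete pipeline for researchers working with
affect-elicitation EEG corpora (e.g. DEAP-style recordings: 128 Hz, 60 s
trials, 0–9 arousal/valence self-ratings):

1. **Conditioning** — zero-phase FIR band-pass (0.75–45 Hz) and
   wavelet-packet soft-threshold denoising (db3, 3 levels, universal
   threshold σ̂·√(2 ln N) with σ̂ = MAD/0.6745 on the finest subband).
2. **Channel selection** — an improved crow search algorithm over channel
   subsets with fitness w₁·EN + w₂·(1−CV) (EN: mean normalized amplitude
   entropy; CV: mean absolute pairwise correlation), extended with a
   Lévy-flight elite step and replace-worst move.
3. **Features** — 527 per channel: 13 time-domain statistics (including
   Hjorth activity/mobility/complexity), 224 wavelet-packet subband
   statistics (db2, 5 levels, 32 subbands × 7 stats), energy, IWMF, IWBF,
   257 spectral-kurtosis bins, and 30 LBP/LNDP/LGP texture-histogram
   values.
4. **Classification** — a hybrid network with parallel 1-D CNN
   (64/128/256 filters), 2-layer BiLSTM (50 units/direction) and DBN
   (RBM stack 200/150/100, CD-1 pretrained) branches fused through a
   fully connected softmax head; trained by mini-batch SGD
   (lr 10⁻³, batch 16, dropout 0.5) on a small numpy autodiff engine —
   no deep-learning framework required.
5. **Tuning** — an employee optimization algorithm (population search with
   elitist "reward" passage, peer exploration and best-member mentoring)
   over learning rate, weight decay and momentum.
6. **Evaluation** — stratified 70:30 splitting and the six standard
   detection metrics (recall, precision, F1, selectivity, NPV, accuracy)
   with stress as the positive class.

A seeded synthetic-EEG generator produces two-class trial sets with the
band signature the method targets (alpha suppression + beta/gamma
elevation under stress) and rule-consistent ratings, so the entire
pipeline is exercisable without any external dataset. A reader for
DEAP-style per-subject containers (pickled dict, `.npz` or `.mat`;
40 trials × 40 rows × 8064 samples with a 40×4 ratings block) is included
for real data.

## Worked example

```python
from eegstress.evaluation import run_experiment

config = {
    "synthetic": {"n_trials_per_class": 20, "n_channels": 8,
                  "informative_channels": [0, 1, 2, 3]},
    "seed": 1,
    "k": 4,                      # channels to select
    "selector": {"iter_max": 30},
    "classifier": {"epochs": 10, "pretrain_epochs": 5},
}
result = run_experiment(config)
print("channels:", result["channels"])
for name, value in result["metrics"].items():
    print(f"{name}: {100 * value:.1f}%")
```

Output:

```
channels: [0, 1, 2, 5]
recall: 100.0%
precision: 100.0%
f1: 100.0%
selectivity: 100.0%
npv: 100.0%
accuracy: 100.0%
```

The generator planted class-discriminative band power on channels 0–3;
the selector recovered three of them plus one background channel (a lone
background channel is uncorrelated with the informative set, so the
redundancy term does not penalize it), and the classifier separates the
12 held-out trials perfectly: recall and precision refer to the stress
class, selectivity and NPV to the calm class.

The same pipeline is available from the shell:

```sh
eegstress simulate --out trials/ --seed 1
eegstress select   --in trials/ --k 4 --seed 1 --out channels.json
eegstress extract  --in trials/ --channels 0,1,2,5 --out features.csv
eegstress run      --config experiment.yaml
```

Library classes follow scikit-learn conventions (`fit`, `transform`,
`predict`, `get_params`): `FIRBandpass`, `WaveletPacketDenoiser`,
`CrowSearchChannelSelector`, `MEFExtractor`, `HybridStressClassifier`.

## Scope

The package does not download or bundle any external dataset, does not
read EDF/BDF, and makes no claim of clinical validity. See
`docs/methods.md` for the model details, numerical conventions and known
limitations.
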