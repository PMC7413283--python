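# actimpute

Imputation of missing intervals in minute-level actigraphy data.

Wrist- and waist-worn accelerometers summarize movement as nonnegative
*activity counts* per minute. Analyses of rest–activity rhythms (intradaily
variability, MVPA bouts, ...) need complete subject-days, but real recordings
are riddled with *missing intervals* — runs of 30 or more consecutive zeros,
usually the device not being worn — so large fractions of collected days get
discarded. `actimpute` fills those gaps. Its core is a **zero-inflated
denoising convolutional autoencoder (ZI-DCAE)**: a ten-layer 1-D
convolutional encoder–decoder that treats the zeroed interval as masking
noise and reconstructs the record, with a clamped hyperbolic tangent output,
max(0, tanh(x)), whose exact point mass at zero reproduces the zero inflation
of count data by construction. Alongside it the package provides the
classical comparison imputers (per-minute mean imputation, and MICE —
multiple imputation by chained equations — with zero-inflated Poisson or
Bayesian linear regressors), the preprocessing/corruption protocol used to
evaluate them, the evaluation statistics, and a calibrated synthetic
actigraphy generator so that everything is testable without any data
downloads.

It is intended for researchers processing minute-epoch accelerometry
(population-survey actigraphy, clinical actigraphy) who want to salvage
incomplete days, and for methodologists comparing imputation strategies on
count-valued time series.

## The model

A record is one subject-day, windowed to the 720 waking minutes
(9 AM – 9 PM). Counts are min–max normalized by a global training-set scale,
the missing interval is overwritten with the token 0.5, and the autoencoder

    encoder  8×30 s2 → 16×20 s2 → 32×10 s2 → 64×10 s1 → 128×10 s1   (720 → k = 60)
    decoder  64×10 s1 → 32×10 s1 → 16×10 s2 → 8×20 s2 → 1×30 s2     (60 → 720)

(valid convolutions; batch norm + tanh after every layer except the clamped-
tanh output) is trained by Adam on the RMSE between the reconstruction and
the normalized uncorrupted record, computed over the whole record. Each
training epoch re-corrupts every record with a fresh seeded random interval;
early stopping tracks the partial RMSE of a fixed-corruption validation set.
Evaluation uses the error statistics standard in this literature: partial
RMSE / partial MAE over the imputed cells only, and the RMSE across records
of per-record SD, intradaily variability (IV), and MVPA minutes inside the
missing interval (cutoff 1267 counts/min uniaxial, 2691 magnitude;
10-minute bouts at ≥80% above cutoff).

The network and its backpropagation are implemented in numpy and verified
against numeric gradients; see `docs/methods.md` for the full model account.

## Worked example

```python
from actimpute import (
    SynthParams, TrainConfig, generate_dataset, preprocess, corrupt_set,
    fit_mean_model, mean_impute, impute_set, partial_rmse, RecordSet, train,
)
from actimpute.experiment import split_records
from actimpute.geometry import build_architecture

data = preprocess(generate_dataset(SynthParams(n_subjects=250, days_per_subject=8, rng_seed=1)))
labelled = split_records(data, 0.9, 0.1, rng_seed=1)
model = train(labelled.split("train"), labelled.split("validation"),
              build_architecture(m=30, k=60),
              TrainConfig(max_epochs=30, rng_seed=1))

test = labelled.split("test")
corrupted = corrupt_set(test, interval_length=30, rng_seed=1)   # hide 30 min/record
dcae = impute_set(model, corrupted)
mean_model = fit_mean_model(labelled.split("train"))
mean = RecordSet([mean_impute(mean_model, r, m) for r, m in zip(corrupted.records, corrupted.masks)],
                 corrupted.masks)
print(f"ZI-DCAE partial RMSE: {partial_rmse(test, dcae, corrupted.masks):.1f} counts")
print(f"mean    partial RMSE: {partial_rmse(test, mean, corrupted.masks):.1f} counts")
```

Output:

```
ZI-DCAE partial RMSE: 813.1 counts
mean    partial RMSE: 835.0 counts
```

The partial RMSE is the root-mean-square reconstruction error over the 30
hidden minutes of each test record, in device counts/min: the autoencoder
recovers the hidden interval more accurately than replacing it with the
per-minute training mean, because it exploits the record's own context
(subject level, bout structure at the gap edges) that the mean cannot see.

The same pipeline is scriptable from the shell:

```bash
actimpute simulate --n-subjects 250 --days-per-subject 8 --seed 1 --out raw.csv
actimpute preprocess --input raw.csv --out windowed.csv
actimpute corrupt --input windowed.csv --out corrupted.csv --mask-out masks.csv
actimpute train --input windowed.csv --model-out model.npz --epochs 30
actimpute impute --input corrupted.csv --masks masks.csv --method zidcae \
                 --model model.npz --out imputed.csv
actimpute evaluate --origin windowed.csv --imputed imputed.csv --masks masks.csv
```

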