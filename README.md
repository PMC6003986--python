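# adprog

Predicting the progression of Alzheimer's disease (AD) at a patient's
*next* clinic visit from the irregular longitudinal record of their past
visits.

AD severity is staged by the Global Clinical Dementia Rating score
(CDRGLOB ∈ {0, 0.5, 1, 2, 3}, from no impairment to severe impairment).
Patients visit at uneven intervals, different numbers of times, and their
records mix continuous, ordinal and nominal variables with substantial
missingness — conditions under which classical fixed-width classifiers and
standard time-series methods struggle. `adprog` implements a shifted
"many-to-one" recurrent network for this problem, together with everything
needed to exercise it end to end: a calibrated synthetic cohort simulator,
the two-step preprocessing pipeline, classical baselines, and patient-level
cross-validated evaluation.

## The model

For a patient with visits at months $t_1 < t_2 < \dots < t_N$, feature
vectors $x_{t_n}$ and inter-visit intervals $\Delta t_n = t_{n+1} - t_n$,
the model predicts the next-visit stage

$$\hat y_{t_{N+1}} = f(x_{t_1},\dots,x_{t_N};\; \Delta t_1,\dots,\Delta t_N),$$

where $\Delta t_N$ — the horizon to the predicted visit — is chosen by the
user. $f$ is a 2-layer LSTM (100 hidden units per layer) over the encoded
visit rows, each row carrying its interval as an extra input, with a
softmax head on the layer-2 hidden state at the last real step:

$$
\begin{aligned}
f_{t_n} &= \sigma(W_f [h_{t_{n-1}}, x_{t_n}] + b_f), &
i_{t_n} &= \sigma(W_i [h_{t_{n-1}}, x_{t_n}] + b_i),\\
\tilde C_{t_n} &= \tanh(W_C [h_{t_{n-1}}, x_{t_n}] + b_C), &
C_{t_n} &= f_{t_n} * C_{t_{n-1}} + i_{t_n} * \tilde C_{t_n},\\
o_{t_n} &= \sigma(W_o [h_{t_{n-1}}, x_{t_n}] + b_o), &
h_{t_n} &= o_{t_n} * \tanh(C_{t_n}),
\end{aligned}
$$

$$\hat y_{t_{N+1}} = \mathrm{softmax}(W h^{(2)}_{t_N} + b).$$

Training minimises a cross-entropy loss with L2 weight regularization
$\lambda \sum_i w_i^2$; forward, backward (BPTT) and the adaptive-moment
optimizer are implemented in numpy and validated against finite
differences. Because the real study cohort is access-restricted, the
package ships a cohort simulator whose stage paths follow the published
per-visit transition matrix, so that learning behaviour can be checked
against a closed-form optimum: when the current stage is fully observed,
no predictor can beat
$\sum_s \pi_s \max_{s'} P[s, s']$.

Three metrics are reported: overall accuracy, PPIA (accuracy restricted to
patients whose stage truly worsens by the next visit) and SPIA (accuracy
restricted to patients whose true next stage is CDR 2 or 3).

## Worked example

```bash
adprog simulate --n 300 --seed 7 --out runs/cohort
adprog train --visits runs/cohort/cohort.csv --truth runs/cohort/truth.csv \
    --schema runs/cohort/schema.json --epochs 10 --out runs/model
adprog evaluate --visits runs/cohort/cohort.csv --truth runs/cohort/truth.csv \
    --schema runs/cohort/schema.json --folds 5 --epochs 10 --out runs/eval
```

The `train` step prints

```
trained 10 epochs; final loss 1.5142 accuracy 0.6467
```

(per-patient training loss and training accuracy for the last epoch), and
`evaluate` writes per-fold metrics plus a summary:

```
LSTM_with_TI: {'model': 'LSTM_with_TI', 'failed_folds': [],
 'accuracy': 0.4000, 'accuracy_sd': 0.0816,
 'ppia': 0.4590, 'ppia_sd': 0.0722,
 'spia': 0.6311, 'spia_sd': 0.1042}
```

Read this as: on 5-fold patient-level cross-validation of a 300-patient
synthetic cohort (240 training patients per fold), the network predicts
the exact next-visit stage for 40% of held-out patients (sample SD across
folds 8.2 points); among patients who truly worsen it is right 46% of the
time, and among patients whose true next stage is severe (CDR 2–3), 63%.
A 300-patient cohort is far too small for this model class — the
transition matrix caps achievable accuracy at roughly 73%, and the
network closes to within 0.05 of that ceiling once trained on 5,000
patients with fully observed CDR elements (the learning check in
`tests/test_acceptance.py`).

The same pipeline is available as a library (`adprog.simulate_cohort`,
`adprog.PreprocessPipeline`, `adprog.fit`, `adprog.cross_validate`, ...),
including the three baseline feature constructions (`aggregate`,
`recent_r`, `last_visit`) for LR/SVM/DT/RF comparisons and the
category-ablation harness (`adprog ablate`).

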