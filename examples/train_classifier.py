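"""Train the 1-D CNN to separate carcinoma from paracancer spectra.

A deliberately tiny run (12 patients, narrow network, few epochs) so it
finishes in under a minute: it demonstrates the patient-level protocol --
whole patients are held out for validation and testing -- and the evaluation
report. Accuracy is not meaningful at this scale (three test patients);
see the test suite for the desk-scale benchmark.
"""

import ramanhisto as rh
from ramanhisto import cnn
from ramanhisto.preprocess import preprocess_dataset
from ramanhisto.synthetic import CohortConfig

cohort = rh.generate_cohort(
    CohortConfig(n_patients=12, n_hcc=9, n_icc=3, spectra_per_sample=12, seed=3)
)
clean = preprocess_dataset(cohort).decimate(2)

split = cnn.split_by_patient(clean, cnn.SplitPlan(test_pairs=3, seed=3))
print("patients per partition:", {k: len(v) for k, v in split.patients.items()})

task = lambda ds: cnn.task_labels(ds, "binary")[1]
model = cnn.build_model(
    cnn.CNNConfig(channel_divisor=8, n_epochs=20, learning_rate=3e-4, seed=3), clean.axis.n_points, 2
)
print(f"architecture: {model.n_conv_layers} conv, {model.n_pool_layers} pool, "
      f"{model.n_fc_layers} fully connected layers")
cnn.train(model, (split.train.X, task(split.train)), (split.val.X, task(split.val)))
print(f"final epoch: train acc {model.history['train_acc'][-1]:.2f}, "
      f"val acc {model.history['val_acc'][-1]:.2f}")

proba, _ = cnn.predict(model, split.test.X)
report = cnn.evaluate(task(split.test), proba, ["paracancer", "cancer"])
print(f"held-out patients: accuracy {report.accuracy:.2f}, AUC {report.auc:.2f}")
print("confusion (% per true class):")
print(report.confusion_percent.round(1))
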