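"""Train the two-pathway CILAD-Net on synthetic beats and print the
nine-metric evaluation report.

A compact run (60 beats/class, 8 epochs) that typically lands well above
0.9 test accuracy in under a minute; the desk-scale study conditions
(500/class, 20 epochs) are exercised by scripts/acceptance.py.
"""

import numpy as np

from cilad import synthetic_data as sd
from cilad.metrics import classification_report
from cilad.model import CiladConfig, SplitSpec, build_cilad, predict, \
    split_data, train_model

beats = sd.gen_ecg_beats(n_per_class=60, n_classes=5, noise_sd=0.05, seed=3)
train, test = split_data(beats, SplitSpec(train_fraction=0.8, seed=3))

cfg = CiladConfig(input_len=187, n_classes=5, epochs=8, seed=0)
net = build_cilad(cfg)
print(f"CILAD-Net with {net.n_params():,} parameters "
      f"(pathway 1: conv32-pool-drop-conv64-pool-inception-LSTM64; "
      f"pathway 2: conv128-relu-pool-batchnorm)")

history = train_model(net, train.signals, train.labels,
                      val=(test.signals, test.labels), config=cfg)
print(history.round(3).to_string(index=False))

_, labels = predict(net, test.signals)
report = classification_report(test.labels, labels)
print(report.to_json())
# accuracy + hamming_loss = 1 by construction; MCC and Cohen's kappa near 1
# confirm the agreement is far beyond chance on all five beat classes.
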