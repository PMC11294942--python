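"""Train the compact U-Net on synthetic lung phantoms and segment a held-out one.

Twelve 32x32 phantoms are split 70/15/15; a depth-3 network with 8 base
filters is trained with Dice loss and Adam, and the best-validation
checkpoint is scored on the held-out test phantoms.
"""

import numpy as np

from lungseg.metrics import dice
from lungseg.nn import (NetworkSpec, TrainConfig, UNet, predict_mask,
                        split_dataset, train)
from lungseg.preprocess import normalize01
from lungseg.synthetic import PhantomSpec, make_dataset

samples = make_dataset(PhantomSpec(size=(32, 32), n_nodules=(1, 2),
                                   nodule_radius=(2.5, 5.0)), 12, seed=0)
data = [(normalize01(s.image).pixels, s.nodule_mask.astype(float)) for s in samples]

cfg = TrainConfig(epochs=150, batch_size=8, seed=0)
tr, va, te = split_dataset(data, cfg)
print(f"split sizes: train={len(tr)} val={len(va)} test={len(te)}")

net = UNet(NetworkSpec(input_size=(32, 32), depth=3, base_filters=8), seed=0)
report = train(net, [data[i] for i in tr], cfg, val_dataset=[data[i] for i in va])

for row in report.epochs[:: max(len(report.epochs) // 5, 1)]:
    print(f"epoch {row['epoch']:4d}  train_loss {row['train_loss']:.4f}"
          f"  train_dice {row['train_dice']:.3f}  val_dice {row['val_dice']:.3f}")
print(f"best validation epoch: {report.best_epoch}")

if report.best_state is not None:
    net.load_state_dict(report.best_state)
test_dice = []
for i in te:
    mask, prob = predict_mask(net, data[i][0], threshold=0.5)
    test_dice.append(dice(mask, data[i][1] > 0.5))
print(f"test Dice per phantom: {[round(d, 3) for d in test_dice]}")
print("(the network learns nodule-vs-rest from a dozen phantoms; real CT")
print(" would need far more data and epochs)")
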