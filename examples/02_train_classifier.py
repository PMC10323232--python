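"""Train a small extrusion-vs-nothing window classifier on synthetic movies.

Samples 10x45x45 windows around annotated events (divisions become "none"
examples for the 2-class model), balances classes, trains the conv+GRU
classifier and saves the model directory.  Scaled down (4 base filters,
10 epochs) so it runs in a few minutes on one CPU.
"""

import numpy as np

from epievents import RunConfig, SynthConfig, generate_movie, train_pipeline
from epievents.nn import NetworkSpec, save_network

pairs = [generate_movie(SynthConfig(seed=s))[:2] for s in (1, 2)]
config = RunConfig(epochs=10, base_filters=4, batch_size=16, seed=0)
spec = NetworkSpec(base_filters=4, n_classes=2)

net, history = train_pipeline(pairs, config, n_classes=2, spec=spec,
                              samples_per_event=16)
save_network(net, "example_output/model")

print("epoch  loss   acc    val_loss  val_acc")
for i in range(len(history["loss"])):
    print(f"{i:5d}  {history['loss'][i]:.3f}  {history['accuracy'][i]:.3f}"
          f"  {history['val_loss'][i]:.3f}     {history['val_accuracy'][i]:.3f}")
# Accuracy is the fraction of windows classified correctly; the validation
# split (25%) is held out from the sampled windows, not from separate movies.
print("model saved to example_output/model")
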