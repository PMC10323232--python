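"""Detect extrusions in a held-out synthetic movie with a trained model.

Runs the full pipeline: rescale to the reference scale, classify overlapping
10x45x45 windows, assemble the extrusion probability map, threshold it
(180/255), drop volumes under 800 voxels, watershed-split merged blobs and
report each surviving volume's centroid as a point event.

Run 02_train_classifier.py first to create example_output/model.
"""

from epievents import (
    RunConfig,
    SynthConfig,
    detect_events,
    generate_movie,
    write_events_csv,
    write_imagej_rois,
    write_probability_map,
)
from epievents.nn import load_network

net = load_network("example_output/model")
movie, truth, _ = generate_movie(SynthConfig(seed=3))  # unseen movie
config = RunConfig()

events, prob_map = detect_events(net, movie, config)
write_imagej_rois(events, "example_output/detections.zip")
write_events_csv(events, "example_output/detections.csv")
write_probability_map(prob_map, "example_output/probability.tif")

n_true = sum(1 for e in truth if e.event_class.value == "extrusion")
print(f"detected {len(events)} extrusion candidates; movie has "
      f"{n_true} planted extrusions")
for e in events.events[:5]:
    print(f"  x={e.x:3d} y={e.y:3d} t={e.t:2d}  p={e.probability:.2f}")
print("ROIs, CSV and 8-bit probability map written to example_output/")
# The probability map TIFF uses the 0 (black) to 255 (white) display scale;
# the CSV carries each detection's peak map probability.
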