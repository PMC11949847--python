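"""Simulate a paired e-nose + image grading dataset and write it to disk.

The synthetic world mirrors the emulated study design: 15 samples per grade,
nine MOS gas sensors recorded at 1 Hz through baseline (200 s), headspace
injection (40 s) and recovery (60 s), and one RGB image per sample whose
color and texture depend on the grade.
"""

from pathlib import Path

from gradefusion import SyntheticConfig, simulate_dataset
from gradefusion.io import write_dataset

config = SyntheticConfig(product="capsule", seed=0)
recordings, images, labels = simulate_dataset(config)

print(f"recordings: {len(recordings)} (one per sample)")
print(f"images:     {len(images)}")
print(f"grades:     {sorted(set(labels))}, {labels.count('Grade1')} each")
rec = recordings[0]
print(f"one recording: {rec.voltages.shape[0]} sensors × "
      f"{rec.voltages.shape[1]} timepoints, phases end at "
      f"{rec.phase_boundaries} s")
print(f"one image: {images[0].pixels.shape} RGB in [0, 1]")

out = Path("scratch/example_dataset")
manifest = write_dataset(config, recordings, images, labels, out)
print(f"dataset written, manifest at {manifest}")
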