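"""Simulate a labelled ECG record and extract per-beat features.

Builds a 300-beat synthetic record (normal / PVC / other mix), runs the
preprocessing chain (stationary-wavelet denoising + Savitzky-Golay
smoothing), cuts beat windows around the annotations and prints the
class-wise means of the 11 features.
"""

import numpy as np
import pandas as pd

from ecgfusion import datasets, synthetic
from ecgfusion.features import FEATURE_NAMES

record = synthetic.generate_record(300, class_mix=(0.6, 0.1, 0.3), seed=7)
print(f"record: {len(record.samples)} samples at {record.fs} Hz, "
      f"{len(record.r_locations)} annotated beats")

X, y = datasets.record_to_features(record)
print(f"extracted {len(X)} feature vectors "
      f"(first/last beats dropped: no RR context)\n")

df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
df["class"] = np.array(["normal", "pvc", "other"])[y]
print("class-wise feature means:")
print(df.groupby("class").mean().round(3).to_string())
print("\nNote: PVC beats show ratRR well below 1 (shortened preceding RR),"
      "\nampP near 0 (no P wave) and a deep S; these are the features the"
      "\nclassifiers rely on.")
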