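"""IHC H-scores and quartile dichotomization.

Computes H-scores from per-sample staining-intensity histograms
(H = 1*pct1 + 2*pct2 + 3*pct3, range 0-300) and splits the cohort the
way IHC biomarkers are grouped: at the median for a typical marker,
at the third quartile for a marker whose risk sits in the top tail.
"""

import pandas as pd

from melmeth import dichotomize, hscore_table

staining = pd.DataFrame(
    {
        "sample_id": [f"pt{i}" for i in range(8)],
        "pct0": [70, 40, 10, 5, 25, 55, 15, 0],
        "pct1": [20, 30, 20, 15, 25, 25, 25, 10],
        "pct2": [10, 20, 40, 30, 30, 15, 35, 30],
        "pct3": [0, 10, 30, 50, 20, 5, 25, 60],
    }
)
scores = hscore_table(staining).set_index("sample_id")["hscore"]
print("H-scores (0 = unstained, 300 = all cells at maximal intensity):")
print(scores.to_string())

median_split = dichotomize(scores, rule="median")
q3_split = dichotomize(scores, rule="q3")
print(f"\nmedian split: high = {sorted(median_split[median_split == 'high'].index)}")
print(f"q3 split (very-high expressers only): high = {sorted(q3_split[q3_split == 'high'].index)}")
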