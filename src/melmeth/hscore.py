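"""Immunohistochemistry H-score.

The H-score summarises a stained section from the percentage of cells at
each staining intensity (0–3): H = 1·pct1 + 2·pct2 + 3·pct3, range
0–300.  Input is the per-sample intensity histogram; image analysis
itself happens upstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_SUM_TOL = 1e-6


def compute_hscore(pct0: float, pct1: float, pct2: float, pct3: float) -> float:
    """H-score from intensity percentages (must sum to 100)."""
    pcts = np.asarray([pct0, pct1, pct2, pct3], dtype=float)
    if np.any(pcts < 0):
        raise ValueError("percentages must be non-negative")
    if abs(pcts.sum() - 100.0) > _SUM_TOL:
        raise ValueError(f"percentages sum to {pcts.sum()}, not 100")
    return float(pct1 + 2.0 * pct2 + 3.0 * pct3)


def hscore_table(staining: pd.DataFrame) -> pd.DataFrame:
    """Vectorised H-scores for a table with sample_id, pct0..pct3."""
    out = pd.DataFrame(
        {
            "sample_id": staining["sample_id"],
            "hscore": [
                compute_hscore(r["pct0"], r["pct1"], r["pct2"], r["pct3"])
                for _, r in staining.iterrows()
            ],
        }
    )
    return out


def read_staining(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "pct0", "pct1", "pct2", "pct3"}
    if not need <= set(df.columns):
        raise ValueError(f"staining table needs columns {sorted(need)}")
    return df


def write_hscores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
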