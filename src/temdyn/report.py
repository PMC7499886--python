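"""Small reporting helpers: class-count tables and printed percentages."""
from __future__ import annotations

from typing import Mapping

import pandas as pd


def percentages(counts: Mapping[str, int], decimals: int = 1) -> dict[str, float]:
    """Share of each group in percent, rounded to ``decimals`` places."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty count table")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}


def classification_report(labels: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Count and percentage of TEs per class label; rows sum to the total."""
    if isinstance(labels, pd.DataFrame):
        labels = labels["te_class"]
    counts = labels.value_counts().sort_index()
    pct = percentages(counts.to_dict())
    return pd.DataFrame({"n": counts, "percent": pd.Series(pct)})
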