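"""Temporal response classification of expressed genes.

Log2 fold changes of each stimulated labeling window versus the starved
baseline are thresholded (strictly) at a fold cutoff; genes are assigned
a direction (induced / repressed / reversal) and a temporal pattern
(sustained / transient / delayed / reversal) with the onset window of
the first threshold crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv
from .quant import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_FOLD = 2.0
DEFAULT_MIN_STARVED_RPKM = 0.5

DIRECTIONS = ("induced", "repressed", "reversal", "none")
CALL_PATTERNS = ("sustained", "transient", "delayed", "reversal", "none")


def log2fc(matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Gene x stimulated-window log2((RPKM_w + eps) / (RPKM_starved + eps))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    starved = matrix.values[matrix.baseline] + pseudocount
    fc = matrix.values[matrix.stimulated].add(pseudocount)
    return np.log2(fc.div(starved, axis=0))


@dataclass(frozen=True)
class ResponseCall:
    gene_id: str
    direction: str      # induced | repressed | reversal | none
    pattern: str        # sustained | transient | delayed | reversal | none
    onset_window: int | None
    sub_flag: str | None = None  # delayed: sustained/transient; reversal: up_down/down_up

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")
        if self.pattern not in CALL_PATTERNS:
            raise ValueError(f"bad pattern {self.pattern!r}")
        none_like = (self.direction == "none", self.pattern == "none", self.onset_window is None)
        if any(none_like) and not all(none_like):
            raise ValueError("direction/pattern/onset must all be none together")
        if (self.direction == "reversal") != (self.pattern == "reversal"):
            raise ValueError("reversal direction iff reversal pattern")


def call_response(gene_id: str, fc: Sequence[float], starved_rpkm: float,
                  fold: float = DEFAULT_FOLD,
                  min_starved_rpkm: float = DEFAULT_MIN_STARVED_RPKM) -> ResponseCall:
    """Classify one gene from its per-window log2 fold changes.

    Thresholds are strict; repression additionally requires starved
    expression above ``min_starved_rpkm``.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.size < 1 or np.any(~np.isfinite(fc)):
        raise ValueError(f"gene {gene_id}: incomplete fold-change vector")
    theta = math.log2(fold)
    up = fc > theta
    down = fc < -theta
    crossed = up | down
    none_call = ResponseCall(gene_id, "none", "none", None)

    if up.any() and down.any():
        onset = int(np.argmax(crossed)) + 1
        order = "up_down" if up[np.argmax(crossed)] else "down_up"
        return ResponseCall(gene_id, "reversal", "reversal", onset, order)
    if up.any():
        direction, hits = "induced", up
    elif down.any():
        if starved_rpkm <= min_starved_rpkm:
            return none_call
        direction, hits = "repressed", down
    else:
        return none_call

    onset = int(np.argmax(hits)) + 1
    base = "sustained" if hits[onset - 1 :].all() else "transient"
    if onset > 1:
        return ResponseCall(gene_id, direction, "delayed", onset, base)
    return ResponseCall(gene_id, direction, base, onset)


def classify_all(matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 fold: float = DEFAULT_FOLD,
                 min_starved_rpkm: float = DEFAULT_MIN_STARVED_RPKM,
                 genes: Sequence[str] | None = None) -> tuple[pd.DataFrame, list[ResponseCall]]:
    """Fold-change matrix plus one ResponseCall per (expressed) gene."""
    fc = log2fc(matrix, pseudocount)
    if genes is not None:
        fc = fc.loc[[g for g in fc.index if g in set(genes)]]
    starved = matrix.values[matrix.baseline]
    calls = [
        call_response(g, fc.loc[g].to_numpy(), float(starved.loc[g]), fold, min_starved_rpkm)
        for g in fc.index
    ]
    return fc, calls


_DIR_RANK = {"induced": 0, "repressed": 1, "reversal": 2}
_PAT_RANK = {"sustained": 0, "transient": 1, "delayed": 2, "reversal": 3}


def order_for_heatmap(calls: Sequence[ResponseCall], fc: pd.DataFrame) -> list[str]:
    """Responder genes grouped by direction then pattern, onset ascending,
    then descending max |fc|; ties broken lexicographically by gene id."""
    responders = [c for c in calls if c.direction != "none"]
    maxabs = fc.abs().max(axis=1)

    def key(c: ResponseCall):
        return (_DIR_RANK[c.direction], _PAT_RANK[c.pattern], c.onset_window,
                -float(maxabs.loc[c.gene_id]), c.gene_id)

    return [c.gene_id for c in sorted(responders, key=key)]


def summarize_counts(calls: Sequence[ResponseCall],
                     count_reversal_in_directions: bool = True) -> pd.DataFrame:
    """Responder counts by (direction, pattern) plus direction totals.

    (direction, pattern) rows partition the responder set; the total rows
    optionally count reversal genes in both direction totals.
    """
    rows = []
    responders = [c for c in calls if c.direction != "none"]
    for direction in ("induced", "repressed", "reversal"):
        for pattern in ("sustained", "transient", "delayed", "reversal"):
            if (direction == "reversal") != (pattern == "reversal"):
                continue
            n = sum(1 for c in responders if c.direction == direction and c.pattern == pattern)
            rows.append({"direction": direction, "pattern": pattern, "count": n})
    n_rev = sum(1 for c in responders if c.direction == "reversal")
    for direction in ("induced", "repressed"):
        n = sum(1 for c in responders if c.direction == direction)
        if count_reversal_in_directions:
            n += n_rev
        rows.append({"direction": direction, "pattern": "total", "count": n})
    return pd.DataFrame(rows, columns=["direction", "pattern", "count"])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def write_calls(calls: Sequence[ResponseCall], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "direction": [c.direction for c in calls],
            "pattern": [c.pattern for c in calls],
            "onset_window": ["" if c.onset_window is None else c.onset_window for c in calls],
            "sub_flag": ["" if c.sub_flag is None else c.sub_flag for c in calls],
        }
    )
    write_tsv(df, path)


def read_calls(path) -> list[ResponseCall]:
    df = read_tsv(path)
    calls = []
    for _, row in df.iterrows():
        onset = row["onset_window"]
        onset = None if (pd.isna(onset) or onset == "") else int(onset)
        sub = row["sub_flag"]
        sub = None if (pd.isna(sub) or sub == "") else str(sub)
        calls.append(ResponseCall(str(row["gene_id"]), str(row["direction"]),
                                  str(row["pattern"]), onset, sub))
    return calls
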