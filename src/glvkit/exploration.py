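"""Input-data exploration: core-taxa filtering, correlation networks,
moving-average smoothing and summary statistics.

Core taxa are those detected (nonzero) in more than 70% of sampled
time points — i.e. strictly fewer than 30% zeros by default.  The
co-occurrence network connects core taxa whose abundance series have
a Pearson correlation of at least 0.5 in magnitude.  Correlation is
computed on the raw abundances; smoothing is a visualization aid and
is never applied before parameter estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables import AbundanceTable

__all__ = [
    "CorrelationNetwork",
    "core_taxa",
    "correlation_network",
    "moving_average",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """Undirected thresholded Pearson co-occurrence network.

    ``edges`` are (taxon_a, taxon_b, r) triples with taxon_a < taxon_b
    lexicographically and |r| at or beyond the thresholds.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float]]


def core_taxa(
    table: AbundanceTable, max_zero_fraction: float = 0.3
) -> list[str]:
    """Taxa whose zero fraction is strictly below ``max_zero_fraction``."""
    zero_frac = (table.values == 0).mean(axis=0)
    return [t for t, z in zip(table.taxa, zero_frac) if z < max_zero_fraction]


def correlation_network(
    table: AbundanceTable,
    pos_threshold: float = 0.5,
    neg_threshold: float = -0.5,
    max_zero_fraction: float = 0.3,
) -> CorrelationNetwork:
    """Build the thresholded Pearson network over the core taxa.

    An edge is kept iff r >= pos_threshold or r <= neg_threshold.
    Pairs involving a constant series have undefined correlation and
    are skipped with a logged warning.
    """
    if table.n_times < 3:
        raise ValidationError(
            f"correlation needs >= 3 time points, got {table.n_times}"
        )
    if not (neg_threshold < 0 < pos_threshold):
        raise ValidationError("thresholds must satisfy neg < 0 < pos")
    nodes = core_taxa(table, max_zero_fraction)
    edges: list[tuple[str, str, float]] = []
    for a, b in ((x, y) for i, x in enumerate(nodes) for y in nodes[i + 1 :]):
        sa, sb = table.series(a), table.series(b)
        if np.ptp(sa) == 0 or np.ptp(sb) == 0:
            logger.warning(
                "skipping pair (%s, %s): constant series, correlation undefined",
                a,
                b,
            )
            continue
        r = float(stats.pearsonr(sa, sb).statistic)
        if r >= pos_threshold or r <= neg_threshold:
            lo, hi = sorted((a, b))
            edges.append((lo, hi, r))
    return CorrelationNetwork(nodes=nodes, edges=edges)


def moving_average(series, window: int = 3) -> np.ndarray:
    """Centered moving average with edge truncation.

    ``window`` must be odd and >= 1; near the boundaries the effective
    window shrinks to the available points.  ``window=1`` is the
    identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("cannot smooth an empty series")
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def summarize(table: AbundanceTable) -> pd.DataFrame:
    """Per-taxon summary: mean, median, min, max and zero fraction."""
    v = table.values
    return pd.DataFrame(
        {
            "mean": v.mean(axis=0),
            "median": np.median(v, axis=0),
            "min": v.min(axis=0),
            "max": v.max(axis=0),
            "zero_fraction": (v == 0).mean(axis=0),
        },
        index=pd.Index(table.taxa, name="Taxon"),
    )
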