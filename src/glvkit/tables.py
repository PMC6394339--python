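"""Time-indexed taxa abundance tables.

The central observed-data container: rows are sampling time points
(strictly increasing, possibly irregularly spaced), columns are taxa,
and every abundance is a finite nonnegative number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["AbundanceTable"]


@dataclass
class AbundanceTable:
    """A taxa-by-time abundance matrix with numeric sampling times.

    Parameters
    ----------
    times
        Strictly increasing sampling times (arbitrary units).
    taxa
        Unique, non-empty taxon names (whitespace-trimmed on construction).
    values
        Matrix of shape ``(len(times), len(taxa))`` with finite
        nonnegative abundances.
    metadata
        Optional mapping from time-point index to a label string.
    """

    times: np.ndarray
    taxa: list[str]
    values: np.ndarray
    metadata: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.taxa = [str(t).strip() for t in self.taxa]
        self._validate()

    def _validate(self) -> None:
        if len(self.taxa) == 0:
            raise ValidationError("abundance table needs at least one taxon")
        if any(t == "" for t in self.taxa):
            raise FormatError("empty taxon name")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon names after trimming: {dupes}")
        if self.times.ndim != 1:
            raise ValidationError("times must be one-dimensional")
        if self.values.shape != (self.times.size, len(self.taxa)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.times.size} times x {len(self.taxa)} taxa"
            )
        if not np.all(np.isfinite(self.times)):
            raise ValidationError("non-finite sampling time")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            bad = np.nonzero(dt <= 0)[0]
            raise ValidationError(
                "times must be strictly increasing; offending rows "
                f"(0-based): {[(int(i), int(i) + 1) for i in bad]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite abundance value")
        if np.any(self.values < 0):
            r, c = np.nonzero(self.values < 0)
            raise ValidationError(
                f"negative abundance at row {int(r[0])}, taxon "
                f"{self.taxa[int(c[0])]!r}"
            )

    # ---- constructors -------------------------------------------------

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, metadata: dict[int, str] | None = None
    ) -> "AbundanceTable":
        """Build from a DataFrame whose index holds the sampling times."""
        order = np.argsort(frame.index.to_numpy())
        frame = frame.iloc[order]
        return cls(
            times=frame.index.to_numpy(dtype=float),
            taxa=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            metadata=metadata,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.taxa)
        frame.insert(0, "Time", self.times)
        return frame

    # ---- accessors ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def series(self, taxon: str) -> np.ndarray:
        """Abundance series of one taxon across all time points."""
        try:
            j = self.taxa.index(taxon)
        except ValueError:
            raise ValidationError(f"unknown taxon {taxon!r}") from None
        return self.values[:, j].copy()

    def subset(self, taxa: list[str]) -> "AbundanceTable":
        """Restrict to the given taxa, in the given order."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise ValidationError(f"taxa not in table: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return AbundanceTable(
            times=self.times.copy(),
            taxa=list(taxa),
            values=self.values[:, idx].copy(),
            metadata=dict(self.metadata) if self.metadata else None,
        )

    def window(self, start: int, end: int) -> "AbundanceTable":
        """Slice rows by 0-based time-point index, both ends inclusive."""
        if not (0 <= start < end < self.n_times):
            raise ValidationError(
                f"window ({start}, {end}) out of range for {self.n_times} "
                "time points (need start < end, both in range)"
            )
        meta = None
        if self.metadata:
            meta = {
                i - start: lab
                for i, lab in self.metadata.items()
                if start <= i <= end
            }
        return AbundanceTable(
            times=self.times[start : end + 1].copy(),
            taxa=list(self.taxa),
            values=self.values[start : end + 1].copy(),
            metadata=meta,
        )
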