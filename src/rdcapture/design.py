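"""Sampling layout of a robust-design study.

A robust design consists of *primary occasions* (field seasons, between which
the population is open to survival and temporary-emigration dynamics), each
subdivided into *secondary occasions* (months or days, across which the
population is treated as closed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class SamplingDesign:
    """Primary/secondary occasion layout of a robust-design study.

    Parameters
    ----------
    primary_labels
        One label per primary occasion (e.g. years ``["2011", ..., "2015"]``).
    secondary_labels
        For each primary, an ordered list of secondary-occasion labels.
        Secondary occasions are positional within a primary; calendar dates
        are metadata only.
    interval_lengths
        Time between consecutive primaries, in years.  Defaults to 1.0 for
        every interval.
    """

    primary_labels: tuple[str, ...]
    secondary_labels: tuple[tuple[str, ...], ...]
    interval_lengths: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.primary_labels) < 1:
            raise ValueError("design needs at least one primary occasion")
        if len(self.secondary_labels) != len(self.primary_labels):
            raise ValueError("secondary_labels must match primary_labels")
        for lab, secs in zip(self.primary_labels, self.secondary_labels):
            if len(secs) < 1:
                raise ValueError(
                    f"primary {lab!r} has no secondary occasions"
                )
        intervals = self.interval_lengths
        if not intervals:
            intervals = tuple(1.0 for _ in range(self.n_primary - 1))
            object.__setattr__(self, "interval_lengths", intervals)
        if len(intervals) != self.n_primary - 1:
            raise ValueError(
                f"interval_lengths has length {len(intervals)}, "
                f"expected {self.n_primary - 1}"
            )
        if any(dt <= 0 for dt in intervals):
            raise ValueError("interval lengths must be positive")

    @classmethod
    def from_counts(
        cls,
        secondaries_per_primary: Sequence[int],
        primary_labels: Sequence[str] | None = None,
        interval_lengths: Sequence[float] | None = None,
    ) -> "SamplingDesign":
        """Build a design from the number of secondaries in each primary."""
        T = len(secondaries_per_primary)
        if primary_labels is None:
            primary_labels = [f"primary{i + 1}" for i in range(T)]
        secs = tuple(
            tuple(f"sec{j + 1}" for j in range(k)) for k in secondaries_per_primary
        )
        return cls(
            tuple(str(x) for x in primary_labels),
            secs,
            tuple(interval_lengths) if interval_lengths is not None else (),
        )

    @property
    def n_primary(self) -> int:
        return len(self.primary_labels)

    @property
    def n_secondary(self) -> tuple[int, ...]:
        """Number of secondary occasions within each primary."""
        return tuple(len(s) for s in self.secondary_labels)

    @property
    def total_secondaries(self) -> int:
        return sum(self.n_secondary)

    @property
    def column_slices(self) -> tuple[slice, ...]:
        """Column ranges of each primary in the flat capture matrix."""
        out, start = [], 0
        for k in self.n_secondary:
            out.append(slice(start, start + k))
            start += k
        return tuple(out)


#: Table-1 layout for the striped/common dolphin matrix: five annual primaries
#: with 3, 4, 4, 4, 4 monthly secondary occasions.
STRIPED_DESIGN = SamplingDesign.from_counts(
    [3, 4, 4, 4, 4], primary_labels=["2011", "2012", "2013", "2014", "2015"]
)

#: Table-1 layout for the bottlenose dolphin matrix: five primaries of 3, 3,
#: 4, 4, 3 daily secondary occasions.
BOTTLENOSE_DESIGN = SamplingDesign.from_counts(
    [3, 3, 4, 4, 3], primary_labels=["2011", "2012", "2013", "2014", "2015"]
)
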