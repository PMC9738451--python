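"""Ordered timepoint designs for time-course experiments."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Default study layout: an uncut control treated as the first of five
#: ordered states, followed by 2, 7, 14 and 21 days post-amputation, with
#: replicate counts (3, 2, 2, 3, 2) -- twelve samples in total.
DEFAULT_TIMEPOINTS = ("control", "2dpa", "7dpa", "14dpa", "21dpa")
DEFAULT_REPLICATES = (3, 2, 2, 3, 2)


@dataclass(frozen=True)
class TimepointDesign:
    """Ordered timepoints with per-timepoint replicate counts.

    Timepoint order is positional: ``timepoints[0]`` is the earliest state
    (typically the unperturbed control) and later entries are successive
    stages. Sample identifiers are derived deterministically as
    ``{label}_r{k}``.
    """

    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    replicates: tuple[int, ...] = DEFAULT_REPLICATES

    def __post_init__(self) -> None:
        if len(self.timepoints) == 0:
            raise ValueError("design must contain at least one timepoint")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoint labels must be unique")
        if len(self.replicates) != len(self.timepoints):
            raise ValueError("one replicate count required per timepoint")
        for r in self.replicates:
            if not isinstance(r, (int,)) or isinstance(r, bool):
                raise ValueError(f"replicate counts must be integers, got {r!r}")
            if r < 1:
                raise ValueError(f"replicate counts must be >= 1, got {r}")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_samples(self) -> int:
        return int(sum(self.replicates))

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{label}_r{k + 1}"
            for label, n in zip(self.timepoints, self.replicates)
            for k in range(n)
        ]

    def order_of(self, label: str) -> int:
        """Positional index of a timepoint label."""
        try:
            return self.timepoints.index(label)
        except ValueError:
            raise KeyError(f"unknown timepoint {label!r}") from None

    def samples_for(self, label: str) -> list[str]:
        n = self.replicates[self.order_of(label)]
        return [f"{label}_r{k + 1}" for k in range(n)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form design table: sample_id, timepoint, order, replicate."""
        rows = []
        for order, (label, n) in enumerate(zip(self.timepoints, self.replicates)):
            for k in range(n):
                rows.append(
                    {
                        "sample_id": f"{label}_r{k + 1}",
                        "timepoint": label,
                        "order": order,
                        "replicate": k + 1,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimepointDesign":
        """Rebuild a design from its long-form table (inverse of to_frame)."""
        required = {"sample_id", "timepoint", "order", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        ordered = frame.sort_values(["order", "replicate"])
        labels: list[str] = []
        reps: list[int] = []
        for (order, label), grp in ordered.groupby(["order", "timepoint"], sort=True):
            labels.append(str(label))
            reps.append(len(grp))
        design = cls(timepoints=tuple(labels), replicates=tuple(reps))
        if design.sample_ids != list(ordered["sample_id"]):
            raise ValueError(
                "design table sample ids do not follow the {label}_r{k} layout"
            )
        return design
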