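"""Per-sample survival outcome container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class SurvivalOutcome:
    """Right-censored time-to-event data for one set of samples.

    Attributes
    ----------
    time:
        Observed follow-up time (years), strictly positive.
    event:
        1 if the event (death) was observed at ``time``, 0 if censored.
    cluster:
        Optional per-sample cluster label (e.g. pedigree or subject id)
        for clustered sandwich standard errors.
    stratum:
        Optional per-sample stratum label (e.g. cohort x ethnicity) for
        stratified meta-analysis.
    """

    time: np.ndarray
    event: np.ndarray
    cluster: np.ndarray | None = None
    stratum: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.ndim != 1 or self.time.shape != self.event.shape:
            raise InvalidArgumentError("time and event must be aligned 1-d arrays")
        if np.any(self.time <= 0):
            raise InvalidArgumentError("follow-up times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise InvalidArgumentError("event indicator must be 0 or 1")
        for name in ("cluster", "stratum"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.shape != self.time.shape:
                    raise InvalidArgumentError(f"{name} labels must align with time")
                setattr(self, name, lab)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, index) -> "SurvivalOutcome":
        """Row-subset by positional index (array of ints or boolean mask)."""
        index = np.asarray(index)
        return SurvivalOutcome(
            time=self.time[index],
            event=self.event[index],
            cluster=None if self.cluster is None else self.cluster[index],
            stratum=None if self.stratum is None else self.stratum[index],
        )
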