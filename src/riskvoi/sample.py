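"""The development sample: covariates plus a binary outcome."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DevelopmentSample"]


@dataclass(frozen=True)
class DevelopmentSample:
    """A rectangular development data set of ``n`` independent observations.

    ``covariates`` is the numeric design matrix (categoricals already
    encoded, transforms already applied) and ``outcomes`` the 0/1 event
    indicator aligned row by row.  Model fitting additionally requires at
    least one event and one non-event; that is enforced by the developers at
    fit time, not here, so degenerate samples can still be constructed and
    inspected.
    """

    covariates: pd.DataFrame
    outcomes: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not isinstance(self.covariates, pd.DataFrame):
            object.__setattr__(
                self, "covariates", pd.DataFrame(np.asarray(self.covariates, float))
            )
        y = np.asarray(self.outcomes, dtype=float).ravel()
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("outcomes must be coded 0/1")
        if len(self.covariates) != y.size:
            raise ValueError(
                f"covariates have {len(self.covariates)} rows but outcomes "
                f"have length {y.size}"
            )
        if y.size < 1:
            raise ValueError("a development sample needs at least one observation")
        if not all(np.issubdtype(dt, np.number) for dt in self.covariates.dtypes):
            raise ValueError("covariates must be numeric (encode categoricals first)")
        object.__setattr__(self, "outcomes", y.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.outcomes.size)

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    @property
    def X(self) -> np.ndarray:
        """Design matrix as a float ndarray (n x k)."""
        return self.covariates.to_numpy(dtype=float)

    def subsample(self, indices) -> "DevelopmentSample":
        idx = np.asarray(indices, dtype=int)
        return DevelopmentSample(
            self.covariates.iloc[idx].reset_index(drop=True), self.outcomes[idx]
        )
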