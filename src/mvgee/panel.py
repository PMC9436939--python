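"""Long-format panel container for multivariate longitudinal data.

A :class:`PanelDataset` holds repeated measurements of one or more named
responses on a set of subjects, together with baseline (time-constant)
covariates. It is the common currency between the simulator, the design
builder and the CSV reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PanelDataset", "PanelValidationError"]

#: Columns every long-format panel must carry; anything else is a covariate.
CORE_COLUMNS = ("subject_id", "visit_time", "response", "value")


class PanelValidationError(ValueError):
    """Raised when a long-format panel violates the format contract."""


@dataclass
class PanelDataset:
    """Repeated measurements of ``k`` responses on ``N`` subjects.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format with columns ``subject_id, visit_time, response, value``
        plus one column per baseline covariate. Each
        ``(subject_id, visit_time, response)`` triple appears at most once.
    response_units : dict, optional
        Unit label per response name (e.g. ``{"FBS": "mg/dl"}``), carried
        as metadata only.
    """

    data: pd.DataFrame
    response_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(
                f"panel is missing required column(s): {missing}"
            )
        key = ["subject_id", "visit_time", "response"]
        dup = df.duplicated(subset=key)
        if dup.any():
            offenders = df.loc[dup, key].head(10).to_dict("records")
            raise PanelValidationError(
                f"duplicate (subject, visit, response) measurement rows: {offenders}"
            )
        if df["value"].isna().any():
            rows = df.index[df["value"].isna()].tolist()[:10]
            raise PanelValidationError(f"missing response values at rows {rows}")
        for cov in self.covariate_names:
            per_subject = df.groupby("subject_id", sort=False)[cov].nunique(dropna=False)
            varying = per_subject[per_subject > 1]
            if len(varying):
                raise PanelValidationError(
                    f"covariate {cov!r} varies within subject(s) "
                    f"{varying.index.tolist()[:5]}; only baseline covariates "
                    "are supported"
                )
            if df[cov].isna().any():
                bad = df.loc[df[cov].isna(), "subject_id"].unique().tolist()[:5]
                raise PanelValidationError(
                    f"covariate {cov!r} missing for subject(s) {bad}"
                )

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in CORE_COLUMNS]

    @property
    def response_names(self) -> list[str]:
        return list(pd.unique(self.data["response"]))

    @property
    def subject_ids(self) -> np.ndarray:
        return pd.unique(self.data["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def visit_times(self) -> np.ndarray:
        return np.sort(pd.unique(self.data["visit_time"]))

    def subset_response(self, response: str) -> "PanelDataset":
        """Panel restricted to a single response (for univariate fits)."""
        if response not in self.response_names:
            raise KeyError(f"response {response!r} not present in panel")
        sub = self.data[self.data["response"] == response].reset_index(drop=True)
        units = {response: self.response_units.get(response, "")}
        return PanelDataset(sub, response_units=units)

    def to_csv(self, path) -> None:
        """Write the long-format table; round-trips through ``read_panel``."""
        cols = list(CORE_COLUMNS) + self.covariate_names
        self.data[cols].to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return self.data.equals(other.data)

    def __len__(self) -> int:
        return len(self.data)
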