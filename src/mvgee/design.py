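"""Stacked-response design matrices for multivariate marginal models.

The k responses of each subject are stacked into a single response vector
and a response-type indicator ``rtype`` (0 for the first response, 1 for
the second, ...) is interacted with selected terms. A term whose
interaction with ``rtype`` is present gets a response-specific effect; a
term without one is shared: a single coefficient applies to every
response. For two responses the model is

    E[Y | X] = b0 + b1*time + b2*X1 + ... + b_r*rtype
               + b_tr*(time x rtype) + b_1r*(X1 x rtype) + ...

so the first response's effects are the base coefficients and the second
response's are base + interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = [
    "ModelSpec",
    "StackedDesign",
    "stack_responses",
    "unstack_design",
    "response_specific_coefficients",
]

SPECIAL_TERMS = ("intercept", "time")


class DesignError(ValueError):
    """Raised when a panel cannot be stacked under a model specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Declares the mean model of a stacked multivariate marginal fit.

    Attributes
    ----------
    responses : tuple of str
        Ordered response names; the position defines the rtype code
        (first -> 0, second -> 1, ...).
    covariates : tuple of str
        Baseline covariate column names entering as main effects.
    interaction_set : frozenset of str
        Subset of ``{"intercept", "time"} | covariates`` whose effects are
        response-specific (each gets a ``term:rtype`` column; the
        intercept's interaction is the ``rtype`` main effect itself).
    corstr : str
        Working correlation structure for the fit.
    alpha_level : float
        Significance threshold used by the model-reduction step.
    """

    responses: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    interaction_set: frozenset[str] = field(default_factory=frozenset)
    family: str = "gaussian"
    link: str = "identity"
    corstr: str = "exchangeable"
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if len(self.responses) < 1:
            raise DesignError("at least one response required")
        if len(set(self.responses)) != len(self.responses):
            raise DesignError("response names must be distinct")
        allowed = set(SPECIAL_TERMS) | set(self.covariates)
        extra = set(self.interaction_set) - allowed
        if extra:
            raise DesignError(
                f"interaction_set entries {sorted(extra)} are not model terms"
            )
        if self.family != "gaussian" or self.link != "identity":
            raise DesignError("only the Gaussian / identity model is supported")
        if self.corstr not in ("independence", "exchangeable", "ar1", "unstructured"):
            raise DesignError(f"unknown working correlation {self.corstr!r}")
        if not 0.0 < self.alpha_level < 1.0:
            raise DesignError("alpha_level must be in (0, 1)")
        object.__setattr__(self, "responses", tuple(self.responses))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interaction_set", frozenset(self.interaction_set))

    @property
    def k(self) -> int:
        return len(self.responses)

    @property
    def base_terms(self) -> list[str]:
        return ["intercept", "time", *self.covariates]

    def full_interactions(self) -> "ModelSpec":
        """Spec with every term response-specific (the Step-I full model)."""
        return replace(
            self, interaction_set=frozenset(set(SPECIAL_TERMS) | set(self.covariates))
        )

    def rtype_names(self) -> list[str]:
        """Names of the rtype dummy columns (k-1 of them; 'rtype' for k=2)."""
        if self.k == 2:
            return ["rtype"]
        return [f"rtype{j}" for j in range(1, self.k)]

    def column_names(self) -> list[str]:
        cols = list(self.base_terms)
        rt = self.rtype_names()
        if self.k > 1:
            if "intercept" in self.interaction_set:
                cols += rt
            for term in ["time", *self.covariates]:
                if term in self.interaction_set:
                    cols += [f"{term}:{r}" for r in rt]
        return cols

    def interaction_column(self, term: str, j: int = 1) -> str:
        """Design-column name of a term's interaction with rtype code j."""
        rt = self.rtype_names()[j - 1]
        return rt if term == "intercept" else f"{term}:{rt}"


@dataclass
class StackedDesign:
    """Design matrix and bookkeeping for a stacked multivariate GEE fit.

    Rows are grouped by subject and ordered within subject by visit time
    then response index. ``visit_index`` is the rank of the row's visit
    time in the panel-wide visit grid (the lag unit for AR-1), and
    ``response_index`` the rtype code of the row.
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    cluster: np.ndarray          # subject id per row (grouped, contiguous)
    visit_time: np.ndarray
    visit_index: np.ndarray
    response_index: np.ndarray
    response_names: tuple[str, ...]
    spec: ModelSpec

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (self.X.shape[0] == n == len(self.cluster)):
            raise DesignError("y, X and cluster_index lengths disagree")
        if self.X.shape[1] != len(self.columns):
            raise DesignError("column names do not match design matrix width")
        if len(set(self.columns)) != len(self.columns):
            raise DesignError("design column names must be unique")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster))

    def cluster_slices(self) -> list[slice]:
        """Contiguous row slice per subject, in order of first appearance."""
        _, starts = np.unique(self.cluster, return_index=True)
        starts = np.sort(starts)
        bounds = list(starts) + [len(self.cluster)]
        return [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]

    def to_frame(self) -> pd.DataFrame:
        """Design as a DataFrame (for CSV export / debugging)."""
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "subject_id", self.cluster)
        df.insert(1, "visit_time", self.visit_time)
        df.insert(2, "response", [self.response_names[j] for j in self.response_index])
        df.insert(3, "y", self.y)
        return df


def stack_responses(panel: PanelDataset, spec: ModelSpec) -> StackedDesign:
    """Build the stacked design for ``panel`` under ``spec``.

    One row per observed (subject, visit, response); a response missing at
    a visit simply contributes no row (unbalanced clusters are allowed).
    Main-effect columns repeat across the responses' rows; interaction
    columns are elementwise products of the term with the rtype dummies.
    """
    df = panel.data
    present = set(df["response"])
    missing_resp = [r for r in spec.responses if r not in present]
    if missing_resp:
        raise DesignError(f"responses {missing_resp} not present in panel")
    for cov in spec.covariates:
        if cov not in df.columns:
            raise DesignError(f"covariate {cov!r} not present in panel")

    sub = df[df["response"].isin(spec.responses)].copy()
    code = {r: j for j, r in enumerate(spec.responses)}
    sub["_rcode"] = sub["response"].map(code)
    sub = sub.sort_values(
        ["subject_id", "visit_time", "_rcode"], kind="mergesort"
    ).reset_index(drop=True)

    for cov in spec.covariates:
        if sub[cov].isna().any():
            bad = sub.loc[sub[cov].isna(), "subject_id"].iloc[0]
            raise DesignError(f"covariate {cov!r} missing for subject {bad!r}")

    times = sub["visit_time"].to_numpy(dtype=float)
    grid = np.sort(pd.unique(df["visit_time"]))
    visit_index = np.searchsorted(grid, times)
    rcode = sub["_rcode"].to_numpy()

    base_cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(sub)),
        "time": times,
    }
    for cov in spec.covariates:
        base_cols[cov] = sub[cov].to_numpy(dtype=float)

    cols: list[str] = []
    mats: list[np.ndarray] = []
    for term in spec.base_terms:
        cols.append(term)
        mats.append(base_cols[term])
    if spec.k > 1:
        rt_dummies = [
            (rcode == j).astype(float) for j in range(1, spec.k)
        ]
        rt_names = spec.rtype_names()
        if "intercept" in spec.interaction_set:
            cols += rt_names
            mats += rt_dummies
        for term in ["time", *spec.covariates]:
            if term in spec.interaction_set:
                for name, dummy in zip(rt_names, rt_dummies):
                    cols.append(f"{term}:{name}")
                    mats.append(base_cols[term] * dummy)

    return StackedDesign(
        y=sub["value"].to_numpy(dtype=float),
        X=np.column_stack(mats),
        columns=cols,
        cluster=sub["subject_id"].to_numpy(),
        visit_time=times,
        visit_index=visit_index,
        response_index=rcode,
        response_names=spec.responses,
        spec=spec,
    )


def unstack_design(design: StackedDesign) -> pd.DataFrame:
    """Recover the long-format panel rows (subject, visit, response, value)."""
    return pd.DataFrame(
        {
            "subject_id": design.cluster,
            "visit_time": design.visit_time,
            "response": [design.response_names[j] for j in design.response_index],
            "value": design.y,
        }
    )


def response_specific_coefficients(fit, spec: ModelSpec) -> pd.DataFrame:
    """Per-response coefficients implied by a stacked fit.

    For the reference response (rtype 0) each term's coefficient is its
    base coefficient. For response j > 0 it is base + interaction when the
    term is response-specific, and the base (shared) coefficient
    otherwise. Standard errors of sums come from the full robust
    covariance: var(a + b) = var(a) + var(b) + 2 cov(a, b).

    Returns a DataFrame with one row per (term, response):
    ``term, response, estimate, se, shared``.
    """
    names = list(fit.params.index)
    expected = spec.column_names()
    if set(names) != set(expected):
        raise DesignError(
            "fit coefficients do not match the model specification "
            f"(fit: {names}, spec: {expected})"
        )
    beta = fit.params
    V = fit.cov_robust
    rows = []
    for term in spec.base_terms:
        shared = term not in spec.interaction_set or spec.k == 1
        for j, resp in enumerate(spec.responses):
            contrast = pd.Series(0.0, index=beta.index)
            contrast[term] = 1.0
            if j > 0 and not shared:
                contrast[spec.interaction_column(term, j)] = 1.0
            est = float(contrast @ beta)
            var = float(contrast @ V @ contrast)
            rows.append(
                {
                    "term": term,
                    "response": resp,
                    "estimate": est,
                    "se": float(np.sqrt(var)),
                    "shared": shared,
                }
            )
    return pd.DataFrame(rows)
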