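"""Working-correlation selection, Wald inference and model reduction.

Covers the inferential workflow around the stacked-response fit:

* QIC (quasi-likelihood under the independence model criterion) for
  comparing working-correlation structures;
* per-response univariate QIC selection of the structure, summed across
  responses;
* robust Wald tests (two-sided by default, with a one-sided reporting
  mode);
* the three-step procedure: (I) fit the full model with every term
  interacted with the response indicator, (II) drop, in one simultaneous
  pass, every rtype interaction whose coefficient is not significantly
  different from zero, (III) refit; terms whose interactions were dropped
  keep a single shared coefficient across responses, which is what buys
  the efficiency gain of the joint model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    ModelSpec,
    StackedDesign,
    response_specific_coefficients,
    stack_responses,
)
from .gee import GEEError, GEEFit, fit_gee
from .panel import PanelDataset

__all__ = [
    "QICValue",
    "qic",
    "select_structure",
    "wald_tests",
    "reduce_model",
    "three_step_fit",
    "ThreeStepResult",
    "N_CORR_PARAMS",
]

#: Correlation-parameter count per structure, used for complexity tie-breaks.
N_CORR_PARAMS = {
    "independence": 0,
    "exchangeable": 1,
    "ar1": 1,
    "unstructured": np.inf,  # m(m-1)/2; always the most complex
}


@dataclass(frozen=True)
class QICValue:
    """QIC decomposition for one fit.

    qic = -2 * QL + penalty, with QL the Gaussian quasi-likelihood under
    the independence model at the fitted coefficients,
    QL = -sum (y - mu)^2 / (2 phi), and
    penalty = 2 * trace(Omega_I @ V_R) where Omega_I = X'X / phi is the
    model-based information under independence and V_R the robust
    covariance of the fit. Under a correctly specified independence model
    the penalty tends to 2p.
    """

    quasi_likelihood: float
    penalty: float
    qic: float
    structure: str


def qic(fit: GEEFit, design: StackedDesign | None = None) -> QICValue:
    """Pan's QIC of a converged Gaussian GEE fit."""
    if not fit.converged:
        raise GEEError("QIC requires a converged fit")
    design = design if design is not None else fit.design
    resid = design.y - design.X @ fit.params.to_numpy()
    phi = fit.scale
    ql = float(-(resid @ resid) / (2.0 * phi))
    omega_i = design.X.T @ design.X / phi
    penalty = float(2.0 * np.trace(omega_i @ fit.cov_robust.to_numpy()))
    value = -2.0 * ql + penalty
    if not np.isfinite(value):
        raise GEEError("QIC is not finite")
    return QICValue(ql, penalty, value, fit.working.structure)


def select_structure(
    panel: PanelDataset,
    spec: ModelSpec,
    structures: tuple[str, ...] = ("independence", "exchangeable", "ar1", "unstructured"),
) -> tuple[pd.DataFrame, str]:
    """Choose the working correlation by summed univariate QIC.

    Each response is fitted on its own (main effects only, no stacking)
    under every candidate structure; per-response QICs are summed and the
    structure with the smallest total wins, ties going to the structure
    with fewer correlation parameters. Candidates that fail to fit or to
    converge for any response are excluded with a warning, never silently
    ranked.

    Returns
    -------
    (table, chosen) : the ranked QIC table (one row per surviving
    candidate, one QIC column per response plus the total) and the name
    of the selected structure.
    """
    if len(structures) < 1:
        raise ValueError("at least one candidate structure required")
    rows = []
    for structure in structures:
        entry: dict[str, float | str] = {"structure": structure}
        total = 0.0
        ok = True
        for resp in spec.responses:
            uni_spec = ModelSpec(
                responses=(resp,),
                covariates=spec.covariates,
                corstr=structure,
                alpha_level=spec.alpha_level,
            )
            try:
                design = stack_responses(panel.subset_response(resp), uni_spec)
                fit = fit_gee(design, corstr=structure)
                if not fit.converged:
                    raise GEEError("did not converge")
                q = qic(fit)
            except GEEError as exc:
                warnings.warn(
                    f"structure {structure!r} excluded "
                    f"(response {resp!r}: {exc})",
                    stacklevel=2,
                )
                ok = False
                break
            entry[f"qic_{resp}"] = q.qic
            total += q.qic
        if ok:
            entry["qic_total"] = total
            rows.append(entry)
    if not rows:
        raise GEEError("no candidate working-correlation structure could be fitted")
    table = pd.DataFrame(rows)
    # argmin with ties broken toward fewer correlation parameters
    order = table.assign(
        _complexity=[N_CORR_PARAMS[s] for s in table["structure"]]
    ).sort_values(["qic_total", "_complexity"], kind="mergesort")
    chosen = str(order.iloc[0]["structure"])
    table = table.sort_values("qic_total", kind="mergesort").reset_index(drop=True)
    return table, chosen


def wald_tests(fit: GEEFit, one_sided: bool = False) -> pd.DataFrame:
    """Robust Wald tests for every coefficient of a fit.

    z = estimate / robust SE; the default p-value is the two-sided normal
    tail 2*(1 - Phi(|z|)). ``one_sided=True`` reports 1 - Phi(|z|), the
    tail in the direction of the observed sign.

    Returns a DataFrame indexed by term with columns
    ``estimate, se, z, p``. A zero SE makes the test undefined and raises.
    """
    se = fit.se_robust
    zero = se[se <= 0]
    if len(zero):
        raise GEEError(
            f"zero robust SE for term(s) {list(zero.index)}; p-value undefined"
        )
    z = fit.params / se
    p = stats.norm.sf(np.abs(z))
    if not one_sided:
        p = 2.0 * p
    return pd.DataFrame(
        {"estimate": fit.params, "se": se, "z": z, "p": p}, index=fit.params.index
    )


def reduce_model(
    full_fit: GEEFit, spec: ModelSpec, alpha_level: float | None = None,
    one_sided: bool = False,
) -> ModelSpec:
    """Step II: prune non-significant response-type interactions.

    Every rtype-interaction term with p >= alpha_level in the full fit is
    removed from the interaction set in ONE simultaneous pass (not
    sequentially); the intercept and time interactions are eligible like
    any other term. Main effects are always retained, so a pruned term
    keeps a single shared coefficient.
    """
    alpha_level = spec.alpha_level if alpha_level is None else alpha_level
    table = wald_tests(full_fit, one_sided=one_sided)
    kept = set()
    for term in spec.interaction_set:
        cols = [spec.interaction_column(term, j) for j in range(1, spec.k)]
        missing = [c for c in cols if c not in table.index]
        if missing:
            raise GEEError(
                f"interaction column(s) {missing} absent from fit; the fit "
                "does not correspond to this specification"
            )
        # with k > 2 a term stays response-specific if ANY dummy is significant
        if any(table.loc[c, "p"] < alpha_level for c in cols):
            kept.add(term)
    return replace(spec, interaction_set=frozenset(kept))


@dataclass
class ThreeStepResult:
    """Bundle returned by the end-to-end three-step procedure."""

    structure_table: pd.DataFrame
    chosen_structure: str
    full_spec: ModelSpec
    full_fit: GEEFit
    reduced_spec: ModelSpec
    final_fit: GEEFit
    inference: pd.DataFrame


def inference_table(
    fit: GEEFit, spec: ModelSpec, one_sided: bool = False
) -> pd.DataFrame:
    """Per-response coefficient report for a stacked fit.

    One row per (term, response) with estimate, robust SE, z and p;
    shared terms repeat the identical row for every response, making the
    sharing visible in the final report.
    """
    coefs = response_specific_coefficients(fit, spec)
    z = coefs["estimate"] / coefs["se"]
    p = stats.norm.sf(np.abs(z))
    if not one_sided:
        p = 2.0 * p
    out = coefs.copy()
    out["z"] = z
    out["p"] = p
    return out


def three_step_fit(
    panel: PanelDataset,
    spec: ModelSpec,
    structures: tuple[str, ...] = ("independence", "exchangeable", "ar1", "unstructured"),
    select: bool = True,
    one_sided: bool = False,
) -> ThreeStepResult:
    """Run the full workflow on a panel.

    1. choose the working correlation by summed univariate QIC (skipped
       when ``select=False``, keeping ``spec.corstr``);
    2. Step I: fit the full model with every term response-specific;
    3. Step II: drop all non-significant rtype interactions in one pass;
    4. Step III: refit the reduced model and report per-response
       coefficients, shared terms appearing with identical rows.
    """
    if select:
        structure_table, chosen = select_structure(panel, spec, structures)
    else:
        structure_table = pd.DataFrame(
            [{"structure": spec.corstr, "qic_total": np.nan}]
        )
        chosen = spec.corstr
    spec = replace(spec, corstr=chosen)

    full_spec = spec.full_interactions()
    full_design = stack_responses(panel, full_spec)
    full_fit = fit_gee(full_design, corstr=chosen)

    reduced_spec = reduce_model(full_fit, full_spec, one_sided=one_sided)
    final_design = stack_responses(panel, reduced_spec)
    final_fit = fit_gee(final_design, corstr=chosen)

    inference = inference_table(final_fit, reduced_spec, one_sided=one_sided)
    return ThreeStepResult(
        structure_table=structure_table,
        chosen_structure=chosen,
        full_spec=full_spec,
        full_fit=full_fit,
        reduced_spec=reduced_spec,
        final_fit=final_fit,
        inference=inference,
    )
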