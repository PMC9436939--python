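"""CSV panel ingestion, YAML configuration and report writing.

The single on-disk data format is a tidy long-format CSV with header
``subject_id,visit_time,response,value,<covariate columns>``; visit times
are numeric months. The reader validates and never silently coerces.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import ModelSpec
from .panel import PanelDataset, PanelValidationError, CORE_COLUMNS
from .selection import ThreeStepResult
from .simulate import CovariateSpec, SimulationConfig

__all__ = [
    "read_panel",
    "write_report",
    "load_simulation_config",
    "dump_simulation_config",
    "load_model_spec",
]


def read_panel(path) -> PanelDataset:
    """Read and validate a long-format panel CSV.

    Raises :class:`PanelValidationError` naming the offending rows for
    duplicate (subject, visit, response) measurements, non-numeric visit
    times or values, missing columns, or an empty file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "response": str})
    except pd.errors.EmptyDataError as exc:
        raise PanelValidationError(f"{path}: empty file") from exc
    if df.empty:
        raise PanelValidationError(f"{path}: no data rows")
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing required column(s) {missing}")
    for col in [c for c in df.columns if c not in ("subject_id", "response")]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: 1-based and header line
            rows = [int(i) + 2 for i in bad[:10]]
            raise PanelValidationError(
                f"{path}: non-numeric entries in column {col!r} at line(s) {rows}"
            )
        df[col] = coerced
    return PanelDataset(df)


def load_simulation_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    covs = tuple(CovariateSpec(**c) for c in raw.pop("covariates", []))
    if "visit_times" in raw:
        raw["visit_times"] = tuple(float(t) for t in raw["visit_times"])
    return SimulationConfig(covariates=covs, **raw)


def dump_simulation_config(config: SimulationConfig, path) -> None:
    d = asdict(config)
    d["visit_times"] = list(d["visit_times"])
    d["covariates"] = [
        {k: v for k, v in c.items() if v is not None} for c in d["covariates"]
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_model_spec(path) -> ModelSpec:
    """Read a ModelSpec from a YAML file (same config format as the CLI)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ModelSpec(
        responses=tuple(raw["responses"]),
        covariates=tuple(raw.get("covariates", ())),
        interaction_set=frozenset(raw.get("interaction_set", ())),
        corstr=raw.get("corstr", "exchangeable"),
        alpha_level=float(raw.get("alpha_level", 0.05)),
    )


def _format_text_report(result: ThreeStepResult) -> str:
    """Human-readable final-model report, 2-decimal coefficient layout."""
    lines = []
    lines.append("Working-correlation selection (summed univariate QIC)")
    lines.append(result.structure_table.to_string(index=False, float_format="%.2f"))
    lines.append(f"Selected structure: {result.chosen_structure}")
    lines.append("")
    lines.append("Final model (shared terms repeat identical rows per response)")
    wide_rows = []
    spec = result.reduced_spec
    inf = result.inference
    for term in spec.base_terms:
        row: dict[str, object] = {"term": term}
        for resp in spec.responses:
            sel = inf[(inf["term"] == term) & (inf["response"] == resp)].iloc[0]
            row[f"{resp} coef"] = f"{sel['estimate']:.2f}"
            row[f"{resp} SE"] = f"{sel['se']:.2f}"
            row[f"{resp} z"] = f"{sel['z']:.2f}"
            row[f"{resp} P"] = f"{sel['p']:.3f}"
        row["shared"] = "yes" if term not in spec.interaction_set else "no"
        wide_rows.append(row)
    lines.append(pd.DataFrame(wide_rows).to_string(index=False))
    return "\n".join(lines) + "\n"


def write_report(
    result: ThreeStepResult,
    outdir,
    seed: int | None = None,
    config_digest: str | None = None,
    one_sided: bool = False,
) -> dict[str, Path]:
    """Write the deterministic file set for a completed three-step fit.

    Produces ``structure_selection.csv``, ``full_model.csv``,
    ``final_model.csv`` (full precision), ``report.txt`` (2-decimal
    layout) and ``manifest.json`` recording seed, package version and the
    input-configuration digest needed to reproduce the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    from .selection import wald_tests  # local import to avoid cycle at module load

    paths = {}
    paths["structure_selection"] = outdir / "structure_selection.csv"
    result.structure_table.to_csv(paths["structure_selection"], index=False)

    full = wald_tests(result.full_fit, one_sided=one_sided)
    paths["full_model"] = outdir / "full_model.csv"
    full.rename_axis("term").to_csv(paths["full_model"])

    paths["final_model"] = outdir / "final_model.csv"
    result.inference.to_csv(paths["final_model"], index=False)

    paths["report"] = outdir / "report.txt"
    paths["report"].write_text(_format_text_report(result))

    manifest = {
        "package": "mvgee",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_digest,
        "chosen_structure": result.chosen_structure,
        "n_clusters": result.final_fit.n_clusters,
        "n_observations": result.final_fit.n_obs,
        "one_sided": one_sided,
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
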