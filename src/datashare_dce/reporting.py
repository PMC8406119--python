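"""Pipeline orchestration, run manifests, and report rendering.

``run_pipeline`` chains screen -> pooled logit -> latent class ->
importance -> uptake grid over a raw survey table, records a manifest
(config hash, input hashes, seed, versions), and ``render_tables`` formats
the fitted models as markdown tables in the published layout: per-level
rows grouped by attribute, "(Ref)" rows without standard errors, and
significance markers at the 5% and 1% levels.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .domain import StudyConfig, validate_dataset
from .latent_class import LatentClassEstimate, fit_latent_class
from .mnl import MnlEstimate, fit_binary_logit
from .postestimation import relative_importance, uptake_grid
from .screening import ScreeningReport, apply_exclusions

__all__ = ["RunManifest", "PipelineResult", "run_pipeline", "render_tables"]


def _hash_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config_hash: str
    input_hashes: dict[str, str]
    seed: int
    versions: dict[str, str]
    timestamp: str

    @classmethod
    def create(
        cls, command: str, config: StudyConfig, inputs: dict[str, pd.DataFrame], seed: int
    ) -> "RunManifest":
        cfg_hash = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
        return cls(
            command=command,
            config_hash=cfg_hash,
            input_hashes={k: _hash_frame(v) for k, v in inputs.items()},
            seed=seed,
            versions={
                "datashare_dce": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config_hash": self.config_hash,
            "input_hashes": self.input_hashes,
            "seed": self.seed,
            "versions": self.versions,
            "timestamp": self.timestamp,
        }


@dataclass
class PipelineResult:
    screening: ScreeningReport
    mnl: MnlEstimate
    latent_class: LatentClassEstimate
    importance: pd.DataFrame
    uptake: pd.DataFrame
    manifest: RunManifest
    partial: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.partial = partial


def run_pipeline(
    config: StudyConfig,
    population: pd.DataFrame,
    choices: pd.DataFrame,
    seed: int = 0,
    n_classes: int = 4,
    n_starts: int = 20,
    uptake_collector: str = "healthcare_provider",
    uptake_new_user: str = "tech_company",
) -> PipelineResult:
    """screen -> fit pooled -> fit latent class -> importance -> uptake.

    Deterministic given ``seed``. A failing stage raises
    :class:`PipelineError` naming the stage, with earlier results preserved
    on the exception.
    """
    manifest = RunManifest.create(
        "run-pipeline", config, {"population": population, "choices": choices}, seed
    )
    partial: dict = {"manifest": manifest}
    stage = "screen"
    try:
        report = validate_dataset(choices, config)
        if any(v["kind"] in ("missing_column", "non_binary_choice")
               for v in report.violations):
            raise ValueError(report.summary())
        retained, screening = apply_exclusions(population)
        partial["screening"] = screening
        kept = set(retained["respondent_id"])
        clean = choices[choices["respondent_id"].isin(kept)].reset_index(drop=True)

        stage = "fit-mnl"
        mnl = fit_binary_logit(clean, config)
        partial["mnl"] = mnl

        stage = "fit-lc"
        lc = fit_latent_class(
            clean, config, n_classes=n_classes, n_starts=n_starts, seed=seed
        )
        partial["latent_class"] = lc

        stage = "importance"
        importance = relative_importance(mnl, config)
        partial["importance"] = importance

        stage = "uptake"
        uptake = uptake_grid(lc, config, uptake_collector, uptake_new_user)
        partial["uptake"] = uptake
    except Exception as exc:
        raise PipelineError(stage, exc, partial) from exc
    return PipelineResult(
        screening=screening,
        mnl=mnl,
        latent_class=lc,
        importance=importance,
        uptake=uptake,
        manifest=manifest,
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fmt_level_rows(table: pd.DataFrame) -> list[str]:
    lines = []
    current_attr = None
    for _, row in table.iterrows():
        if row["attribute"] != current_attr and row["attribute"] != "intercept":
            current_attr = row["attribute"]
            lines.append(f"| **{current_attr}** | | | |")
        label = row["level"] if row["attribute"] != "intercept" else "Intercept"
        if row.get("reference", False):
            lines.append(f"| {label} (Ref) | {row['estimate']:.2f} (N/A) | N/A | N/A |")
        else:
            est = f"{row['estimate']:.2f}{_stars(row['p_value'])} ({row['se']:.2f})"
            ci = f"{row['ci_low']:.2f} to {row['ci_high']:.2f}"
            pv = "<.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}"
            lines.append(f"| {label} | {est} | {pv} | {ci} |")
    return lines


def render_mnl_table(est: MnlEstimate) -> str:
    lines = [
        "| Attribute and level | Estimate (SE) | P value | 95% CI |",
        "|---|---|---|---|",
    ]
    lines += _fmt_level_rows(est.level_table())
    lines.append(f"| Log-likelihood | {est.log_likelihood:.0f} | | |")
    lines.append(f"| AIC | {est.aic:.0f} | | |")
    return "\n".join(lines)


def render_lc_table(lc: LatentClassEstimate) -> str:
    header = "| Attribute and level | " + " | ".join(
        f"Class {c + 1}" for c in range(lc.n_classes)
    ) + " |"
    lines = [header, "|" + "---|" * (lc.n_classes + 1)]
    for attr in lc.config.attributes:
        lines.append(f"| **{attr.name}** |" + " |" * lc.n_classes)
        for lvl in attr.levels:
            cells = []
            for c in range(lc.n_classes):
                val = lc.class_coefficient(c, attr.name, lvl)
                if lvl == attr.reference_level:
                    cells.append(f"{val:.2f} (N/A)")
                elif lc.class_se is not None:
                    cols = lc.config.column_names()
                    se = lc.class_se[c, cols.index(f"{attr.name}[{lvl}]")]
                    cells.append(f"{val:.2f} ({se:.2f})")
                else:
                    cells.append(f"{val:.2f}")
            ref = " (Ref)" if lvl == attr.reference_level else ""
            lines.append(f"| {lvl}{ref} | " + " | ".join(cells) + " |")
    lines.append(
        "| Intercept | " + " | ".join(f"{a:.2f}" for a in lc.class_asc) + " |"
    )
    lines.append(
        "| Average class probability (%) | "
        + " | ".join(f"{100 * p:.0f}" for p in lc.average_class_probability)
        + " |"
    )
    lines.append(f"| AIC | {lc.aic:,.0f} |" + " |" * (lc.n_classes - 1))
    lines.append(f"| Log-likelihood | {lc.log_likelihood:,.0f} |" + " |" * (lc.n_classes - 1))
    if lc.n_classes > 1:
        lines.append("| **Class membership** |" + " |" * lc.n_classes)
        labels = ["constant", *lc.membership_countries]
        for j, lab in enumerate(labels):
            cells = [f"{lc.membership_coefs[c, j]:.2f}" for c in range(lc.n_classes - 1)]
            cells.append("Ref")
            lines.append(f"| {lab} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_uptake_table(grid: pd.DataFrame) -> str:
    info_cols = [c for c in grid.columns if c not in ("review", "reason")]
    lines = [
        "| Scenario | " + " | ".join(f"{c} (%)" for c in info_cols) + " |",
        "|" + "---|" * (len(info_cols) + 1),
    ]
    for review in grid["review"].unique():
        lines.append(f"| **{review}** |" + " |" * len(info_cols))
        sub = grid[grid["review"] == review]
        for _, row in sub.iterrows():
            cells = " | ".join(f"{row[c]:.0f}" for c in info_cols)
            lines.append(f"| {row['reason']} | {cells} |")
    return "\n".join(lines)


def render_tables(result: PipelineResult) -> str:
    """Full markdown report: screening, pooled logit, latent class, uptake."""
    s = result.screening
    parts = [
        "# Choice-model report",
        "",
        f"Screening: {s.n_received} received, {s.n_excluded_speed} speeders and "
        f"{s.n_excluded_incomplete} incompletes excluded, {s.n_retained} retained "
        f"({s.retention_percent:.2f}%).",
        "",
        "## Pooled binary logit",
        "",
        render_mnl_table(result.mnl),
        "",
        "## Latent class model",
        "",
        render_lc_table(result.latent_class),
        "",
        "## Relative attribute importance (pooled model)",
        "",
        result.importance.to_markdown(index=False, floatfmt=".3f"),
        "",
        "## Class-adjusted acceptance uptake",
        "",
        render_uptake_table(result.uptake),
        "",
        f"Manifest: {json.dumps(result.manifest.to_dict())}",
    ]
    return "\n".join(parts)
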