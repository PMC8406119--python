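"""Core domain types for binary accept/reject discrete choice experiments.

A study is described by a :class:`StudyConfig`: an ordered list of
categorical attributes, each with ordered levels and a designated reference
level. Choice tasks present one hypothetical profile (one level per
attribute) which the respondent accepts or rejects.

All estimation uses *effect coding*: each attribute with L levels
contributes L-1 columns; a non-reference level sets its own column to 1,
the reference level sets all of the attribute's columns to -1. Coded level
effects therefore sum to zero within an attribute, and the reference-level
effect is recovered as minus the sum of the estimated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AttributeSpec",
    "PriorSpec",
    "StudyConfig",
    "ConfigurationError",
    "effect_code",
    "effect_code_frame",
    "decode_vector",
    "reference_level_estimate",
    "validate_dataset",
]


class ConfigurationError(ValueError):
    """A profile, level or dataset is inconsistent with the study config."""


@dataclass(frozen=True)
class AttributeSpec:
    """One categorical attribute of the choice situation.

    Parameters
    ----------
    name : str
        Attribute identifier (e.g. ``"information"``).
    levels : tuple of str
        Ordered level identifiers, at least two, unique.
    reference_level : str
        The level coded -1 on all of the attribute's columns. Must be a
        member of ``levels``.
    """

    name: str
    levels: tuple[str, ...]
    reference_level: str

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ConfigurationError(
                f"attribute {self.name!r} needs >= 2 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError(f"attribute {self.name!r} has duplicate levels")
        if self.reference_level not in self.levels:
            raise ConfigurationError(
                f"reference level {self.reference_level!r} not among levels of "
                f"attribute {self.name!r}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors on the K effect-coded coefficients.

    ``sd == 0`` for every coefficient degenerates to a fixed (point) prior.
    """

    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.sd):
            raise ConfigurationError("prior mean and sd must have equal length")
        if any(s < 0 for s in self.sd):
            raise ConfigurationError("prior sds must be non-negative")

    @classmethod
    def fixed(cls, mean: Sequence[float]) -> "PriorSpec":
        return cls(tuple(float(m) for m in mean), (0.0,) * len(mean))

    @property
    def k(self) -> int:
        return len(self.mean)

    @property
    def is_fixed(self) -> bool:
        return all(s == 0 for s in self.sd)


@dataclass(frozen=True)
class StudyConfig:
    """Single source of truth for attributes, coding order and design size."""

    attributes: tuple[AttributeSpec, ...]
    info_types: tuple[str, ...] = ("genetic", "lifestyle")
    n_blocks: int = 4
    tasks_per_block: int = 8
    priors: PriorSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigurationError("attribute names must be unique")
        if self.n_blocks < 1 or self.tasks_per_block < 1:
            raise ConfigurationError("n_blocks and tasks_per_block must be positive")
        if self.priors is not None and self.priors.k != self.k:
            raise ConfigurationError(
                f"priors have length {self.priors.k}, expected K={self.k}"
            )

    @property
    def k(self) -> int:
        """Number of effect-coded parameters: sum over attributes of L-1."""
        return sum(a.n_levels - 1 for a in self.attributes)

    @property
    def n_tasks(self) -> int:
        return self.n_blocks * self.tasks_per_block

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise ConfigurationError(f"unknown attribute {name!r}")

    def column_names(self) -> list[str]:
        """Canonical coded-column labels, ``attr[level]``, in coding order."""
        return [
            f"{a.name}[{lvl}]" for a in self.attributes for lvl in a.nonreference_levels
        ]

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "attributes": [
                {
                    "name": a.name,
                    "levels": list(a.levels),
                    "reference_level": a.reference_level,
                }
                for a in self.attributes
            ],
            "info_types": list(self.info_types),
            "n_blocks": self.n_blocks,
            "tasks_per_block": self.tasks_per_block,
            "seed": self.seed,
        }
        if self.priors is not None:
            d["priors"] = {"mean": list(self.priors.mean), "sd": list(self.priors.sd)}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        priors = None
        if d.get("priors") is not None:
            priors = PriorSpec(
                tuple(float(x) for x in d["priors"]["mean"]),
                tuple(float(x) for x in d["priors"]["sd"]),
            )
        return cls(
            attributes=tuple(
                AttributeSpec(a["name"], tuple(a["levels"]), a["reference_level"])
                for a in d["attributes"]
            ),
            info_types=tuple(d.get("info_types", ("genetic", "lifestyle"))),
            n_blocks=int(d.get("n_blocks", 4)),
            tasks_per_block=int(d.get("tasks_per_block", 8)),
            priors=priors,
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# Effect coding
# --------------------------------------------------------------------------


def effect_code(profile: Mapping[str, str], config: StudyConfig) -> np.ndarray:
    """Effect-code one profile into the canonical K-vector.

    Non-reference level -> indicator 1 in its own column; reference level
    -> -1 in all of the attribute's columns. Column order follows the
    config's attribute order and, within an attribute, the listed order of
    non-reference levels.
    """
    out = np.zeros(config.k)
    pos = 0
    for attr in config.attributes:
        try:
            level = profile[attr.name]
        except KeyError:
            raise ConfigurationError(f"profile missing attribute {attr.name!r}")
        nonref = attr.nonreference_levels
        width = len(nonref)
        if level == attr.reference_level:
            out[pos : pos + width] = -1.0
        else:
            try:
                out[pos + nonref.index(level)] = 1.0
            except ValueError:
                raise ConfigurationError(
                    f"unknown level {level!r} for attribute {attr.name!r}"
                )
        pos += width
    return out


def effect_code_frame(frame: pd.DataFrame, config: StudyConfig) -> np.ndarray:
    """Vectorized effect coding of a DataFrame with one column per attribute.

    Returns an (n_rows, K) float array in canonical column order. Unknown
    level tokens raise :class:`ConfigurationError`.
    """
    n = len(frame)
    out = np.zeros((n, config.k))
    pos = 0
    for attr in config.attributes:
        if attr.name not in frame.columns:
            raise ConfigurationError(f"dataset missing attribute column {attr.name!r}")
        col = frame[attr.name].to_numpy()
        nonref = attr.nonreference_levels
        width = len(nonref)
        known = np.isin(col, attr.levels)
        if not known.all():
            bad = sorted(set(col[~known]))
            raise ConfigurationError(
                f"unknown level(s) {bad} for attribute {attr.name!r}"
            )
        is_ref = col == attr.reference_level
        out[is_ref, pos : pos + width] = -1.0
        for j, lvl in enumerate(nonref):
            out[col == lvl, pos + j] = 1.0
        pos += width
    return out


def decode_vector(coded: np.ndarray, config: StudyConfig) -> dict[str, str]:
    """Invert :func:`effect_code`; exact round trip for any valid profile."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape != (config.k,):
        raise ConfigurationError(f"expected vector of length K={config.k}")
    profile: dict[str, str] = {}
    pos = 0
    for attr in config.attributes:
        nonref = attr.nonreference_levels
        width = len(nonref)
        chunk = coded[pos : pos + width]
        if np.all(chunk == -1.0):
            profile[attr.name] = attr.reference_level
        else:
            ones = np.flatnonzero(chunk == 1.0)
            if len(ones) != 1 or not np.all(np.delete(chunk, ones) == 0.0):
                raise ConfigurationError(
                    f"invalid coded block for attribute {attr.name!r}: {chunk}"
                )
            profile[attr.name] = nonref[ones[0]]
        pos += width
    return profile


def reference_level_estimate(nonref_estimates: Iterable[float]) -> float:
    """Derived reference-level effect: minus the sum of the estimated ones.

    Effect coding constrains an attribute's level effects to sum to zero,
    so the reference level's effect is not a free parameter.
    """
    vals = [float(v) for v in nonref_estimates]
    if not vals:
        raise ValueError("need at least one non-reference estimate")
    return -sum(vals)


# --------------------------------------------------------------------------
# Dataset validation
# --------------------------------------------------------------------------

REQUIRED_CHOICE_COLUMNS = ("respondent_id", "info_type", "block", "task_id", "choice")


@dataclass
class ValidationReport:
    """Report-only description of problems in a long-format choice table."""

    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, **detail) -> None:
        self.violations.append({"kind": kind, **detail})

    def summary(self) -> str:
        if self.ok:
            return "dataset valid: no violations"
        lines = [f"{len(self.violations)} violation(s):"]
        for v in self.violations[:50]:
            lines.append("  - " + ", ".join(f"{k}={v[k]}" for k in v))
        return "\n".join(lines)


def validate_dataset(
    dataset: pd.DataFrame,
    config: StudyConfig,
    design: "pd.DataFrame | None" = None,
) -> ValidationReport:
    """Check a long-format choice table against the study configuration.

    Flags missing columns, unknown level tokens, non-binary choices,
    duplicate respondent/info-type/task rows, and (when a design table
    with ``task_id``/``block`` columns is given) respondents answering
    tasks outside their assigned block. Never mutates the dataset.
    """
    report = ValidationReport()
    for col in REQUIRED_CHOICE_COLUMNS:
        if col not in dataset.columns:
            report.add("missing_column", column=col)
    for attr in config.attributes:
        if attr.name not in dataset.columns:
            report.add("missing_column", column=attr.name)
            continue
        bad = ~dataset[attr.name].isin(attr.levels)
        for idx in dataset.index[bad]:
            report.add(
                "unknown_level",
                row=int(idx),
                attribute=attr.name,
                level=dataset.at[idx, attr.name],
            )
    if "choice" in dataset.columns:
        nonbin = ~dataset["choice"].isin([0, 1])
        for idx in dataset.index[nonbin]:
            report.add("non_binary_choice", row=int(idx), value=dataset.at[idx, "choice"])
    key_cols = ["respondent_id", "info_type", "task_id"]
    if all(c in dataset.columns for c in key_cols):
        dup = dataset.duplicated(subset=key_cols, keep=False)
        for idx in dataset.index[dup]:
            report.add(
                "duplicate_task_row",
                row=int(idx),
                respondent_id=dataset.at[idx, "respondent_id"],
                task_id=int(dataset.at[idx, "task_id"]),
            )
    if design is not None and {"task_id", "block"}.issubset(design.columns) and {
        "task_id",
        "block",
    }.issubset(dataset.columns):
        task_block = dict(zip(design["task_id"], design["block"]))
        for idx in dataset.index:
            tid = dataset.at[idx, "task_id"]
            if tid not in task_block:
                report.add("unknown_task", row=int(idx), task_id=int(tid))
            elif task_block[tid] != dataset.at[idx, "block"]:
                report.add(
                    "task_outside_block",
                    row=int(idx),
                    task_id=int(tid),
                    assigned_block=int(dataset.at[idx, "block"]),
                    design_block=int(task_block[tid]),
                )
    return report
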