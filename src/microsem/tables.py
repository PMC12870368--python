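"""Validated in-memory tables and their on-disk formats.

The interchange format is TSV (UTF-8, "." decimal): feature tables are
samples x features with the sample identifier in the first column, metadata
is samples x attributes.  A minimal dense BIOM-style JSON layout is accepted
read-only for abundance tables.  Results serialize to TSV/JSON and causal
graphs additionally to DOT.

Orientation is fixed package-wide: samples are rows, features are columns.
Missing values are not permitted anywhere; no stage imputes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import FLOAT_FMT
from .errors import FormatError, ValidationError

VALID_SCALES = ("counts", "relative", "clr", "log", "concentration")
VALID_KINDS = ("taxon", "metabolite", "mixed")
VALID_ARMS = ("HS-Comp", "HS-CON", "Ref")

_REL_TOL = 1e-8
_CLR_TOL = 1e-8


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class FeatureTable:
    """Samples x features numeric matrix with a declared measurement scale.

    ``data`` carries sample ids on the index and feature ids on the columns.
    The scale declaration is validated on construction: counts must be
    non-negative integers, relative rows must sum to 1 and clr rows to 0.
    ``concentration`` (raw non-negative measurements, e.g. mM SCFA levels)
    carries no row constraint.
    """

    data: pd.DataFrame
    scale: str
    feature_kind: str = "mixed"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.feature_kind not in VALID_KINDS:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("missing values are not permitted in feature tables")
        if self.scale == "counts":
            if (values < 0).any():
                raise ValidationError("counts must be non-negative")
            if not np.allclose(values, np.round(values), atol=1e-9):
                raise ValidationError("counts must be integral")
        elif self.scale == "relative":
            if (values < 0).any():
                raise ValidationError("relative abundances must be non-negative")
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=_REL_TOL):
                bad = self.data.index[np.abs(sums - 1.0) > _REL_TOL].tolist()
                raise ValidationError(f"relative rows must sum to 1 (violations: {bad[:5]})")
        elif self.scale == "concentration":
            if (values < 0).any():
                raise ValidationError("concentrations must be non-negative")
        elif self.scale == "clr":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 0.0, atol=max(_CLR_TOL, _CLR_TOL * values.shape[1])):
                bad = self.data.index[np.abs(sums) > _CLR_TOL * max(1, values.shape[1])].tolist()
                raise ValidationError(f"clr rows must sum to 0 (violations: {bad[:5]})")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def write(self, path) -> None:
        write_table(self.data, path)


@dataclass
class SampleMetadata:
    """Per-sample design information: farm/house, arm, phase, age."""

    data: pd.DataFrame
    arm_levels: tuple = VALID_ARMS

    REQUIRED = ("farm", "arm", "phase")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        _check_unique(self.data.index, "sample")
        bad = set(self.data["arm"]) - set(self.arm_levels)
        if bad:
            raise ValidationError(f"unknown arm levels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def require_samples(self, sample_ids: Iterable) -> None:
        """Referential check used by consuming stages before any join."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing[:5]}")

    def write(self, path) -> None:
        write_table(self.data, path)


def read_feature_table(path, scale: str, feature_kind: str = "mixed") -> FeatureTable:
    """Read a samples x features table, validating the declared scale.

    TSV with a header of feature ids and sample ids in the first column; a
    dense BIOM-style JSON object (keys ``rows``/``columns``/``data``) is also
    accepted.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = _read_biom_json(path)
    else:
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed text
            raise FormatError(f"could not parse {path}: {exc}") from exc
    return FeatureTable(frame, scale=scale, feature_kind=feature_kind)


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        rows = [r["id"] for r in obj["rows"]]
        cols = [c["id"] for c in obj["columns"]]
        data = np.asarray(obj["data"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path} is not dense BIOM-style JSON: {exc}") from exc
    if data.shape != (len(rows), len(cols)):
        raise FormatError("BIOM data shape does not match row/column lists")
    # BIOM convention is observations x samples; transpose to samples x features
    return pd.DataFrame(data.T, index=cols, columns=rows)


def read_metadata(path) -> SampleMetadata:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    return SampleMetadata(frame)


def write_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles, thresholds, seeds, model space.

    Stored as a YAML mapping with one section per stage.  ``defaults()``
    returns the study conditions the synthetic generator emulates.
    """

    sections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sec, mapping in self.sections.items():
            if not isinstance(mapping, Mapping):
                raise ValidationError(f"config section {sec!r} must be a mapping")
        for key in ("alpha", "fdr_cut", "min_support", "min_confidence"):
            for sec in self.sections.values():
                if key in sec and not (0.0 <= float(sec[key]) <= 1.0):
                    raise ValidationError(f"{key} must lie in [0, 1]")
        for key in ("n_perm", "n_boot", "n_sims", "samples_per_farm", "depth_mean"):
            for sec in self.sections.values():
                if key in sec and int(sec[key]) <= 0:
                    raise ValidationError(f"{key} must be a positive integer")

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        if not isinstance(obj, Mapping):
            raise FormatError("config root must be a mapping of sections")
        return cls(dict(obj))

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.sections, fh, sort_keys=True)

    @classmethod
    def defaults(cls) -> "RunConfig":
        return cls(
            {
                "simulate": {
                    "n_taxa": 60,
                    "n_metabolites": 8,
                    "farms_comp": 5,
                    "farms_con": 2,
                    "farms_ref": 3,
                    "samples_per_farm": 12,
                    "depth_mean": 20000,
                    "dirichlet_concentration": 200.0,
                    "farm_sd": 0.3,
                    "taxon_embedding_gain": 2.0,
                    "lacto_effect": 2.0,
                    "escherichia_effect": -2.0,
                    "noise_family": "uniform",
                    "ref_effect_fraction": 0.25,
                },
                "preprocess": {"pseudocount": 0.5, "log_offset": 0.5},
                "did": {"alpha": 0.05, "fdr_cut": 0.1, "n_perm": 10000},
                "select": {
                    "min_support": 0.2,
                    "min_confidence": 0.6,
                    "max_candidates": 20,
                    "top_k": 8,
                    "n_trees": 1000,
                    "n_rounds": 100,
                    "max_depth": 3,
                    "learning_rate": 0.3,
                },
                "efa": {"max_nfactors": 5, "vss_complexity": 1, "kappa": 4},
                "sem": {"n_boot": 1000, "alpha": 0.05},
                "causal": {"n_sims": 1000},
                "seed": {"global": 42},
            }
        )


# ---------------------------------------------------------------------------
# Result serialization


def write_results(result, path, fmt: str) -> None:
    """Serialize a result object deterministically.

    ``fmt`` is one of ``tsv``, ``json``, ``dot``.  Objects participate by
    exposing ``to_frame()`` (TSV), ``to_dict()`` (JSON) or ``to_dot()`` (DOT).
    """
    fmt = fmt.lower()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        if not hasattr(result, "to_frame"):
            raise ValidationError(f"{type(result).__name__} has no TSV form")
        write_table(result.to_frame(), path)
    elif fmt == "json":
        if not hasattr(result, "to_dict"):
            raise ValidationError(f"{type(result).__name__} has no JSON form")
        with open(path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    elif fmt == "dot":
        if not hasattr(result, "to_dot"):
            raise ValidationError(f"{type(result).__name__} has no DOT form")
        path.write_text(result.to_dot())
    else:
        raise ValidationError(f"unknown output format {fmt!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dag_to_dot(variables: Sequence[str], adjacency: np.ndarray, label: str | None = None) -> str:
    """Render a weighted adjacency matrix (B[i, j] = effect of j on i) as DOT."""
    lines = ["digraph G {"]
    if label:
        lines.append(f'  label="{label}";')
    for v in variables:
        lines.append(f'  "{v}";')
    adjacency = np.asarray(adjacency)
    for i, child in enumerate(variables):
        for j, parent in enumerate(variables):
            w = adjacency[i, j]
            if w != 0:
                lines.append(f'  "{parent}" -> "{child}" [label="{w:.3g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
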