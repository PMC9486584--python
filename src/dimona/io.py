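"""Reading, validation and filtering of per-layer omics tables.

An omics layer is a features x samples abundance matrix tagged with a layer
name (e.g. ``mrna``, ``protein``) and a condition label (one of the two
compared sample groups). Auxiliary tables map drugs to their molecular
targets and record per-cell-line drug sensitivities used as ground truth.

Filtering conventions
---------------------
Features are dropped when *more than* a given fraction of their measurements
is zero (``filter_zero_fraction``) or missing (``filter_missing_fraction``);
"more than" is implemented as a strict inequality, so boundary features are
kept. Zeros and missing values are distinct concepts filtered by separate
operations. Filtering is applied per condition: each condition's matrix is
filtered independently over its own samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "DrugTargetMap",
    "SensitivityTable",
    "read_omics_table",
    "read_drug_targets",
    "read_sensitivities",
    "filter_zero_fraction",
    "filter_missing_fraction",
    "restrict_features",
]

#: Tokens recognised as missing entries when reading tables.
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class OmicsMatrix:
    """One omics layer's abundance matrix for one condition.

    ``data`` is a features x samples DataFrame; the index holds feature
    identifiers and the columns sample identifiers. Missing entries are NaN.
    """

    layer_name: str
    condition: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def _replace(self, data: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(self.layer_name, self.condition, data)


@dataclass
class DrugTargetMap:
    """Mapping from drug id to its set of ``(layer_name, feature_id)`` targets."""

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, targets in self.entries.items():
            if not targets:
                raise ValueError(f"drug {drug!r} has an empty target set")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.entries)

    def targets_of(self, drug: str) -> set[tuple[str, str]]:
        return self.entries[drug]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, drug: str) -> bool:
        return drug in self.entries


@dataclass
class SensitivityTable:
    """Per-cell-line drug sensitivity measurements with condition labels.

    ``data`` has columns ``cell_line_id``, ``condition``, ``drug_id``,
    ``sensitivity``. A drug qualifies for ground-truth testing only when it
    has at least ``min_reps`` measurements in each condition (checked by the
    evaluation step, not at construction).
    """

    data: pd.DataFrame

    REQUIRED = ("cell_line_id", "condition", "drug_id", "sensitivity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sensitivity table lacks columns: {missing}")
        self.data = self.data.copy()
        self.data["sensitivity"] = self.data["sensitivity"].astype(float)

    def replicate_counts(self) -> pd.DataFrame:
        """Measurements per (drug, condition)."""
        return (
            self.data.groupby(["drug_id", "condition"], sort=True)
            .size()
            .rename("n")
            .reset_index()
        )

    def values_for(self, drug: str, condition: str) -> np.ndarray:
        sel = (self.data["drug_id"] == drug) & (self.data["condition"] == condition)
        return self.data.loc[sel, "sensitivity"].to_numpy()


def read_omics_table(
    path,
    layer_name: str,
    condition: str,
    sep: str = "\t",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
) -> OmicsMatrix:
    """Read a delimited abundance table into an :class:`OmicsMatrix`.

    The first column holds feature identifiers, the header row sample
    identifiers; every other cell must be numeric or one of
    ``missing_tokens`` (mapped to NaN).
    """
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
    )
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in abundance table ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(layer_name=layer_name, condition=condition, data=df)


def read_drug_targets(path, sep: str = "\t") -> DrugTargetMap:
    """Read a drug-target table with columns drug_id, target_id, target_layer."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"drug_id", "target_id", "target_layer"}
    if not required.issubset(df.columns):
        raise ValueError(f"drug target table needs columns {sorted(required)}")
    entries: dict[str, set[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        entries.setdefault(row.drug_id, set()).add((row.target_layer, row.target_id))
    return DrugTargetMap(entries)


def read_sensitivities(path, sep: str = "\t") -> SensitivityTable:
    """Read a sensitivity table with columns cell_line_id, condition, drug_id, sensitivity."""
    return SensitivityTable(pd.read_csv(path, sep=sep))


def filter_zero_fraction(m: OmicsMatrix, max_zero_frac: float = 0.9) -> OmicsMatrix:
    """Drop features with more than ``max_zero_frac`` zero measurements.

    The fraction is taken over all samples (missing entries count in the
    denominator but are not zeros). Strictly-greater-than: a feature exactly
    at the threshold is kept. Survivor order is preserved.
    """
    zero_frac = (m.data == 0).sum(axis=1) / m.n_samples
    return m._replace(m.data.loc[zero_frac <= max_zero_frac])


def filter_missing_fraction(m: OmicsMatrix, max_missing_frac: float = 0.2) -> OmicsMatrix:
    """Drop features with more than ``max_missing_frac`` missing entries."""
    miss_frac = m.data.isna().sum(axis=1) / m.n_samples
    return m._replace(m.data.loc[miss_frac <= max_missing_frac])


def restrict_features(m: OmicsMatrix, keep) -> OmicsMatrix:
    """Restrict to the intersection with ``keep``, preserving matrix order.

    Used e.g. to narrow genetic layers to a curated disease-relevant gene
    subset before network construction. An empty intersection is an error.
    """
    keep = set(keep)
    mask = [f in keep for f in m.feature_ids]
    if not any(mask):
        raise ValueError(
            f"restriction removes every feature of layer {m.layer_name!r}"
        )
    return m._replace(m.data.loc[mask])
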