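"""Samples × features container with metadata kept out of the model's reach.

Selection and modelling code must never consume site labels, outcomes or
other bookkeeping as predictors, so the columns of the underlying DataFrame
are partitioned explicitly: free radiomic features, a whitelist of fixed
clinical features that always enter the model, and metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: the five clinical covariates that are always part of the model
FIXED_CLINICAL = ["lesion_radius", "ecog", "age", "smoking", "first_line_ici"]

LABEL_COL = "pfs6"
SITE_COL = "site_id"


@dataclass
class FeatureMatrix:
    data: pd.DataFrame
    feature_columns: list[str]
    fixed_columns: list[str] = field(default_factory=lambda: list(FIXED_CLINICAL))
    metadata_columns: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.feature_columns) + list(self.fixed_columns) + list(
            self.metadata_columns
        )
        if len(set(cols)) != len(cols):
            raise ValueError("duplicated column names across blocks")
        missing = set(cols) - set(self.data.columns)
        if missing:
            raise ValueError(f"columns missing from data: {sorted(missing)}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicated columns in data: {list(dup)}")

    # ------------------------------------------------------------ access

    @property
    def selectable_columns(self) -> list[str]:
        """Columns a model may use: free features + fixed clinical."""
        return list(self.feature_columns) + list(self.fixed_columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data[LABEL_COL].to_numpy(dtype=int)

    @property
    def sites(self) -> np.ndarray:
        return self.data[SITE_COL].to_numpy()

    def values(self, columns: list[str] | None = None) -> np.ndarray:
        cols = self.selectable_columns if columns is None else columns
        return self.data[cols].to_numpy(dtype=float)

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return replace(self, data=self.data.loc[np.asarray(mask)].reset_index(drop=True))

    def subset_sites(self, sites: list[str] | tuple[str, ...]) -> "FeatureMatrix":
        return self.subset_rows(np.isin(self.sites, list(sites)))

    # --------------------------------------------------------------- I/O

    def to_csv(self, path, schema_path=None) -> None:
        import json
        from pathlib import Path

        self.data.to_csv(path, index=False)
        if schema_path is None:
            schema_path = Path(path).with_suffix(".schema.json")
        schema = {
            "feature_columns": list(self.feature_columns),
            "fixed_columns": list(self.fixed_columns),
            "metadata_columns": list(self.metadata_columns),
            "provenance": _jsonable(self.provenance),
        }
        Path(schema_path).write_text(json.dumps(schema, indent=2))

    @classmethod
    def from_csv(cls, path, schema_path=None) -> "FeatureMatrix":
        import json
        from pathlib import Path

        if schema_path is None:
            schema_path = Path(path).with_suffix(".schema.json")
        schema = json.loads(Path(schema_path).read_text())
        data = pd.read_csv(path)
        return cls(
            data=data,
            feature_columns=schema["feature_columns"],
            fixed_columns=schema["fixed_columns"],
            metadata_columns=schema["metadata_columns"],
            provenance=schema.get("provenance", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
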