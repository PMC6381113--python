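"""Core data containers and delimited-text I/O.

The universal exchange object between pipeline stages is the
:class:`LongitudinalDataset`: a tidy sample x feature abundance matrix plus
per-sample metadata (subject, location, altitude in km, batch label).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Metadata columns every dataset must carry.
REQUIRED_METADATA = ("sample", "subject", "location", "altitude_km", "batch")


class SchemaError(ValueError):
    """A table is missing a required column or is otherwise malformed."""


@dataclass
class LongitudinalDataset:
    """Sample x feature abundances with aligned per-sample metadata.

    Parameters
    ----------
    metadata
        One row per sample with at least the columns in
        :data:`REQUIRED_METADATA`.  ``sample`` values must be unique.
    values
        Abundance matrix indexed by sample id, one column per feature.
    truth
        Optional generative truth attached by the synthetic-data module
        (per-feature hyperparameters and per-subject slopes/intercepts),
        consumed by parameter-recovery tests.  Never serialized.
    """

    metadata: pd.DataFrame
    values: pd.DataFrame
    truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {missing}")
        if self.metadata["sample"].duplicated().any():
            raise SchemaError("duplicate sample ids in metadata")
        meta_samples = self.metadata["sample"].to_numpy()
        if not np.array_equal(self.values.index.to_numpy(), meta_samples):
            # realign rather than fail: the two tables travel separately on disk
            try:
                self.values = self.values.loc[meta_samples]
            except KeyError as exc:
                raise SchemaError("values index does not match metadata samples") from exc

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    def feature_arrays(self, feature: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, altitude_km, subject) arrays for one feature, NaNs dropped."""
        y = self.values[feature].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        return (
            y[keep],
            self.metadata["altitude_km"].to_numpy(dtype=float)[keep],
            self.metadata["subject"].to_numpy()[keep],
        )

    def subset_features(self, features: list[str]) -> "LongitudinalDataset":
        truth = None
        if self.truth is not None:
            truth = {k: v for k, v in self.truth.items() if k in set(features)}
        return LongitudinalDataset(self.metadata, self.values[list(features)], truth)


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table with tab/comma autodetection."""
    return pd.read_csv(path, sep=None, engine="python")


def write_dataset(data: LongitudinalDataset, values_path: str | Path,
                  metadata_path: str | Path) -> None:
    """Write abundances and metadata as TSV (stable float formatting)."""
    data.values.to_csv(values_path, sep="\t", index_label="sample", float_format="%.10g")
    data.metadata.to_csv(metadata_path, sep="\t", index=False, float_format="%.10g")


def read_dataset(values_path: str | Path, metadata_path: str | Path) -> LongitudinalDataset:
    """Read a dataset written by :func:`write_dataset` (tab or comma delimited)."""
    metadata = _read_table(metadata_path)
    missing = [c for c in REQUIRED_METADATA if c not in metadata.columns]
    if missing:
        raise SchemaError(f"{metadata_path}: missing required column(s): {missing}")
    values = _read_table(values_path)
    if "sample" not in values.columns:
        raise SchemaError(f"{values_path}: missing 'sample' index column")
    values = values.set_index("sample")
    return LongitudinalDataset(metadata, values)
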