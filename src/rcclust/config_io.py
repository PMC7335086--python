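"""Input/output for the recursive consensus clustering pipeline.

Three CSV inputs drive a run: an expression matrix (rows = genes/transcripts,
columns = samples/cells, values normalized and log2(x+1)-transformed
upstream), an optional sample-annotation table of categorical attributes, and
a two-column ``parameter,value`` configuration file.  The main tabular output
is ``ClusterInfo.csv`` holding per-level and final (concatenated) cluster
assignments for every sample.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "RCCConfig",
    "read_expression_csv",
    "read_annotation_csv",
    "read_config_csv",
    "write_cluster_info",
    "read_cluster_info",
]


class InputError(ValueError):
    """Raised for any malformed or inconsistent input file."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.  Identifiers are unique and order is preserved.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise InputError("id lengths do not match matrix shape")
        if n_genes < 2 or n_samples < 2:
            raise InputError("need at least 2 genes and 2 samples")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise InputError(f"duplicate {name} ids: {sorted(set(dup))}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InputError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        gene_ids: Optional[np.ndarray] = None,
        sample_ids: Optional[np.ndarray] = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given ids (order as given)."""
        values = self.values
        genes = self.gene_ids
        samples = self.sample_ids
        if gene_ids is not None:
            idx = pd.Index(genes).get_indexer(gene_ids)
            if (idx < 0).any():
                missing = np.asarray(gene_ids)[idx < 0]
                raise InputError(f"unknown gene ids: {list(missing[:5])}")
            values = values[idx, :]
            genes = np.asarray(gene_ids, dtype=object)
        if sample_ids is not None:
            idx = pd.Index(samples).get_indexer(sample_ids)
            if (idx < 0).any():
                missing = np.asarray(sample_ids)[idx < 0]
                raise InputError(f"unknown sample ids: {list(missing[:5])}")
            values = values[:, idx]
            samples = np.asarray(sample_ids, dtype=object)
        return ExpressionMatrix(values.copy(), genes, samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Categorical attributes per sample (columns = attributes)."""

    table: pd.DataFrame  # index = sample ids, string-valued columns

    def __post_init__(self) -> None:
        self.table = self.table.astype(str)
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()]
            raise InputError(f"duplicate sample ids in annotation: {sorted(set(dup))}")

    def aligned_to(self, sample_ids: np.ndarray) -> pd.DataFrame:
        """Annotation reindexed to the matrix columns; missing samples get 'NA'."""
        extra = self.table.index.difference(pd.Index(sample_ids))
        if len(extra):
            raise InputError(
                f"annotated samples absent from expression matrix: {sorted(extra)[:5]}"
            )
        return self.table.reindex(pd.Index(sample_ids)).fillna("NA")


#: config keys accepted in the configuration CSV -> RCCConfig field
_CONFIG_KEYS = {
    "expression_matrix": "expression_matrix",
    "annotation_file": "annotation_file",
    "gene_list": "gene_list",
    "data_type": "data_type",
    "min_slope_deg": "min_slope_deg",
    "min_samples": "min_samples",
    "min_line_length": "min_line_length",
    "variant_gene_pct": "variant_gene_pct",
    "min_de_pct": "min_de_pct",
    "output_dir": "output_dir",
    "seed": "seed",
    "repeats_per_process": "repeats_per_process",
    "n_processes": "n_processes",
    "weight_slope_deg": "weight_slope_deg",
    "weight_line_length": "weight_line_length",
    "intra_stability_min": "intra_stability_min",
    "inter_overlap_max": "inter_overlap_max",
    "marker_fdr": "marker_fdr",
    "marker_lfc": "marker_lfc",
    "bulk_min_features": "bulk_min_features",
    "cutoff_level": "cutoff_level",
}

_INT_FIELDS = {
    "min_samples",
    "min_line_length",
    "seed",
    "repeats_per_process",
    "n_processes",
    "bulk_min_features",
    "cutoff_level",
}
_FLOAT_FIELDS = {
    "min_slope_deg",
    "variant_gene_pct",
    "min_de_pct",
    "weight_slope_deg",
    "weight_line_length",
    "intra_stability_min",
    "inter_overlap_max",
    "marker_fdr",
    "marker_lfc",
}


@dataclass
class RCCConfig:
    """All tunable parameters of a run, with published defaults.

    ``variant_gene_pct`` defaults to 3 for bulk data and 1 for single-cell
    data when not given.  ``min_de_pct`` defaults to 20 for datasets with
    more than 1000 samples and 10 otherwise, resolved at run time.
    """

    data_type: str = "bulk"  # "bulk" | "single-cell"
    min_slope_deg: float = 10.0
    min_samples: int = 20
    min_line_length: float = 30.0
    variant_gene_pct: Optional[float] = None
    min_de_pct: Optional[float] = None
    expression_matrix: Optional[str] = None
    annotation_file: Optional[str] = None
    gene_list: Optional[str] = None
    output_dir: str = "."
    seed: Optional[int] = None
    repeats_per_process: int = 100
    n_processes: int = 8
    weight_slope_deg: float = 5.0
    weight_line_length: float = 40.0
    intra_stability_min: float = 0.8
    inter_overlap_max: float = 0.2
    marker_fdr: float = 0.01
    marker_lfc: float = 1.0
    bulk_min_features: int = 500
    cutoff_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.data_type not in ("bulk", "single-cell"):
            raise InputError(
                f"data_type must be 'bulk' or 'single-cell', got {self.data_type!r}"
            )
        for name in (
            "min_slope_deg",
            "min_line_length",
            "weight_slope_deg",
            "weight_line_length",
            "intra_stability_min",
            "inter_overlap_max",
            "marker_fdr",
            "marker_lfc",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be strictly positive")
        if self.min_samples < 4:
            raise InputError("min_samples must be >= 4")
        if self.variant_gene_pct is not None and not (0 < self.variant_gene_pct <= 100):
            raise InputError("variant_gene_pct must be in (0, 100]")
        if self.min_de_pct is not None and not (0 < self.min_de_pct <= 100):
            raise InputError("min_de_pct must be in (0, 100]")
        if self.repeats_per_process < 1 or self.n_processes < 1:
            raise InputError("repeats_per_process and n_processes must be >= 1")
        if self.bulk_min_features < 1:
            raise InputError("bulk_min_features must be >= 1")
        if self.cutoff_level is not None and self.cutoff_level < 1:
            raise InputError("cutoff_level must be >= 1")

    def resolved_pct(self) -> float:
        if self.variant_gene_pct is not None:
            return self.variant_gene_pct
        return 3.0 if self.data_type == "bulk" else 1.0

    def resolved_min_de_pct(self, n_samples: int) -> float:
        if self.min_de_pct is not None:
            return self.min_de_pct
        return 20.0 if n_samples > 1000 else 10.0

    def replace(self, **kwargs) -> "RCCConfig":
        return dataclasses.replace(self, **kwargs)


def read_expression_csv(path) -> ExpressionMatrix:
    """Load a genes x samples expression CSV (first column = gene ids)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression file not found: {path}")
    df = pd.read_csv(path, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise InputError(f"expression matrix is empty: {path}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise InputError(
                f"non-numeric value at gene {row!r}, sample {col!r} in {path}"
            )
        if numeric.isna().any():
            row = df.index[numeric.isna().to_numpy().argmax()]
            raise InputError(f"missing value at gene {row!r}, sample {col!r} in {path}")
        df[col] = numeric
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 50).any():
        warnings.warn(
            "expression values outside [0, 50]; input is expected to be "
            "normalized and log2(x+1)-transformed",
            stacklevel=2,
        )
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def read_annotation_csv(path) -> SampleAnnotation:
    """Load a sample-annotation CSV (first column = sample ids)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise InputError(f"annotation file has no attribute columns: {path}")
    return SampleAnnotation(df)


def read_config_csv(path) -> RCCConfig:
    """Parse a two-column ``parameter,value`` CSV into an :class:`RCCConfig`.

    Keys are case-insensitive and whitespace-trimmed; the value ``NA`` marks
    an optional parameter as absent; unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    df = pd.read_csv(
        path,
        header=None,
        dtype=str,
        comment="#",
        skip_blank_lines=True,
        keep_default_na=False,
    )
    if df.shape[1] < 2:
        raise InputError("config CSV must have two columns: parameter,value")
    # tolerate a literal "parameter,value" header row
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("parameter", "param", "name", "key"):
        df = df.iloc[1:]
    kwargs: dict = {}
    for _, row in df.iterrows():
        key = str(row.iloc[0]).strip().lower()
        raw = str(row.iloc[1]).strip()
        if key not in _CONFIG_KEYS:
            raise InputError(f"unknown config parameter: {key!r}")
        name = _CONFIG_KEYS[key]
        if raw.upper() in ("NA", "NONE", ""):
            kwargs[name] = None
            continue
        if name in _INT_FIELDS:
            try:
                kwargs[name] = int(raw)
            except ValueError:
                raise InputError(f"config parameter {key!r} must be an integer")
        elif name in _FLOAT_FIELDS:
            try:
                kwargs[name] = float(raw)
            except ValueError:
                raise InputError(f"config parameter {key!r} must be a number")
        else:
            kwargs[name] = raw
    if "data_type" not in kwargs or kwargs["data_type"] is None:
        raise InputError("config must set data_type (bulk or single-cell)")
    # None for a field with a non-None default means "use the default"
    defaults = RCCConfig(data_type=kwargs["data_type"])
    for name, value in list(kwargs.items()):
        if value is None and getattr(defaults, name) is not None:
            del kwargs[name]
    return RCCConfig(**kwargs)


def write_cluster_info(tree, path) -> pd.DataFrame:
    """Write per-level and final cluster assignments to ``ClusterInfo.csv``.

    One row per sample: the sample id, its cluster label at each level
    (blank once its branch has terminated) and the final concatenated
    (dotted) label.  Returns the written table.
    """
    frame = tree.assignments_frame()
    frame.index.name = "sample"
    frame.to_csv(path, index=True)
    return frame


def read_cluster_info(path) -> pd.DataFrame:
    """Re-load a ClusterInfo.csv written by :func:`write_cluster_info`."""
    df = pd.read_csv(path, index_col="sample", dtype=str)
    return df.fillna("")
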