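"""Synthetic group-structured expression matrices with known labels.

The generator emulates the kind of simulated single-cell-like matrices used
to benchmark cluster-number recovery: per-gene baseline log2 expression
drawn from Normal(5, 1), i.i.d. Normal(0, noise_sd) noise, and for each
group a dedicated block of marker genes shifted upward by ``effect_log2``
in that group's samples only.  Two canonical designs are provided: five
equal-sized subgroups ("mat1"-style) and five subgroups of varying
proportions ("mat2"-style).  Nested specs add a second tier whose
sub-group markers are disjoint from — and weaker than — the super-group
markers, so that only per-node feature re-selection can expose them.

Values are clipped at 0 (log2(x+1) expression is non-negative); an
optional dropout threshold zeroes values below it to mimic scRNA-seq
sparsity.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config_io import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "MAT1_SIZES",
    "MAT2_SIZES",
    "simulate_flat",
    "simulate_nested",
    "simulate_survival",
]

#: five equal subgroups / five subgroups of varying proportions
MAT1_SIZES = (50, 50, 50, 50, 50)
MAT2_SIZES = (100, 60, 40, 30, 20)

BASELINE_MEAN = 5.0
BASELINE_SD = 1.0


@dataclass
class SyntheticSpec:
    """Parameters of one tier of group structure.

    ``nesting`` optionally maps each group to a child spec whose
    ``group_sizes`` must sum to the parent group's size; child marker
    blocks are allocated from genes unused by any other block.
    """

    group_sizes: Sequence[int] = MAT1_SIZES
    n_genes: int = 2000
    markers_per_group: int = 40
    effect_log2: float = 3.0
    noise_sd: float = 1.0
    dropout_threshold: Optional[float] = None
    nesting: Optional[List[Optional["SyntheticSpec"]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("every group needs >= 2 samples")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.markers_per_group * len(self.group_sizes) > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.nesting is not None:
            if len(self.nesting) != len(self.group_sizes):
                raise ValueError("nesting must give one entry per group")
            for size, sub in zip(self.group_sizes, self.nesting):
                if sub is not None and sum(sub.group_sizes) != size:
                    raise ValueError("nested group sizes must sum to parent size")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))


def _ids(prefix: str, n: int) -> np.ndarray:
    width = len(str(n))
    return np.asarray([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _allocate_blocks(spec: SyntheticSpec) -> int:
    """Total marker genes needed across all tiers (disjoint blocks)."""
    total = spec.markers_per_group * len(spec.group_sizes)
    if spec.nesting:
        for sub in spec.nesting:
            if sub is not None:
                total += _allocate_blocks(sub)
    return total


def _apply_tier(
    values: np.ndarray,
    spec: SyntheticSpec,
    col_offset: int,
    next_gene: int,
    labels: List[List[str]],
    prefix: str,
    depth: int,
) -> int:
    """Add this tier's marker shifts in place; returns next free gene row."""
    start = col_offset
    for g, size in enumerate(spec.group_sizes, start=1):
        cols = slice(start, start + size)
        rows = slice(next_gene, next_gene + spec.markers_per_group)
        values[rows, cols] += spec.effect_log2
        label = f"{prefix}{g}" if not prefix else f"{prefix}.{g}"
        for lv in range(depth, len(labels)):
            for c in range(start, start + size):
                labels[lv][c] = label
        next_gene += spec.markers_per_group
        if spec.nesting and spec.nesting[g - 1] is not None:
            next_gene = _apply_tier(
                values, spec.nesting[g - 1], start, next_gene, labels, label, depth + 1
            )
        start += size
    return next_gene


def _generate(spec: SyntheticSpec, n_levels: int):
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    g = spec.n_genes
    if _allocate_blocks(spec) > g:
        raise ValueError("overlapping marker-block allocation: not enough genes")
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=(g, 1))
    values = baseline + rng.normal(0.0, spec.noise_sd, size=(g, n))
    labels = [["" for _ in range(n)] for _ in range(n_levels)]
    _apply_tier(values, spec, 0, 0, labels, "", 0)
    np.clip(values, 0.0, None, out=values)
    if spec.dropout_threshold is not None:
        values[values < spec.dropout_threshold] = 0.0
    X = ExpressionMatrix(values, _ids("gene", g), _ids("sample", n))
    return X, labels


def simulate_flat(spec: SyntheticSpec):
    """Flat design: returns ``(ExpressionMatrix, true_labels)``.

    ``true_labels`` is a pandas Series of group labels ("1".."k") indexed
    by sample id.
    """
    if spec.nesting is not None:
        raise ValueError("use simulate_nested for nested specs")
    X, labels = _generate(spec, n_levels=1)
    truth = pd.Series(labels[0], index=pd.Index(X.sample_ids), name="truth")
    return X, truth


def _depth(spec: SyntheticSpec) -> int:
    if not spec.nesting:
        return 1
    return 1 + max(_depth(s) for s in spec.nesting if s is not None)


def simulate_nested(spec: SyntheticSpec):
    """Nested design: returns ``(ExpressionMatrix, labels_frame)``.

    ``labels_frame`` has one column per tier (``level1``, ``level2``, ...)
    with dotted labels; the last column is the leaf-level ground truth.
    Samples of a group without a nested sub-spec keep their parent label at
    deeper levels.
    """
    if spec.nesting is None:
        raise ValueError("spec has no nesting; use simulate_flat")
    depth = _depth(spec)
    X, labels = _generate(spec, n_levels=depth)
    frame = pd.DataFrame(
        {f"level{i + 1}": labels[i] for i in range(depth)},
        index=pd.Index(X.sample_ids),
    )
    return X, frame


def simulate_survival(
    labels: pd.Series,
    hazard_ratios: Sequence[float],
    censor_rate: float = 0.0,
    seed: int = 0,
    base_hazard: float = 0.1,
) -> pd.DataFrame:
    """Exponential survival times per cluster with independent censoring.

    ``hazard_ratios`` gives one multiplier per cluster (sorted label
    order); events occur at rate ``base_hazard * ratio``.  ``censor_rate``
    is the expected fraction censored under equal hazards; 0 disables
    censoring.  Returns columns ``time`` and ``event`` indexed by sample.
    """
    labels = pd.Series(labels).astype(str)
    uniq = sorted(labels.unique())
    ratios = list(hazard_ratios)
    if len(ratios) != len(uniq):
        raise ValueError("need one hazard ratio per cluster")
    if any(r <= 0 for r in ratios):
        raise ValueError("hazard ratios must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rate = labels.map(dict(zip(uniq, ratios))).to_numpy(dtype=float) * base_hazard
    times = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_scale = (1.0 - censor_rate) / (censor_rate * base_hazard)
        ctimes = rng.exponential(censor_scale, size=len(times))
        event = (times <= ctimes).astype(int)
        times = np.minimum(times, ctimes)
    else:
        event = np.ones(len(times), dtype=int)
    return pd.DataFrame({"time": times, "event": event}, index=labels.index)
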