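"""Probe collapsing, per-study normalization and age-group assignment.

Each microarray study enters as a probe (or gene) x sample matrix. Probes are
collapsed to a shared gene namespace, every study is normalized with a
generalized-log transform (a closed-form variance-stabilizing transform that
plays the role of log2 + VSN) followed by quantile normalization, and samples
are assigned to the two age brackets of the compendium design: younger
(20-40 years) and older (60-90 years). A study is only retained when both
groups keep at least ``min_per_group`` samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YOUNG_BRACKET = (20.0, 40.0)
OLD_BRACKET = (60.0, 90.0)


@dataclass
class StudyExpression:
    """One study's gene x sample expression matrix plus sample metadata.

    ``matrix`` has gene IDs as the index and sample IDs as columns.
    ``sample_meta`` has one row per sample with columns ``sample``, ``group``
    (``young``/``old``) and ``age`` (years).
    """

    study_id: str
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self, min_per_group: int = 3) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID in study {self.study_id}: {dup}")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError(f"non-finite expression values in study {self.study_id}")
        if list(self.matrix.columns) != list(self.sample_meta["sample"]):
            raise ValueError(f"matrix columns and sample_meta disagree in {self.study_id}")
        counts = self.sample_meta["group"].value_counts()
        for grp in ("young", "old"):
            if counts.get(grp, 0) < min_per_group:
                raise ValueError(
                    f"study {self.study_id}: group '{grp}' has "
                    f"{counts.get(grp, 0)} < {min_per_group} samples"
                )

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta.set_index("sample")["group"]


@dataclass
class Compendium:
    """A set of harmonized studies and the shared gene universe."""

    studies: list[StudyExpression]
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_universe:
            self.gene_universe = sorted(
                set.intersection(*(set(s.matrix.index) for s in self.studies))
            )
        if not self.gene_universe:
            raise ValueError("empty gene universe across studies")


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: dict[str, str] | pd.Series,
    rule: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene level.

    Multiple probes mapping to the same gene are combined by ``rule``
    (mean by default, median by configuration). Probes absent from the map
    are dropped; the number dropped is logged.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("empty probe-to-gene map")
    mapped = probe_matrix.index.intersection(mapping.index)
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = probe_matrix.loc[mapped]
    grouped = sub.groupby(mapping.loc[mapped].to_numpy())
    collapsed = grouped.median() if rule == "median" else grouped.mean()
    collapsed.index.name = probe_matrix.index.name
    return collapsed


def glog2(x: np.ndarray | float, c: float) -> np.ndarray | float:
    """Generalized log2: ``log2((x + sqrt(x^2 + c^2)) / 2)``.

    Monotone, defined at 0 (maps to ``log2(c/2)``) and asymptotically equal
    to ``log2(x)`` for ``x >> c`` — the closed-form stand-in for the
    variance-stabilizing normalization step.
    """
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's values are replaced by the mean of the sorted columns at
    the same rank; ties within a column receive the average of the reference
    values at their tied ranks, which makes the transform idempotent and
    keeps constant columns finite.
    """
    arr = matrix.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order, dtype=float)
        ranks[order] = np.arange(len(col), dtype=float)
        # average reference values over tied ranks
        ser = pd.Series(ref[ranks.astype(int)], index=col)
        tie_means = ser.groupby(level=0).transform("mean").to_numpy()
        out[:, j] = tie_means
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_study(
    matrix: pd.DataFrame,
    steps: Sequence[str] = ("glog2", "quantile"),
    glog_quantile: float = 0.05,
) -> pd.DataFrame:
    """Apply the normalization chain to a raw study matrix.

    ``glog2`` is the combined log2 + variance-stabilization step: the offset
    ``c`` is set to the ``glog_quantile`` quantile of the positive values so
    small intensities are damped while large ones pass through as plain log2.
    ``quantile`` equalizes per-sample distributions. Raw values must be
    non-negative for the glog step.
    """
    out = matrix
    for step in steps:
        if step in ("glog2", "log2", "vsn"):
            vals = out.to_numpy(dtype=float)
            if (vals < 0).any():
                raise ValueError("negative raw values are not allowed under the log step")
            pos = vals[vals > 0]
            c = float(np.quantile(pos, glog_quantile)) if pos.size else 1.0
            out = pd.DataFrame(glog2(vals, c), index=out.index, columns=out.columns)
        elif step == "quantile":
            out = quantile_normalize(out)
        else:
            raise ValueError(f"unknown normalization step: {step!r}")
    return out


def assign_groups(
    sample_meta: pd.DataFrame,
    young: tuple[float, float] = YOUNG_BRACKET,
    old: tuple[float, float] = OLD_BRACKET,
    min_per_group: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Bracket samples into young/old groups and apply the inclusion rule.

    Returns ``(grouped_meta, excluded_meta, retained)``. Samples whose age
    falls outside both brackets are excluded (and logged); the study is
    flagged not-retained when either group ends up with fewer than
    ``min_per_group`` samples. Rejection is a reported condition, not an
    exception.
    """
    ages = sample_meta["age"].astype(float)
    is_young = ages.between(*young)
    is_old = ages.between(*old)
    grouped = sample_meta[is_young | is_old].copy()
    grouped["group"] = np.where(is_young[is_young | is_old], "young", "old")
    excluded = sample_meta[~(is_young | is_old)].copy()
    if len(excluded):
        logger.info("assign_groups: excluded %d samples outside brackets", len(excluded))
    counts = grouped["group"].value_counts()
    retained = all(counts.get(g, 0) >= min_per_group for g in ("young", "old"))
    if not retained:
        logger.warning(
            "assign_groups: study rejected (young=%d, old=%d, need >= %d each)",
            counts.get("young", 0), counts.get("old", 0), min_per_group,
        )
    return grouped, excluded, retained


def build_compendium(
    studies: Iterable[StudyExpression],
    universe_mode: Literal["intersection", "union"] = "intersection",
    min_studies: int = 2,
) -> Compendium:
    """Assemble a compendium with a shared gene universe.

    ``intersection`` keeps genes measured in every study (the default — the
    meta-analysis then has a p-value per study for every gene). ``union``
    keeps genes measured in at least ``min_studies`` studies; the
    meta-analysis handles the missing studies by reducing the degrees of
    freedom per gene.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("no studies supplied")
    gene_sets = [set(s.matrix.index) for s in studies]
    if universe_mode == "intersection":
        universe = set.intersection(*gene_sets)
    elif universe_mode == "union":
        counts: dict[str, int] = {}
        for gs in gene_sets:
            for g in gs:
                counts[g] = counts.get(g, 0) + 1
        universe = {g for g, k in counts.items() if k >= min_studies}
    else:
        raise ValueError(f"unknown universe_mode: {universe_mode!r}")
    if not universe:
        raise ValueError("empty gene universe across studies")
    return Compendium(studies=studies, gene_universe=sorted(universe))
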