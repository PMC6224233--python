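"""Follow-up statistics: qPCR relative quantification, age correlation,
two-group tests.

The 2^-ddCt method converts qPCR cycle thresholds into fold changes: per
sample, dCt = Ct(target) - Ct(reference); ddCt calibrates each sample's dCt
against the mean control dCt (the Livak convention); fold = 2^-ddCt.
Age-association follow-ups use Spearman rank correlation (exact permutation
p for small n), and group comparisons use Student's t.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def ddct(
    table: pd.DataFrame,
    control_label: str = "control",
    target_gene: str | None = None,
) -> dict:
    """2^-ddCt fold changes from a long-format Ct table.

    ``table`` needs columns ``sample, group, gene, role, Ct`` with exactly
    one reference row per sample and (for multi-target tables) a
    ``target_gene`` selection. Returns per-sample fold changes, group
    mean ± SE summaries, and a two-sided two-sample t-test on the dCt
    values (the scale on which the noise is additive).
    """
    targets = table[table["role"] == "target"]
    if target_gene is not None:
        targets = targets[targets["gene"] == target_gene]
    refs = table[table["role"] == "reference"].set_index("sample")["Ct"]
    missing = set(targets["sample"]) - set(refs.index)
    if missing:
        raise ValueError(f"missing reference Ct for samples: {sorted(missing)}")
    per = targets[["sample", "group", "Ct"]].copy()
    per["dCt"] = per["Ct"].to_numpy() - refs.loc[per["sample"]].to_numpy()
    control_dct = per.loc[per["group"] == control_label, "dCt"]
    if control_dct.empty:
        raise ValueError(f"no samples in control group {control_label!r}")
    per["ddCt"] = per["dCt"] - control_dct.mean()
    per["fold"] = np.exp2(-per["ddCt"])
    summary = per.groupby("group")["fold"].agg(
        mean_fold="mean", se_fold=lambda x: x.std(ddof=1) / math.sqrt(len(x)), n="size"
    )
    groups = [g for g in per["group"].unique() if g != control_label]
    t_stat, p = (np.nan, np.nan)
    if groups:
        treated_dct = per.loc[per["group"] == groups[0], "dCt"]
        t_stat, p = stats.ttest_ind(treated_dct, control_dct, equal_var=True)
    return {
        "per_sample": per.reset_index(drop=True),
        "summary": summary,
        "t": float(t_stat),
        "p": float(p),
    }


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 10)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    denom_x = rx - rx.mean()
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)] - ry.mean()
        r = float(np.dot(denom_x, ryp) / np.sqrt(np.dot(denom_x, denom_x) * np.dot(ryp, ryp)))
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_age(expression: Sequence[float], ages: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation of expression with age: ``(rho, p)``.

    Midranks handle ties; p comes from the t-approximation, replaced by an
    exhaustive permutation p for n <= 10. A constant input yields
    ``(nan, nan)``.
    """
    x = np.asarray(expression, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(x) != len(a) or len(x) < 4:
        raise ValueError("need aligned vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(a) == 0:
        warnings.warn("constant input: Spearman rho undefined", RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, a)
    if len(x) <= 10:
        p = _exact_spearman_p(x, a, rho)
    return float(rho), float(p)


def two_group_test(
    values: Sequence[float],
    groups: Sequence[str],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided Student's t-test between the two labeled groups.

    Equal-variance (classical Student) by default; Welch via
    ``equal_var=False``, and as an automatic fallback when a group has zero
    variance (with a warning).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    g1 = values[groups == labels[0]]
    g2 = values[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 values per group")
    if equal_var and (np.var(g1, ddof=1) == 0 or np.var(g2, ddof=1) == 0):
        warnings.warn("degenerate variances: falling back to Welch", RuntimeWarning,
                      stacklevel=2)
        equal_var = False
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)
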