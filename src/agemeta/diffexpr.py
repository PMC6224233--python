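"""Per-study differential expression: empirical-Bayes moderated t-test.

Gene-wise two-group comparisons in a single microarray study are unstable
because per-gene variances are estimated from few samples. The moderated
t-test shrinks each gene's sample variance toward a pooled prior estimated
from all genes: with residual degrees of freedom ``d`` and sample variance
``s^2``, the posterior variance is

    s_post^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t statistic ``effect / (s_post * sqrt(1/n1 + 1/n2))`` is
referred to a t distribution with ``d + d0`` degrees of freedom. The prior
``(d0, s0^2)`` is estimated by method of moments on ``log s^2`` (the scaled
F-distribution fit of empirical-Bayes linear models), with the inverse
trigamma solved by Newton iteration.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_D0_CAP = 1e6  # treated as infinite shrinkage


def trigamma_inverse(x: np.ndarray | float, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by Newton iteration.

    Uses the standard monotone iteration on ``1/y`` (trigamma is convex and
    decreasing); values of ``x`` that would imply ``y`` beyond the cap are
    clipped, which downstream is interpreted as infinite prior df.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x  # starting value: asymptotic inverse
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(-dif / y < tol):
            break
    return np.clip(y, 1e-8, _D0_CAP)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior ``(d0, s0^2)``.

    Fits a scaled F distribution to the sample variances ``s2`` (each with
    ``df`` residual degrees of freedom) via the mean and variance of
    ``log s2``. Returns ``d0 = inf`` (capped) when the observed spread of
    log-variances does not exceed its sampling expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return float(_D0_CAP), float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = float(2.0 * trigamma_inverse(e_var)[0])
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = float(_D0_CAP)
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t(
    matrix: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test for every gene (row) of ``matrix``.

    ``groups`` labels each column as ``young`` or ``old``; the reported
    effect is the old-minus-young mean difference in log2 units.
    ``d0_override`` forces the prior degrees of freedom (0 disables
    shrinkage entirely, recovering the ordinary two-sample t).

    Returns a per-gene DataFrame with columns ``effect, se, t_ord, t_mod,
    df, d0, s0_2, p, fdr, direction``.
    """
    groups = np.asarray(groups)
    old = matrix.loc[:, groups == "old"].to_numpy(dtype=float)
    young = matrix.loc[:, groups == "young"].to_numpy(dtype=float)
    n1, n2 = old.shape[1], young.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples in each group")
    df = float(n1 + n2 - 2)
    effect = old.mean(axis=1) - young.mean(axis=1)
    ss = old.var(axis=1, ddof=1) * (n1 - 1) + young.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0, s0_2 = fit_f_dist(s2, df)

    zero_var = s2 <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} gene(s) with zero variance in both groups; p set to 1",
            RuntimeWarning, stacklevel=2,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = effect / (np.sqrt(s2) * scale)
    if d0 >= _D0_CAP:
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 <= 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = effect / (np.sqrt(s2_post) * scale)

    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(zero_var, 1.0, p)
    t_ord = np.where(zero_var, 0.0, t_ord)
    t_mod = np.where(zero_var, 0.0, t_mod)

    se = np.sqrt(s2_post) * scale
    result = pd.DataFrame({
        "effect": effect,
        "se": se,
        "t_ord": t_ord,
        "t_mod": t_mod,
        "df": df,
        "d0": d0,
        "s0_2": s0_2,
        "p": p,
        "fdr": bh_fdr(p),
        "direction": np.where(effect >= 0, "up", "down"),
    }, index=matrix.index)
    result.index.name = "gene"
    return result


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(
    de: pd.DataFrame, alpha_p: float = 0.05, alpha_fdr: float = 0.05
) -> list[str]:
    """Genes passing both the raw-p and the FDR threshold (the default rule)."""
    mask = de["p"] < alpha_p
    if alpha_fdr is not None:
        mask &= de["fdr"] < alpha_fdr
    sig = de.index[mask].tolist()
    logger.info(
        "significant_genes: %d of %d at p<%g%s", len(sig), len(de), alpha_p,
        f" and FDR<{alpha_fdr:g}" if alpha_fdr is not None else "",
    )
    return sig


def study_overlap(gene_lists: dict[str, Iterable[str]]) -> tuple[set[str], dict[frozenset, int]]:
    """All-study intersection plus the full Venn cell counts.

    The second return value maps each non-empty study combination (frozenset
    of study IDs) to the number of genes significant in exactly those
    studies.
    """
    if len(gene_lists) < 2:
        raise ValueError("need >= 2 study lists")
    sets = {k: set(v) for k, v in gene_lists.items()}
    names = list(sets)
    intersection = set.intersection(*sets.values())
    cells: dict[frozenset, int] = {}
    all_genes = set.union(*sets.values())
    membership: dict[str, frozenset] = {}
    for g in all_genes:
        membership[g] = frozenset(k for k in names if g in sets[k])
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            cells[key] = sum(1 for m in membership.values() if m == key)
    return intersection, cells
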