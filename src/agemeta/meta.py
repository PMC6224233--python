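"""Three-method meta-analysis across studies and the consensus gene list.

Per-gene evidence from the individual studies is combined with:

* **Fisher's method** — ``X = -2 * sum(ln p)`` against a chi-square with
  ``2k`` degrees of freedom (k = number of studies contributing a p-value);
* **fixed-effect model** — inverse-variance pooling of the per-study
  log2 effects, with Cochran's Q as the heterogeneity check;
* **vote counting** — the number of studies calling the gene significant at
  a fixed per-study threshold.

A gene is in the *consensus* list when all three methods call it significant
(combined p < 0.001 for Fisher and the fixed-effect z, votes >= 2 by
default); its direction is the sign of the pooled fixed-effect estimate.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_P_FLOOR = np.nextafter(0.0, 1.0)


def fisher_combine(pvals: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Combine per-study p-values gene-wise with Fisher's method.

    ``pvals`` is genes x studies; NaN marks a gene missing from a study and
    reduces that gene's degrees of freedom (df = 2 * number of available
    studies). Zeros are clamped to the smallest positive float with a
    warning. For a single available study the combination is the identity.
    Returns columns ``fisher_X, fisher_df, fisher_p, n_studies``.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if np.nanmin(arr, initial=1.0) < 0 or np.nanmax(arr, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if (arr == 0).any():
        warnings.warn("p-value of 0 clamped to the smallest positive float",
                      RuntimeWarning, stacklevel=2)
        arr = np.where(arr == 0, _P_FLOOR, arr)
    avail = ~np.isnan(arr)
    k = avail.sum(axis=1)
    if (k == 0).any():
        raise ValueError("every gene needs >= 1 study p-value")
    with np.errstate(invalid="ignore"):
        x = -2.0 * np.nansum(np.log(arr), axis=1)
    df = 2 * k
    p = stats.chi2.sf(x, df)
    index = pvals.index if isinstance(pvals, pd.DataFrame) else None
    return pd.DataFrame(
        {"fisher_X": x, "fisher_df": df, "fisher_p": p, "n_studies": k}, index=index
    )


def fixed_effect_combine(
    effects: np.ndarray | pd.DataFrame, ses: np.ndarray | pd.DataFrame
) -> pd.DataFrame:
    """Inverse-variance fixed-effect pooling with Cochran's Q, gene-wise.

    ``effects`` and ``ses`` are genes x studies; NaN marks missing studies.
    Weights are ``1/SE^2``; the pooled SE is ``1/sqrt(sum w)``;
    ``Q = sum w (e - pooled)^2`` is referred to chi-square with k-1 df.
    For a single available study the pooled estimate is that study and Q is
    reported as NaN. Returns columns ``fe_effect, fe_se, fe_z, fe_p, Q,
    Q_df, Q_p``.
    """
    e = np.asarray(effects, dtype=float)
    s = np.asarray(ses, dtype=float)
    if e.ndim == 1:
        e, s = e[:, None], s[:, None]
    if np.nanmin(s, initial=np.inf) <= 0:
        raise ValueError("standard errors must be > 0")
    avail = ~(np.isnan(e) | np.isnan(s))
    k = avail.sum(axis=1)
    if (k == 0).any():
        raise ValueError("every gene needs >= 1 study effect")
    w = np.where(avail, 1.0 / (s * s), 0.0)
    wsum = w.sum(axis=1)
    pooled = np.where(avail, w * np.nan_to_num(e), 0.0).sum(axis=1) / wsum
    pooled_se = 1.0 / np.sqrt(wsum)
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    dev = np.where(avail, np.nan_to_num(e) - pooled[:, None], 0.0)
    q = (w * dev * dev).sum(axis=1)
    q_df = k - 1.0
    q_p = np.where(q_df >= 1, stats.chi2.sf(q, np.maximum(q_df, 1)), np.nan)
    q = np.where(q_df >= 1, q, np.nan)
    q_df = np.where(q_df >= 1, q_df, np.nan)
    index = effects.index if isinstance(effects, pd.DataFrame) else None
    return pd.DataFrame({
        "fe_effect": pooled, "fe_se": pooled_se, "fe_z": z, "fe_p": p,
        "Q": q, "Q_df": q_df, "Q_p": q_p,
    }, index=index)


def vote_count(
    pvals: np.ndarray | pd.DataFrame,
    directions: np.ndarray | pd.DataFrame | None = None,
    threshold: float = 0.05,
    direction_consistent: bool = False,
) -> np.ndarray:
    """Votes per gene: number of studies with p below ``threshold``.

    With ``direction_consistent=True`` only studies agreeing with the
    majority effect sign contribute votes. NaN p-values (missing studies)
    never vote.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    sig = np.where(np.isnan(p), False, p < threshold)
    if direction_consistent:
        if directions is None:
            raise ValueError("direction_consistent requires per-study directions")
        d = np.sign(np.asarray(directions, dtype=float))
        maj = np.sign(np.nansum(np.where(sig, d, 0.0), axis=1))
        maj = np.where(maj == 0, 1.0, maj)
        sig = sig & (d == maj[:, None])
    return sig.sum(axis=1).astype(int)


def meta_analyze(
    de_results: Mapping[str, pd.DataFrame],
    per_study_p: float = 0.05,
    min_studies: int = 2,
    direction_consistent_votes: bool = False,
) -> pd.DataFrame:
    """Run all three combination methods over per-study DE tables.

    ``de_results`` maps study ID to the per-gene table from
    :func:`agemeta.diffexpr.moderated_t`. Genes present in fewer than
    ``min_studies`` studies are dropped (logged).
    """
    studies = list(de_results)
    genes = sorted(set().union(*(set(t.index) for t in de_results.values())))
    pmat = pd.DataFrame(np.nan, index=genes, columns=studies)
    emat = pd.DataFrame(np.nan, index=genes, columns=studies)
    smat = pd.DataFrame(np.nan, index=genes, columns=studies)
    for sid, tab in de_results.items():
        pmat.loc[tab.index, sid] = tab["p"].to_numpy()
        emat.loc[tab.index, sid] = tab["effect"].to_numpy()
        smat.loc[tab.index, sid] = tab["se"].to_numpy()
    avail = (~pmat.isna()).sum(axis=1)
    keep = avail >= min_studies
    if (~keep).any():
        logger.info("meta_analyze: dropped %d genes present in < %d studies",
                    int((~keep).sum()), min_studies)
    pmat, emat, smat = pmat[keep], emat[keep], smat[keep]
    out = fisher_combine(pmat)
    out = out.join(fixed_effect_combine(emat, smat))
    out["votes"] = vote_count(
        pmat, directions=emat, threshold=per_study_p,
        direction_consistent=direction_consistent_votes,
    )
    out.index.name = "gene"
    return out


def consensus(
    meta_table: pd.DataFrame,
    p_combined_threshold: float = 0.001,
    vote_threshold: int = 2,
    discordance_z_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-method significance flags, the consensus AND, and directions.

    Flags: Fisher combined p < threshold; fixed-effect combined p <
    threshold; votes >= ``vote_threshold``. Consensus requires all three.
    Direction is the sign of the pooled fixed-effect estimate; genes whose
    pooled |z| falls below ``discordance_z_floor`` are labeled
    ``discordant``.
    """
    out = meta_table.copy()
    out["sig_fisher"] = out["fisher_p"] < p_combined_threshold
    out["sig_fe"] = out["fe_p"] < p_combined_threshold
    out["sig_votes"] = out["votes"] >= vote_threshold
    out["consensus"] = out["sig_fisher"] & out["sig_fe"] & out["sig_votes"]
    direction = np.where(out["fe_effect"] >= 0, "up", "down")
    if discordance_z_floor > 0:
        direction = np.where(
            np.abs(out["fe_z"]) < discordance_z_floor, "discordant", direction
        )
    out["direction"] = direction
    logger.info(
        "consensus: fisher=%d, fixed-effect=%d, votes=%d, all three=%d",
        int(out["sig_fisher"].sum()), int(out["sig_fe"].sum()),
        int(out["sig_votes"].sum()), int(out["consensus"].sum()),
    )
    return out


def direction_breakdown(n_down: int, n_up: int) -> dict[str, float]:
    """Down/up percentages of a consensus list, rounded to one decimal.

    The published funnel reports 635 down and 625 up of 1,260 consensus
    genes, i.e. 50.4% / 49.6%.
    """
    total = n_down + n_up
    if total <= 0:
        raise ValueError("empty consensus list")
    return {
        "total": float(total),
        "down_pct": round(100.0 * n_down / total, 1),
        "up_pct": round(100.0 * n_up / total, 1),
    }
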