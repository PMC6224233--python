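"""Gene-set over-representation and aging-reference enrichment.

Over-representation analysis (ORA) asks whether a query gene list overlaps
each gene set more than expected given the background universe, using the
one-sided hypergeometric upper tail, with BH correction across sets and the
fold enrichment ``(a/(a+b)) / ((a+c)/N)`` as the effect measure. A separate
2x2 odds-ratio analysis (with Woolf confidence intervals and Fisher's exact
p) quantifies the enrichment of network modules in a curated aging-gene
reference, as in GenAge-style follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment: counts, OR with 95% CI, exact p."""

    name: str
    a: int  # query ∩ set
    b: int  # query \ set
    c: int  # (background ∩ set) \ query
    d: int  # rest
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    fold_enrichment: float
    haldane_corrected: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, tab-separated genes)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(set(genes))]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _counts(query: set, gene_set: set, background: set) -> tuple[int, int, int, int]:
    a = len(query & gene_set)
    b = len(query - gene_set)
    c = len((background & gene_set) - query)
    d = len(background) - a - b - c
    return a, b, c, d


def fold_enrichment(a: int, b: int, c: int, n_background: int) -> float:
    """``(a/(a+b)) / ((a+c)/N)`` — query hit rate over background set rate."""
    if a + b == 0 or a + c == 0 or n_background == 0:
        return float("nan")
    return (a / (a + b)) / ((a + c) / n_background)


def ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    min_overlap: int = 2,
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation for every gene set.

    Sets are intersected with the background; the query must be a subset of
    the background. Sets with fewer than ``min_overlap`` query hits are
    skipped. ``ease=True`` applies the EASE-score penalty (one query hit
    removed before the tail computation) for compatibility with
    DAVID-style output. Results carry BH FDR across the tested sets and are
    sorted by FDR.
    """
    bg = set(background)
    q = set(query)
    if not bg or not q:
        raise ValueError("background and query must be non-empty")
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    rows = []
    for name, members in gene_sets.items():
        gs = set(members) & bg
        a, b, c, d = _counts(q, gs, bg)
        if a < min_overlap:
            continue
        n_bg = len(bg)
        a_eff = max(a - 1, 0) if ease else a
        # P(X >= a) with X ~ Hypergeom(N=n_bg, K=|set|, n=|query|)
        p = stats.hypergeom.sf(a_eff - 1, n_bg, a + c, a + b)
        rows.append({
            "set": name, "a": a, "b": b, "c": c, "d": d,
            "fold_enrichment": fold_enrichment(a, b, c, n_bg),
            "p": float(p),
        })
    out = pd.DataFrame(rows, columns=["set", "a", "b", "c", "d", "fold_enrichment", "p"])
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["fdr", "p", "set"]).reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def odds_ratio_enrichment(
    module_genes: Iterable[str],
    reference_set: Iterable[str],
    background: Iterable[str],
    name: str = "reference",
) -> EnrichmentResult:
    """2x2 odds-ratio enrichment of a module in a reference gene set.

    OR = (a*d)/(b*c) with the Woolf 95% CI
    ``exp(ln OR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))`` and Fisher's exact
    two-sided p on the uncorrected table. When any cell is zero the
    Haldane-Anscombe +0.5 correction is applied to the OR and CI and the
    result is flagged.
    """
    bg = set(background)
    module = set(module_genes) & bg
    ref = set(reference_set) & bg
    if not bg >= (set(module_genes) | set(reference_set)):
        missing = (set(module_genes) | set(reference_set)) - bg
        raise ValueError(f"background is missing {len(missing)} input genes")
    a, b, c, d = _counts(module, ref, bg)
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    odds = (aa * dd) / (bb * cc)
    log_se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    ci_low = float(np.exp(np.log(odds) - 1.96 * log_se))
    ci_high = float(np.exp(np.log(odds) + 1.96 * log_se))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        name=name, a=a, b=b, c=c, d=d,
        odds_ratio=float(odds), ci_low=ci_low, ci_high=ci_high,
        p_value=float(p),
        fold_enrichment=fold_enrichment(a, b, c, len(bg)),
        haldane_corrected=corrected,
    )
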