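"""Gene-set over-representation of the consensus list and module-level
enrichment in the aging reference set.

Runs hypergeometric ORA of the consensus genes against the bundled GMT sets
(the planted aging reference should dominate the decoys), then tests each
significant network module for enrichment in the aging reference with odds
ratios, Woolf 95% confidence intervals and Fisher's exact p.
"""

from pathlib import Path

import pandas as pd

from agemeta.enrichment import odds_ratio_enrichment, ora, read_gmt

DATA = Path("results/data")
META = Path("results/meta")
NET = Path("results/network")
OUT = Path("results/enrichment")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(META / "meta.tsv", sep="\t", index_col="gene")
    background = meta.index.tolist()
    query = meta.index[meta.consensus].tolist()
    sets = read_gmt(DATA / "gene_sets.gmt")

    table = ora(query, sets, background)
    table.to_csv(OUT / "ora.tsv", sep="\t", index=False)
    top = table.iloc[0]
    print(f"ORA over {len(sets)} sets: top set {top.set} "
          f"(fold enrichment {top.fold_enrichment:.2f}, FDR {top.fdr:.2g}); "
          f"{int((table.fdr < 0.05).sum())} sets at FDR < 0.05")

    aging = sets["AGING_REFERENCE"]
    modules = pd.read_csv(NET / "modules.tsv", sep="\t")
    rows = []
    for r in modules.itertuples():
        res = odds_ratio_enrichment(r.members.split(","), aging, background,
                                    name=r.module)
        rows.append({"module": r.module, "size": r.size, "a": res.a,
                     "OR": res.odds_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p_value,
                     "haldane": res.haldane_corrected})
    out = pd.DataFrame(rows).sort_values("p")
    out.to_csv(OUT / "aging_or.tsv", sep="\t", index=False)
    sig = out[out.p < 0.05]
    print(f"aging-reference enrichment: {len(sig)} of {len(out)} modules at "
          f"p < 0.05; strongest: "
          + (", ".join(f"{r.module} (OR={r.OR:.1f}, CI {r.ci_low:.2f}-{r.ci_high:.2f})"
                       for r in sig.head(2).itertuples()) if len(sig) else "none"))


if __name__ == "__main__":
    main()
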