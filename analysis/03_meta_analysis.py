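"""Three-method meta-analysis and the consensus gene list.

Combines the per-study DE tables with Fisher's method, the fixed-effect
model (with Cochran's Q) and vote counting; applies the published
significance rules (combined p < 0.001, votes >= 2); reports the per-method
funnel, the consensus list with up/down percentages, and recovery of the
planted truth.
"""

from pathlib import Path

import pandas as pd

from agemeta.meta import consensus, direction_breakdown, meta_analyze
from agemeta.synthetic import PlantedTruth

DATA = Path("results/data")
DE = Path("results/de")
OUT = Path("results/meta")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    de_tables = {
        p.name[3:-4]: pd.read_csv(p, sep="\t", index_col="gene")
        for p in sorted(DE.glob("de_study*.tsv"))
    }
    table = consensus(meta_analyze(de_tables))
    table.to_csv(OUT / "meta.tsv", sep="\t")

    n_fisher = int(table.sig_fisher.sum())
    n_fe = int(table.sig_fe.sum())
    n_votes = int(table.sig_votes.sum())
    cons = table[table.consensus]
    print(f"per-method significant genes: Fisher {n_fisher}, "
          f"fixed-effect {n_fe}, vote counting {n_votes}")
    n_down = int((cons.direction == "down").sum())
    n_up = int((cons.direction == "up").sum())
    b = direction_breakdown(n_down, n_up)
    print(f"consensus (all three methods): {len(cons)} genes — "
          f"{n_down} down ({b['down_pct']}%), {n_up} up ({b['up_pct']}%)")

    truth = PlantedTruth.from_json(DATA / "truth.json")
    cons_set = set(cons.index)
    recovery = len(cons_set & truth.de_genes) / len(truth.de_genes)
    fpr = len(cons_set & truth.null_genes) / len(truth.null_genes)
    print(f"planted-truth recovery: {100 * recovery:.1f}% of planted genes; "
          f"false-positive rate among nulls {100 * fpr:.2f}%")
    pd.Series(sorted(cons_set), name="gene").to_csv(
        OUT / "consensus_genes.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
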