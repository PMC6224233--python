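"""Per-study differential expression with the moderated t-test.

For each simulated study: empirical-Bayes moderated t (old vs young), BH
FDR, and the per-study significant list at p < 0.05 and FDR < 0.05. Also
reports the all-study overlap (the Venn intersection of independent
analyses), which is expected to be far smaller than any per-study list —
the motivation for meta-analysis.
"""

from pathlib import Path

from agemeta import io
from agemeta.diffexpr import moderated_t, significant_genes, study_overlap
from agemeta.synthetic import PlantedTruth

DATA = Path("results/data")
OUT = Path("results/de")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = PlantedTruth.from_json(DATA / "truth.json")
    lists = {}
    for expr_path in sorted(DATA.glob("study*_expression.tsv")):
        sid = expr_path.name.split("_expression")[0]
        study = io.read_study(expr_path, DATA / f"{sid}_samples.tsv", study_id=sid)
        de = moderated_t(study.matrix, study.groups.loc[study.matrix.columns])
        de.to_csv(OUT / f"de_{sid}.tsv", sep="\t")
        lists[sid] = significant_genes(de)
        print(f"{sid}: {len(lists[sid])} significant genes "
              f"(p<0.05 & FDR<0.05) of {len(de)}")
    inter, _ = study_overlap(lists)
    purity = len(inter & truth.de_genes) / len(inter) if inter else float("nan")
    print(f"all-study overlap: {len(inter)} genes "
          f"({100 * purity:.1f}% planted) — single-study agreement is sparse")


if __name__ == "__main__":
    main()
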