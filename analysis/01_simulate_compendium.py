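"""Simulate the five-study frontal-cortex-style compendium with planted truth.

Emulates the published study structure: five studies with per-study sample
sizes 9/12, 13/18, 52/22, 13/13, 74/90 (young/old), a shared 7,274-gene
universe, ~8.6% of genes planted up- and ~8.7% down-regulated with age at a
one-log2-unit shift, study-level batch offsets and unit residual noise.
Writes per-study expression + metadata TSVs, a scored PPI edge list over the
planted communities, GMT gene sets (a half-overlapping aging reference plus
random decoys), the qPCR Ct table, and the ground truth JSON.
"""

from pathlib import Path

from agemeta import io
from agemeta.enrichment import write_gmt
from agemeta.synthetic import (
    CompendiumSpec,
    generate_compendium,
    generate_gene_sets,
    generate_ppi,
    generate_qpcr,
)

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CompendiumSpec(seed=SEED)
    studies, truth = generate_compendium(spec)
    for s in studies:
        io.write_study(s, OUT)
    n_samples = sum(len(s.sample_meta) for s in studies)
    print(f"simulated {len(studies)} studies, {spec.genes_total} genes, "
          f"{n_samples} samples ({len(truth.up_genes)} up / "
          f"{len(truth.down_genes)} down planted)")

    edges = generate_ppi(truth, seed=SEED)
    io.write_edge_list(edges, OUT / "ppi_edges.tsv")
    print(f"PPI edge list: {len(edges)} scored edges over "
          f"{len(truth.planted_module_assignments)} community genes")

    write_gmt(generate_gene_sets(truth, seed=SEED), OUT / "gene_sets.gmt")
    io.write_qpcr(
        generate_qpcr(["Cdc42", "Hdac1", "Yes1"],
                      {"Cdc42": 0.5, "Hdac1": 2.0, "Yes1": 1.8},
                      ct_noise_sd=0.15, seed=SEED),
        OUT / "qpcr_ct.tsv",
    )
    truth.to_json(OUT / "truth.json")
    print(f"wrote gene sets, qPCR Ct table and ground truth to {OUT}")


if __name__ == "__main__":
    main()
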