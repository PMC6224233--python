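"""Synthetic multi-study compendia, PPI graphs, gene sets and qPCR tables.

Everything downstream of this module (differential expression, three-method
meta-analysis, network hub/module discovery, enrichment, qPCR statistics) is
exercised on data generated here with planted ground truth, so the whole
pipeline is testable without downloading any microarray series.

The default :class:`CompendiumSpec` emulates the structure of the published
five-study frontal-cortex compendium: five studies with the published
per-study sample sizes (9/12, 13/18, 52/22, 13/13, 74/90 young/old), a
shared universe of 7,274 genes, a mix of up- and downregulated age effects,
study-level batch shifts and Gaussian residual noise. Ages are drawn
uniformly within the two design brackets (20-40 and 60-90 years); a
continuous-age mode exists for correlation-with-age follow-ups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import StudyExpression

# Young/old sample sizes of the five published studies (Table-1 structure).
DEFAULT_N_YOUNG = (9, 13, 52, 13, 74)
DEFAULT_N_OLD = (12, 18, 22, 13, 90)


@dataclass
class CompendiumSpec:
    """Parameters of a synthetic multi-study compendium.

    ``frac_up`` and ``frac_down`` are the proportions of the gene universe
    planted as truly age-regulated (old vs young); defaults reproduce the
    published consensus fractions (625 up and 635 down of 7,274 genes).
    ``effect_size_delta`` is the standardized mean shift (old - young) in
    log2 units applied to planted genes. ``study_batch_sd`` is the SD of
    per-study, per-gene baseline offsets; ``noise_sd`` the residual SD.
    """

    n_studies: int = 5
    genes_total: int = 7274
    n_young: int | Sequence[int] = DEFAULT_N_YOUNG
    n_old: int | Sequence[int] = DEFAULT_N_OLD
    frac_up: float = 625 / 7274
    frac_down: float = 635 / 7274
    effect_size_delta: float = 1.0
    study_batch_sd: float = 0.3
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    module_size: int = 20
    age_mode: Literal["two_group", "continuous"] = "two_group"
    scale: Literal["log2", "raw"] = "log2"
    raw_mult_noise_sd: float = 0.1
    seed: int = 0

    def per_study(self, values: int | Sequence[int], name: str) -> list[int]:
        if isinstance(values, (int, np.integer)):
            out = [int(values)] * self.n_studies
        else:
            out = [int(v) for v in values]
            if len(out) != self.n_studies:
                raise ValueError(f"{name}: expected {self.n_studies} values, got {len(out)}")
        return out

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies: must be >= 1")
        if self.genes_total < 1:
            raise ValueError("genes_total: must be >= 1")
        for name, vals in (("n_young", self.n_young), ("n_old", self.n_old)):
            for v in self.per_study(vals, name):
                if v < 3:
                    raise ValueError(f"{name}: every study needs >= 3 samples per group")
        for name, v in (("frac_up", self.frac_up), ("frac_down", self.frac_down)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up: frac_up + frac_down must be <= 1")
        for name, v in (("study_batch_sd", self.study_batch_sd), ("noise_sd", self.noise_sd)):
            if v < 0:
                raise ValueError(f"{name}: must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic compendium."""

    up_genes: set[str]
    down_genes: set[str]
    null_genes: set[str]
    planted_module_assignments: dict[str, int] = field(default_factory=dict)
    aging_reference_set: set[str] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    @property
    def universe(self) -> set[str]:
        return self.up_genes | self.down_genes | self.null_genes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "up_genes": sorted(self.up_genes),
            "down_genes": sorted(self.down_genes),
            "null_genes": sorted(self.null_genes),
            "planted_module_assignments": self.planted_module_assignments,
            "aging_reference_set": sorted(self.aging_reference_set),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            up_genes=set(d["up_genes"]),
            down_genes=set(d["down_genes"]),
            null_genes=set(d["null_genes"]),
            planted_module_assignments={k: int(v) for k, v in d["planted_module_assignments"].items()},
            aging_reference_set=set(d["aging_reference_set"]),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_compendium(
    spec: CompendiumSpec,
    aging_overlap_fraction: float = 0.5,
    aging_set_size: int = 60,
) -> tuple[list[StudyExpression], PlantedTruth]:
    """Simulate per-study expression matrices with planted age effects.

    Expression is simulated directly on the log2 scale as
    ``baseline(gene) + study_offset(study, gene) + group_effect + noise``,
    where the group effect is ``+delta`` (up genes) or ``-delta`` (down
    genes) in old samples only. With ``spec.scale == 'raw'`` the log2 values
    are exponentiated and multiplicative noise added, to exercise the
    normalization chain. Output is bit-reproducible for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.genes_total)
    n_up = int(round(spec.frac_up * spec.genes_total))
    n_down = int(round(spec.frac_down * spec.genes_total))
    perm = rng.permutation(spec.genes_total)
    up = [genes[i] for i in perm[:n_up]]
    down = [genes[i] for i in perm[n_up:n_up + n_down]]
    null = [genes[i] for i in perm[n_up + n_down:]]

    effect = np.zeros(spec.genes_total)
    idx = {g: i for i, g in enumerate(genes)}
    for g in up:
        effect[idx[g]] = spec.effect_size_delta
    for g in down:
        effect[idx[g]] = -spec.effect_size_delta

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.genes_total)
    n_young = spec.per_study(spec.n_young, "n_young")
    n_old = spec.per_study(spec.n_old, "n_old")

    studies: list[StudyExpression] = []
    for s in range(spec.n_studies):
        ny, no = n_young[s], n_old[s]
        n = ny + no
        study_id = f"study{s + 1}"
        samples = [f"{study_id}_s{j + 1:03d}" for j in range(n)]
        offsets = rng.normal(0.0, spec.study_batch_sd, spec.genes_total)
        if spec.age_mode == "continuous":
            ages = rng.uniform(20.0, 90.0, n)
            groups = np.where(ages <= 55.0, "young", "old")
            # linear trend centered at 55 y, scaled so the bracket-mean
            # difference (old 60-90 vs young 20-40) equals delta
            dose = (ages - 55.0) / 45.0
            group_term = np.outer(effect, dose)
        else:
            ages = np.concatenate([
                rng.uniform(*_bracket("young"), ny),
                rng.uniform(*_bracket("old"), no),
            ])
            groups = np.array(["young"] * ny + ["old"] * no)
            group_term = np.outer(effect, (groups == "old").astype(float))
        noise = rng.normal(0.0, spec.noise_sd, (spec.genes_total, n))
        mat = baseline[:, None] + offsets[:, None] + group_term + noise
        if spec.scale == "raw":
            mult = rng.normal(0.0, spec.raw_mult_noise_sd, (spec.genes_total, n))
            mat = np.exp2(mat) * np.exp(mult)
        matrix = pd.DataFrame(mat, index=genes, columns=samples)
        matrix.index.name = "gene"
        meta = pd.DataFrame({
            "sample": samples,
            "study": study_id,
            "group": groups,
            "age": np.round(ages, 1),
        })
        studies.append(StudyExpression(study_id=study_id, matrix=matrix, sample_meta=meta))

    modules = _assign_modules(up + down, spec.module_size)
    aging_set = _aging_reference(rng, up + down, null, aging_set_size, aging_overlap_fraction)
    truth = PlantedTruth(
        up_genes=set(up),
        down_genes=set(down),
        null_genes=set(null),
        planted_module_assignments=modules,
        aging_reference_set=aging_set,
    )
    return studies, truth


def _bracket(group: str) -> tuple[float, float]:
    return (20.0, 40.0) if group == "young" else (60.0, 90.0)


def _assign_modules(de_genes: Sequence[str], module_size: int) -> dict[str, int]:
    return {g: i // module_size for i, g in enumerate(de_genes)}


def _aging_reference(
    rng: np.random.Generator,
    de_genes: Sequence[str],
    null_genes: Sequence[str],
    size: int,
    overlap_fraction: float,
) -> set[str]:
    n_de = min(int(round(size * overlap_fraction)), len(de_genes))
    n_null = min(size - n_de, len(null_genes))
    picked_de = rng.choice(np.asarray(de_genes), n_de, replace=False) if n_de else []
    picked_null = rng.choice(np.asarray(null_genes), n_null, replace=False) if n_null else []
    return set(picked_de) | set(picked_null)


def generate_ppi(
    truth: PlantedTruth,
    intra_p: float = 0.3,
    inter_p: float = 0.01,
    score_range: tuple[int, int] = (901, 999),
    seed: int = 0,
    hub_genes: Sequence[str] = (),
    hub_degree: int = 30,
    background_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Planted-partition interaction graph standing in for a STRING edge list.

    Genes sharing a planted community label are wired with probability
    ``intra_p``, all other pairs with ``inter_p``; every edge carries a
    combined score drawn uniformly from ``score_range`` on the 0-1000
    convention (the default range sits above the >900 confidence cut).
    ``hub_genes`` receive additional random attachments until their degree
    reaches ``hub_degree``. Returns a tidy edge list with columns
    ``protein1, protein2, combined_score``.
    """
    if not (0.0 <= inter_p < intra_p <= 1.0) and not (intra_p == inter_p == 0.0):
        if not (0.0 <= inter_p <= intra_p <= 1.0):
            raise ValueError("need 0 <= inter_p <= intra_p <= 1")
    rng = np.random.default_rng(seed)
    community = dict(truth.planted_module_assignments)
    nodes = sorted(community)
    if background_genes is not None:
        for g in background_genes:
            community.setdefault(g, -1)
        nodes = sorted(community)
    edges: set[tuple[str, str]] = set()
    arr = np.array(nodes)
    labels = np.array([community[g] for g in nodes])
    n = len(nodes)
    # vectorized Bernoulli over the upper triangle
    iu, ju = np.triu_indices(n, k=1)
    same = (labels[iu] == labels[ju]) & (labels[iu] >= 0)
    probs = np.where(same, intra_p, inter_p)
    keep = rng.random(len(probs)) < probs
    for a, b in zip(arr[iu[keep]], arr[ju[keep]]):
        edges.add((a, b) if a < b else (b, a))
    # top up designated hubs with random attachments
    for hub in hub_genes:
        if hub not in community:
            raise ValueError(f"hub gene {hub!r} is not a network node")
        deg = sum(1 for e in edges if hub in e)
        others = [g for g in nodes if g != hub]
        rng.shuffle(others)
        for other in others:
            if deg >= hub_degree:
                break
            e = (hub, other) if hub < other else (other, hub)
            if e not in edges:
                edges.add(e)
                deg += 1
    lo, hi = score_range
    rows = sorted(edges)
    scores = rng.integers(lo, hi + 1, len(rows))
    return pd.DataFrame({
        "protein1": [a for a, _ in rows],
        "protein2": [b for _, b in rows],
        "combined_score": scores,
    })


def generate_gene_sets(
    truth: PlantedTruth,
    n_random_sets: int = 10,
    set_size: int = 40,
    seed: int = 0,
) -> dict[str, list[str]]:
    """GMT-style gene sets: the planted aging reference plus random decoys."""
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(truth.universe))
    sets = {"AGING_REFERENCE": sorted(truth.aging_reference_set)}
    for i in range(n_random_sets):
        sets[f"RANDOM_SET_{i + 1:02d}"] = sorted(
            rng.choice(universe, min(set_size, len(universe)), replace=False)
        )
    return sets


def generate_qpcr(
    genes: Sequence[str],
    fold_changes: Mapping[str, float] | Sequence[float],
    n_control: int = 6,
    n_treated: int = 6,
    ct_noise_sd: float = 0.1,
    reference_gene: str = "Gapdh",
    reference_ct: float = 18.0,
    target_ct: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for relative-quantification analysis.

    The reference gene's Ct is constant in expectation across groups; each
    target gene's Ct is shifted by ``-log2(fold)`` in the treated group, so
    the 2^-ddCt calculation recovers ``fold`` exactly at zero noise. Columns:
    ``sample, group, gene, role, Ct``.
    """
    if not isinstance(fold_changes, Mapping):
        fold_changes = dict(zip(genes, fold_changes))
    for g in genes:
        fold = float(fold_changes[g])
        if fold <= 0:
            raise ValueError(f"fold change for {g!r} must be > 0, got {fold}")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [("control", f"ctrl_{i + 1}") for i in range(n_control)] + [
        ("treated", f"trt_{i + 1}") for i in range(n_treated)
    ]
    for group, sample in samples:
        rows.append({
            "sample": sample, "group": group, "gene": reference_gene,
            "role": "reference",
            "Ct": reference_ct + rng.normal(0.0, ct_noise_sd),
        })
        for g in genes:
            shift = -np.log2(float(fold_changes[g])) if group == "treated" else 0.0
            rows.append({
                "sample": sample, "group": group, "gene": g, "role": "target",
                "Ct": target_ct + shift + rng.normal(0.0, ct_noise_sd),
            })
    return pd.DataFrame(rows)
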