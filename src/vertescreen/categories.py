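"""Vertebral phenotype categories, set intersections, and pleiotropy.

The retained parameters are grouped into six general vertebral categories
(somitogenesis, spine shape, tail morphology, vertebral form, vertebral
number, vertebral processes).  Gene-parameter hits are rolled up into
per-category gene sets; overlaps between categories are tabulated as
exclusive intersection cells (the counts underlying an UpSet plot), and
per-gene vertebral pleiotropy relates the number of vertebral parameters a
gene hits to its total phenotype count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

DEFAULT_LETHALITY_LABEL = "preweaning lethality"


@dataclass(frozen=True)
class PleiotropyProfile:
    gene_symbol: str
    n_vertebral_parameters: int
    n_total_phenotypes: int
    vertebral_fraction: float
    vertebral_only: bool
    majority_vertebral: bool  # vertebral_fraction >= 0.5 (boundary inclusive)
    lethality_only_other: bool


def assign(
    gene_parameter_pairs,
    category_map: dict[str, str],
    strict: bool = True,
) -> dict[str, set[str]]:
    """Roll gene-parameter hits up into per-category gene sets.

    `gene_parameter_pairs` is an iterable of (gene_symbol, parameter_id).
    Genes hitting several parameters of one category count once (set
    semantics).  In strict mode an unmapped parameter is an error; in
    permissive mode it is skipped.
    """
    sets: dict[str, set[str]] = {cat: set() for cat in sorted(set(category_map.values()))}
    unmapped = set()
    for gene, pid in gene_parameter_pairs:
        cat = category_map.get(pid)
        if cat is None:
            unmapped.add(pid)
            continue
        sets[cat].add(gene)
    if unmapped and strict:
        raise ValueError(f"parameters missing from category map: {sorted(unmapped)}")
    return sets


def intersections(category_sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Exclusive intersection-cell counts (UpSet form).

    Each element of the union is assigned to exactly one cell: the set of
    categories it belongs to.  Cells therefore partition the union, and the
    cell counts sum to the union's size.  Only nonempty cells are returned,
    keyed by frozenset of category names.
    """
    if not category_sets:
        raise ValueError("at least one category set required")
    membership: dict[str, frozenset] = {}
    for cat, genes in category_sets.items():
        for g in genes:
            membership[g] = membership.get(g, frozenset()) | {cat}
    cells: dict[frozenset, int] = {}
    for combo in membership.values():
        cells[combo] = cells.get(combo, 0) + 1
    return cells


def intersections_frame(category_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Cell counts as a table with one indicator column per category."""
    cats = sorted(category_sets)
    cells = intersections(category_sets)
    rows = []
    for combo, n in sorted(cells.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        row = {c: (c in combo) for c in cats}
        row["degree"] = len(combo)
        row["count"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_overlaps(category_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Raw (non-exclusive) pairwise shared-gene counts between categories."""
    rows = [
        {"category_a": a, "category_b": b,
         "n_shared": len(category_sets[a] & category_sets[b])}
        for a, b in combinations(sorted(category_sets), 2)
    ]
    return pd.DataFrame(rows)


def pleiotropy(
    gene_parameter_pairs,
    total_phenotypes: dict[str, int],
    other_phenotype_labels: dict[str, list[str]] | None = None,
    lethality_label: str = DEFAULT_LETHALITY_LABEL,
) -> list[PleiotropyProfile]:
    """Per-gene vertebral pleiotropy profiles.

    `total_phenotypes` maps each gene to its total phenotype count (vertebral
    and non-vertebral; supplied, not recomputed).  `other_phenotype_labels`
    optionally lists each gene's non-vertebral phenotype names, used to flag
    genes whose only other phenotype is preweaning lethality
    (case-insensitive substring match on `lethality_label`).
    """
    per_gene: dict[str, set[str]] = {}
    for gene, pid in gene_parameter_pairs:
        per_gene.setdefault(gene, set()).add(pid)
    other_phenotype_labels = other_phenotype_labels or {}
    needle = lethality_label.strip().lower()

    profiles = []
    for gene in sorted(per_gene):
        n_vert = len(per_gene[gene])
        n_total = total_phenotypes.get(gene)
        if n_total is None:
            raise KeyError(f"no total phenotype count supplied for {gene}")
        if n_total < n_vert:
            raise ValueError(
                f"{gene}: total phenotypes {n_total} < vertebral parameters {n_vert}"
            )
        frac = n_vert / n_total
        others = other_phenotype_labels.get(gene, [])
        lethal_only = (
            n_total > n_vert
            and len(others) > 0
            and all(needle in lbl.strip().lower() for lbl in others)
        )
        profiles.append(
            PleiotropyProfile(
                gene_symbol=gene,
                n_vertebral_parameters=n_vert,
                n_total_phenotypes=n_total,
                vertebral_fraction=frac,
                vertebral_only=n_vert == n_total,
                majority_vertebral=frac >= 0.5,
                lethality_only_other=lethal_only,
            )
        )
    return profiles


def pleiotropy_frame(profiles: list[PleiotropyProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in profiles])


def category_summary(category_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Unique-gene count per category plus the size of the union."""
    rows = [{"category": c, "n_unique_genes": len(s)} for c, s in sorted(category_sets.items())]
    rows.append({"category": "union", "n_unique_genes": len(set().union(*category_sets.values()))})
    return pd.DataFrame(rows)
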