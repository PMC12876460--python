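"""Parameter catalogue: the retained vertebral parameters and exclusion lists.

The screen starts from 76 skeleton-related phenotyping parameters across the
adult X-ray (XRY), dysmorphology/SHIRPA (CSD), body-composition (DXA) and
embryo gross-morphology (GEL/GEM/GEO/GEP) pipelines, and keeps only those
that pertain to the vertebral column and have at least one associated gene.
The shipped catalogue records the 25 retained parameters, their six general
vertebral categories, and the parameters excluded (with reasons). It is a
plain YAML file so other screens can swap in their own catalogue.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Six general vertebral phenotype categories.
CATEGORIES = (
    "somitogenesis",
    "spine shape",
    "tail morphology",
    "vertebral form",
    "vertebral number",
    "vertebral processes",
)


@dataclass(frozen=True)
class ParameterInfo:
    parameter_id: str
    name: str
    category: str
    n_genes_reference: int | None = None


@dataclass
class ParameterCatalogue:
    """The retained vertebral parameters plus exclusion lists."""

    parameters: dict[str, ParameterInfo]
    excluded: dict[str, list[str]] = field(default_factory=dict)

    @property
    def parameter_ids(self) -> set[str]:
        return set(self.parameters)

    def category_map(self) -> dict[str, str]:
        """parameter_id -> category mapping (CategoryMap)."""
        return {pid: info.category for pid, info in self.parameters.items()}

    def reference_gene_counts(self) -> dict[str, int]:
        """Published per-parameter candidate-gene counts (reporting only)."""
        return {
            pid: info.n_genes_reference
            for pid, info in self.parameters.items()
            if info.n_genes_reference is not None
        }


def load_catalogue(path: str | Path | None = None) -> ParameterCatalogue:
    """Load a parameter catalogue YAML; default is the shipped vertebral one."""
    if path is None:
        ref = importlib.resources.files("vertescreen.data") / "vertebral_parameters.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    params = {}
    for pid, rec in raw.get("parameters", {}).items():
        cat = rec["category"]
        if cat not in CATEGORIES:
            raise ValueError(f"unknown vertebral category {cat!r} for {pid}")
        params[pid] = ParameterInfo(
            parameter_id=pid,
            name=rec.get("name", pid),
            category=cat,
            n_genes_reference=rec.get("n_genes"),
        )
    return ParameterCatalogue(parameters=params, excluded=raw.get("excluded", {}))
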