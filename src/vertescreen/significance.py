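"""Candidate-gene identification from knockout statistical results.

Each record is one gene x parameter x zygosity statistical-analysis row with
per-sex knockout-effect p-values, a genotype main-effect p-value, a
sex-by-genotype interaction p-value, and the phenotyping framework's own
significance flag.  A gene is called significant in a sex when any of its
rows has that sex's knockout-effect p-value below alpha (default 1e-4,
strict `<`); genes are then classified as male-only / female-only /
both-sexes / not-considered (no sex-stratified analysis) / considered but
not significant.  Sexual dimorphism is a separate screen on the interaction
p-value, and life stage (embryo vs adult) follows from the procedure that
produced the parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

DEFAULT_ALPHA = 1e-4

#: Procedure-code -> life-stage mapping: embryo gross morphology at
#: E9.5/E12.5/E14.5-15.5/E18.5 vs adult X-ray / SHIRPA-dysmorphology / DXA.
EMBRYO_PROCEDURES = frozenset({"GEL", "GEM", "GEO", "GEP"})
ADULT_PROCEDURES = frozenset({"XRY", "CSD", "DXA"})

ZYGOSITIES = ("homozygote", "heterozygote", "hemizygote")

_ZYGOSITY_ALIASES = {
    "homozygote": "homozygote",
    "homozygous": "homozygote",
    "hom": "homozygote",
    "heterozygote": "heterozygote",
    "heterozygous": "heterozygote",
    "het": "heterozygote",
    "hemizygote": "hemizygote",
    "hemizygous": "hemizygote",
    "hemi": "hemizygote",
}


class SexCategory(str, Enum):
    MALE_ONLY = "male-only"
    FEMALE_ONLY = "female-only"
    BOTH = "both sexes"
    NOT_CONSIDERED = "not considered"
    NOT_SIGNIFICANT = "considered but not significant"


@dataclass(frozen=True)
class StatResultRow:
    """One statistical-analysis record for a gene x parameter x zygosity."""

    gene_symbol: str
    parameter_id: str
    parameter_name: str
    procedure_code: str
    zygosity: str
    male_ko_p: float | None = None
    female_ko_p: float | None = None
    genotype_main_p: float | None = None
    interaction_p: float | None = None
    significant_flag: bool = False

    def __post_init__(self):
        zyg = _ZYGOSITY_ALIASES.get(self.zygosity.strip().lower())
        if zyg is None:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        object.__setattr__(self, "zygosity", zyg)
        for name in ("male_ko_p", "female_ko_p", "genotype_main_p", "interaction_p"):
            p = getattr(self, name)
            if p is not None and math.isnan(p):
                object.__setattr__(self, name, None)
            elif p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1] for {self.gene_symbol}")


@dataclass(frozen=True)
class ParameterFilterConfig:
    """Which parameters enter the screen.

    An empty include set means "all parameters not explicitly excluded"
    (permissive default-open).  `strict` makes unknown parameter IDs an error
    rather than silently passing them through the permissive filter.
    """

    include_parameter_ids: frozenset[str] = frozenset()
    exclude_parameter_ids: frozenset[str] = frozenset()
    exclusion_reasons: dict[str, str] = field(default_factory=dict)
    strict: bool = False

    def __post_init__(self):
        overlap = self.include_parameter_ids & self.exclude_parameter_ids
        if overlap:
            raise ValueError(f"parameters both included and excluded: {sorted(overlap)}")


@dataclass
class GeneSignificance:
    gene_symbol: str
    sex_category: SexCategory
    dimorphic: bool
    main_effect_only: bool
    zygosities: set[str]
    life_stages: set[str]
    parameters_hit: set[str]


def select_parameters(
    rows: list[StatResultRow], cfg: ParameterFilterConfig
) -> tuple[list[StatResultRow], pd.DataFrame]:
    """Restrict rows to the configured parameters and drop empty parameters.

    Parameters with zero significant genes are removed (thirteen skeletal
    parameters met this fate in the original screen).  Returns the surviving
    rows and a per-parameter summary of significant-gene counts.
    """
    if cfg.strict and cfg.include_parameter_ids:
        known = cfg.include_parameter_ids | cfg.exclude_parameter_ids
        unknown = sorted({r.parameter_id for r in rows} - known)
        if unknown:
            raise ValueError(f"unknown parameter ids: {unknown}")

    def admitted(pid: str) -> bool:
        if pid in cfg.exclude_parameter_ids:
            return False
        if cfg.include_parameter_ids:
            return pid in cfg.include_parameter_ids
        return True

    kept = [r for r in rows if admitted(r.parameter_id)]
    genes_per_param: dict[str, set[str]] = {}
    for r in kept:
        if r.significant_flag:
            genes_per_param.setdefault(r.parameter_id, set()).add(r.gene_symbol)
    nonempty = {pid for pid, genes in genes_per_param.items() if genes}
    kept = [r for r in kept if r.parameter_id in nonempty]
    summary = pd.DataFrame(
        sorted(
            ((pid, len(genes)) for pid, genes in genes_per_param.items() if genes),
            key=lambda t: t[0],
        ),
        columns=["parameter_id", "n_significant_genes"],
    )
    return kept, summary


def _below(p: float | None, alpha: float) -> bool:
    return p is not None and p < alpha


def classify_sex(rows: list[StatResultRow], alpha: float = DEFAULT_ALPHA) -> SexCategory:
    """Classify one gene's rows into the five per-sex significance categories.

    Missing p-values are never significant; a gene whose rows carry no
    sex-stratified p-values at all was "not considered" by sex.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not rows:
        raise ValueError("classify_sex requires at least one row")
    any_sex_p = any(r.male_ko_p is not None or r.female_ko_p is not None for r in rows)
    male = any(_below(r.male_ko_p, alpha) for r in rows)
    female = any(_below(r.female_ko_p, alpha) for r in rows)
    if male and female:
        return SexCategory.BOTH
    if male:
        return SexCategory.MALE_ONLY
    if female:
        return SexCategory.FEMALE_ONLY
    if not any_sex_p:
        return SexCategory.NOT_CONSIDERED
    return SexCategory.NOT_SIGNIFICANT


def flag_dimorphism(rows: list[StatResultRow], alpha: float = DEFAULT_ALPHA) -> bool:
    """Sexual-dimorphism screen: any sex x genotype interaction p < alpha."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return any(_below(r.interaction_p, alpha) for r in rows)


def screen_main_effect(rows: list[StatResultRow], alpha: float = DEFAULT_ALPHA) -> bool:
    """Stricter screen: genotype main effect p < alpha with no significant
    interaction anywhere (interaction veto applies across all rows)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if flag_dimorphism(rows, alpha):
        return False
    return any(_below(r.genotype_main_p, alpha) for r in rows)


def classify_life_stage(procedure_code: str) -> str:
    """Map a procedure code to "embryo" or "adult"."""
    code = procedure_code.strip().upper()
    if code in EMBRYO_PROCEDURES:
        return "embryo"
    if code in ADULT_PROCEDURES:
        return "adult"
    raise ValueError(f"unknown procedure code {procedure_code!r}")


def summarize(
    rows: list[StatResultRow],
    cfg: ParameterFilterConfig | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[GeneSignificance], pd.DataFrame]:
    """Per-gene classification plus category-count summary.

    Zygosity and life-stage tallies are over the gene's *significant* rows
    (the rows flagged significant by the upstream framework); a gene hit in
    both homozygous and heterozygous rows contributes to both tallies, so
    zygosity totals may exceed the number of genes.
    """
    if cfg is not None:
        rows, _ = select_parameters(rows, cfg)
    by_gene: dict[str, list[StatResultRow]] = {}
    for r in rows:
        by_gene.setdefault(r.gene_symbol, []).append(r)

    records: list[GeneSignificance] = []
    for gene in sorted(by_gene):
        grows = by_gene[gene]
        sig_rows = [r for r in grows if r.significant_flag]
        records.append(
            GeneSignificance(
                gene_symbol=gene,
                sex_category=classify_sex(grows, alpha),
                dimorphic=flag_dimorphism(grows, alpha),
                main_effect_only=screen_main_effect(grows, alpha),
                zygosities={r.zygosity for r in sig_rows},
                life_stages={classify_life_stage(r.procedure_code) for r in sig_rows},
                parameters_hit={r.parameter_id for r in sig_rows},
            )
        )

    sig_records = [g for g in records if g.parameters_hit]
    stage_counts = {"embryo-only": 0, "adult-only": 0, "both": 0}
    for g in sig_records:
        if g.life_stages == {"embryo"}:
            stage_counts["embryo-only"] += 1
        elif g.life_stages == {"adult"}:
            stage_counts["adult-only"] += 1
        elif g.life_stages == {"embryo", "adult"}:
            stage_counts["both"] += 1

    items = [("n_genes", len(records)), ("n_significant_genes", len(sig_records))]
    for cat in SexCategory:
        items.append(
            (f"sex:{cat.value}", sum(g.sex_category is cat for g in records))
        )
    items.append(("dimorphic", sum(g.dimorphic for g in records)))
    for zyg in ZYGOSITIES:
        items.append(
            (f"zygosity:{zyg}", sum(zyg in g.zygosities for g in records))
        )
    for label, n in stage_counts.items():
        items.append((f"life_stage:{label}", n))
    summary = pd.DataFrame(items, columns=["statistic", "count"])
    return records, summary


# -- tabular I/O --------------------------------------------------------------

#: Canonical column names; a column map config may rename external exports.
STAT_COLUMNS = [
    "gene_symbol",
    "parameter_id",
    "parameter_name",
    "procedure_code",
    "zygosity",
    "male_ko_p",
    "female_ko_p",
    "genotype_main_p",
    "interaction_p",
    "significant_flag",
]


def rows_from_frame(df: pd.DataFrame, column_map: dict[str, str] | None = None) -> list[StatResultRow]:
    """Build StatResultRow records from a table, optionally renaming columns
    (external name -> canonical name)."""
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("gene_symbol", "parameter_id", "procedure_code", "zygosity") if c not in df.columns]
    if missing:
        raise ValueError(f"statistical-results table missing columns: {missing}")
    rows = []
    for rec in df.to_dict("records"):
        def p(col):
            v = rec.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        flag = rec.get("significant_flag", False)
        if isinstance(flag, str):
            flag = flag.strip().lower() in {"true", "1", "yes"}
        rows.append(
            StatResultRow(
                gene_symbol=str(rec["gene_symbol"]),
                parameter_id=str(rec["parameter_id"]),
                parameter_name=str(rec.get("parameter_name", "")),
                procedure_code=str(rec["procedure_code"]),
                zygosity=str(rec["zygosity"]),
                male_ko_p=p("male_ko_p"),
                female_ko_p=p("female_ko_p"),
                genotype_main_p=p("genotype_main_p"),
                interaction_p=p("interaction_p"),
                significant_flag=bool(flag),
            )
        )
    return rows


def read_stat_results(path, column_map: dict[str, str] | None = None) -> list[StatResultRow]:
    sep = "," if str(path).endswith(".csv") else "\t"
    return rows_from_frame(pd.read_csv(path, sep=sep), column_map)


def significance_frame(records: list[GeneSignificance]) -> pd.DataFrame:
    """One row per gene, sets serialized as semicolon-joined sorted strings."""
    return pd.DataFrame(
        {
            "gene_symbol": [g.gene_symbol for g in records],
            "sex_category": [g.sex_category.value for g in records],
            "dimorphic": [g.dimorphic for g in records],
            "main_effect_only": [g.main_effect_only for g in records],
            "zygosities": [";".join(sorted(g.zygosities)) for g in records],
            "life_stages": [";".join(sorted(g.life_stages)) for g in records],
            "parameters_hit": [";".join(sorted(g.parameters_hit)) for g in records],
        }
    )
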