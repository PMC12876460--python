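"""Synthetic inputs with planted ground truth for the vertebral screen.

Generates all four pipeline inputs — a gene annotation on a mouse-like
genome, a knockout statistical-results table, per-animal categorical
observations, and a somite expression matrix with DE lists — with known
planted structure (significant genes and their sex/zygosity/life-stage
categories, per-stratum penetrance, spatial gene clusters, expression
cluster profiles) so every downstream stage can be validated without any
external download.

One seed governs a whole simulation; each operation derives its own
deterministic sub-stream, so adding one operation never shifts another's
output.  Non-significant p-values are drawn uniformly on [alpha, 1) so that
planted truth is recoverable by construction (a planted non-significant
gene can never cross the threshold by chance).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import GeneLocus
from .expression import SOMITE_LEVELS, STAGES, ExpressionMatrix
from .penetrance import ObservationRecord
from .significance import SexCategory, StatResultRow

#: GRCm39-like chromosome lengths in bp (19 autosomes + X + Y, ~2.7 Gb).
MOUSE_CHROMOSOMES: dict[str, int] = {
    "1": 195_154_279, "2": 181_755_017, "3": 159_745_316, "4": 156_860_686,
    "5": 151_758_149, "6": 149_588_044, "7": 144_995_196, "8": 130_127_694,
    "9": 124_359_700, "10": 130_530_862, "11": 121_973_369, "12": 120_092_757,
    "13": 120_883_175, "14": 125_139_656, "15": 104_073_951, "16": 98_008_968,
    "17": 95_294_699, "18": 90_720_763, "19": 61_420_004,
    "X": 169_476_592, "Y": 91_455_967,
}

#: Sex-category mix planted among significant genes, mirroring the observed
#: screen proportions (male-only 53, female-only 34, both 41, not considered
#: 71, considered-but-not-significant 5, of 204).
SEX_CATEGORY_WEIGHTS = {
    SexCategory.MALE_ONLY: 53,
    SexCategory.FEMALE_ONLY: 34,
    SexCategory.BOTH: 41,
    SexCategory.NOT_CONSIDERED: 71,
    SexCategory.NOT_SIGNIFICANT: 5,
}

#: Life-stage mix (embryo-only 63, adult-only 139, both 2, of 204).
LIFE_STAGE_WEIGHTS = {"embryo": 63, "adult": 139, "both": 2}

ADULT_PARAMETER_IDS = (
    "IMPC_XRY_019_001", "IMPC_XRY_018_001", "IMPC_XRY_060_001",
    "IMPC_XRY_055_001", "IMPC_XRY_057_001", "IMPC_CSD_002_001",
    "IMPC_XRY_017_001", "IMPC_XRY_063_001",
)
EMBRYO_PARAMETER_IDS = (
    "IMPC_GEL_064_001", "IMPC_GEL_033_001", "IMPC_GEM_029_001",
    "IMPC_GEO_033_001", "IMPC_GEP_038_001", "IMPC_GEP_078_001",
)

# fixed sub-stream ids per operation
_OP_ANNOTATION, _OP_TARGETS, _OP_STATS, _OP_OBS, _OP_EXPR = range(5)


@dataclass
class SimConfig:
    """Study conditions for one simulation.

    Defaults mirror the screen's own scale where it states one: 204 target
    genes, alpha 1e-4, the six somite stages with somite-trio levels, six
    developmental stages, 5% non-call records.
    """

    seed: int = 0
    n_genes: int = 2_000
    n_target_genes: int = 204
    chromosomes: dict[str, int] = field(default_factory=lambda: dict(MOUSE_CHROMOSOMES))
    n_parameters: int = 25
    alpha_true: float = 1e-4
    penetrance_truth: dict[str, float] = field(
        default_factory=lambda: {
            "GenePen02": 0.2, "GenePen04": 0.4, "GenePen06": 0.6,
            "GenePen08": 0.8, "GenePen10": 1.0,
        }
    )
    n_animals_per_stratum: int = 20
    noncall_fraction: float = 0.05
    control_fraction: float = 0.25
    n_planted_spatial_clusters: int = 10
    genes_per_cluster: int = 5
    cluster_span_bp: int = 100_000
    expression_cluster_count: int = 8
    n_dimorphic_genes: int = 0
    noise_sd: float = 0.25
    gene_length_bp: int = 10_000
    not_expressed_fraction: float = 0.10
    n_expression_replicates: int = 2

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("chromosome list must be nonempty")
        if any(L <= 0 for L in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        for name in ("n_genes", "n_target_genes", "n_animals_per_stratum",
                     "gene_length_bp", "n_expression_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes cannot exceed n_genes")
        for name in ("alpha_true", "noncall_fraction", "control_fraction",
                     "not_expressed_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(not 0 <= p <= 1 for p in self.penetrance_truth.values()):
            raise ValueError("planted penetrance probabilities must be in [0, 1]")
        if self.cluster_span_bp < 1:
            raise ValueError("cluster_span_bp must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def rng(self, op: int) -> np.random.Generator:
        """Deterministic per-operation random sub-stream."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(op,)))


@dataclass
class GroundTruth:
    """Planted structure, for downstream recovery testing."""

    significant_genes: set[str] = field(default_factory=set)
    dimorphic_genes: set[str] = field(default_factory=set)
    sex_category: dict[str, str] = field(default_factory=dict)
    life_stage: dict[str, str] = field(default_factory=dict)
    zygosities: dict[str, list[str]] = field(default_factory=dict)
    stratum_penetrance: dict[str, float] = field(default_factory=dict)
    spatially_clustered_genes: set[str] = field(default_factory=set)
    expression_cluster_assignment: dict[str, int] = field(default_factory=dict)
    maturation_pattern_assignment: dict[str, int] = field(default_factory=dict)
    de_stage_genes: set[str] = field(default_factory=set)
    de_maturation_genes: set[str] = field(default_factory=set)
    not_expressed_genes: set[str] = field(default_factory=set)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for f in dataclasses.fields(GroundTruth):
            a, b = getattr(self, f.name), getattr(other, f.name)
            merged = {**a, **b} if isinstance(a, dict) else a | b
            setattr(out, f.name, merged)
        return out

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, set):
                return sorted(v)
            return v

        return json.dumps(
            {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(GroundTruth)},
            indent=2,
        )


def _symbol(i: int) -> str:
    return f"Gene{i:05d}"


def simulate_annotation(cfg: SimConfig) -> list[GeneLocus]:
    """Gene loci with unique symbols, chromosome chosen proportional to
    length and start uniform along the chromosome."""
    rng = cfg.rng(_OP_ANNOTATION)
    names = list(cfg.chromosomes)
    lengths = np.array([cfg.chromosomes[c] for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=cfg.n_genes, p=lengths / lengths.sum())
    loci = []
    for i, ci in enumerate(chrom_idx):
        L = cfg.chromosomes[names[ci]]
        span = min(cfg.gene_length_bp, L)
        start = int(rng.integers(1, max(L - span, 1) + 1))
        loci.append(GeneLocus(_symbol(i), names[ci], start, start + span - 1))
    return loci


def plant_clustered_targets(
    loci: list[GeneLocus], cfg: SimConfig
) -> tuple[list[GeneLocus], set[str], GroundTruth]:
    """Choose a target gene set and plant spatial clusters within it.

    Returns (updated loci, target symbols, ground truth).  Cluster members
    are relocated so that each planted group lies within `cluster_span_bp`
    of its anchor (hence of one another); the remaining targets and all
    non-target loci keep their original uniform coordinates.
    """
    n_clustered = cfg.n_planted_spatial_clusters * cfg.genes_per_cluster
    if n_clustered > cfg.n_target_genes:
        raise ValueError("planted clusters require more genes than n_target_genes")
    rng = cfg.rng(_OP_TARGETS)
    order = rng.permutation(len(loci))
    target_idx = order[: cfg.n_target_genes]
    targets = {loci[i].symbol for i in target_idx}

    new_loci = list(loci)
    clustered: set[str] = set()
    for c in range(cfg.n_planted_spatial_clusters):
        members = target_idx[c * cfg.genes_per_cluster : (c + 1) * cfg.genes_per_cluster]
        anchor = new_loci[members[0]]
        L = cfg.chromosomes[anchor.chromosome]
        base = min(anchor.start, max(L - cfg.cluster_span_bp - cfg.gene_length_bp, 1))
        offsets = rng.integers(0, cfg.cluster_span_bp + 1, size=len(members))
        offsets[0] = 0
        for m, off in zip(members, offsets):
            start = int(base + off)
            end = start + cfg.gene_length_bp - 1
            new_loci[m] = GeneLocus(new_loci[m].symbol, anchor.chromosome, start, end)
            clustered.add(new_loci[m].symbol)
    truth = GroundTruth(spatially_clustered_genes=clustered)
    return new_loci, targets, truth


def _loguniform_p(rng: np.random.Generator, alpha: float, n: int = 1) -> np.ndarray:
    """Significant p-values: log-uniform on [1e-10, alpha) — strictly below
    threshold so boundary ambiguity cannot arise."""
    lo, hi = np.log10(1e-10), np.log10(alpha)
    return 10 ** rng.uniform(lo, hi, size=n)


def _null_p(rng: np.random.Generator, alpha: float, n: int = 1) -> np.ndarray:
    # uniform on [alpha, 1): never significant, by construction
    return rng.uniform(alpha, 1.0, size=n)


def simulate_stat_results(
    loci: list[GeneLocus],
    cfg: SimConfig,
    significant_genes: set[str] | None = None,
) -> tuple[list[StatResultRow], GroundTruth]:
    """Knockout statistical-results rows with planted significance structure.

    Each planted significant gene receives a sex category, life stage(s) and
    zygosity set drawn from the screen-like mixes; rows are emitted so that
    downstream classification recovers the planted categories exactly.  A
    matching number of background genes receive only non-significant rows.
    If `significant_genes` is given (e.g. the spatially planted target set)
    it is used instead of drawing a fresh set.
    """
    rng = cfg.rng(_OP_STATS)
    alpha = cfg.alpha_true
    symbols = [l.symbol for l in loci]
    chrom_of = {l.symbol: l.chromosome for l in loci}
    if significant_genes is None:
        sig = sorted(rng.permutation(symbols)[: cfg.n_target_genes].tolist())
    else:
        sig = sorted(significant_genes)

    cats, cat_w = zip(*[(c, w) for c, w in SEX_CATEGORY_WEIGHTS.items()])
    stages, stage_w = zip(*LIFE_STAGE_WEIGHTS.items())
    cat_p = np.array(cat_w) / sum(cat_w)
    stage_p = np.array(stage_w) / sum(stage_w)

    dimorphic = set(rng.permutation(sig)[: cfg.n_dimorphic_genes].tolist())
    truth = GroundTruth(significant_genes=set(sig), dimorphic_genes=dimorphic)
    rows: list[StatResultRow] = []

    def emit(gene, pid, zyg, male_p, female_p, main_p, inter_p, flag):
        rows.append(
            StatResultRow(
                gene_symbol=gene,
                parameter_id=pid,
                parameter_name=pid,
                procedure_code=pid.split("_")[1],
                zygosity=zyg,
                male_ko_p=male_p,
                female_ko_p=female_p,
                genotype_main_p=main_p,
                interaction_p=inter_p,
                significant_flag=flag,
            )
        )

    for gene in sig:
        cat = cats[rng.choice(len(cats), p=cat_p)]
        stage = stages[rng.choice(len(stages), p=stage_p)]
        if stage == "both":
            stage_list = ["embryo", "adult"]
        else:
            stage_list = [stage]
        zygs = ["homozygote"]
        if rng.random() < 0.2:
            zygs.append("heterozygote")
        if chrom_of[gene] == "X" and rng.random() < 0.05:
            zygs = ["hemizygote"]
        truth.sex_category[gene] = cat.value
        truth.life_stage[gene] = stage
        truth.zygosities[gene] = sorted(zygs)

        for st in stage_list:
            pool = EMBRYO_PARAMETER_IDS if st == "embryo" else ADULT_PARAMETER_IDS
            pid = pool[int(rng.integers(len(pool)))]
            for zyg in zygs:
                if cat is SexCategory.NOT_CONSIDERED:
                    male_p = female_p = None
                    main_p = float(_loguniform_p(rng, alpha)[0])
                else:
                    male_p = (
                        float(_loguniform_p(rng, alpha)[0])
                        if cat in (SexCategory.MALE_ONLY, SexCategory.BOTH)
                        else float(_null_p(rng, alpha)[0])
                    )
                    female_p = (
                        float(_loguniform_p(rng, alpha)[0])
                        if cat in (SexCategory.FEMALE_ONLY, SexCategory.BOTH)
                        else float(_null_p(rng, alpha)[0])
                    )
                    main_p = float(_null_p(rng, alpha)[0])
                inter_p = (
                    float(_loguniform_p(rng, alpha)[0])
                    if gene in dimorphic
                    else float(_null_p(rng, alpha)[0])
                )
                emit(gene, pid, zyg, male_p, female_p, main_p, inter_p, True)

    # background: non-significant rows for a sample of the remaining genes
    background = [s for s in symbols if s not in truth.significant_genes]
    n_bg = min(len(background), cfg.n_target_genes)
    for gene in rng.permutation(background)[:n_bg]:
        pid = ADULT_PARAMETER_IDS[int(rng.integers(len(ADULT_PARAMETER_IDS)))]
        male_p, female_p, main_p, inter_p = _null_p(rng, alpha, 4)
        emit(gene, pid, "homozygote", float(male_p), float(female_p),
             float(main_p), float(inter_p), False)
    return rows, truth


def simulate_observations(cfg: SimConfig) -> tuple[list[ObservationRecord], GroundTruth]:
    """Per-animal categorical calls with planted per-stratum penetrance.

    For every entry of `penetrance_truth` (gene symbol -> probability) the
    generator emits `n_animals_per_stratum` experimental records per sex
    ("abnormal" with the planted probability, else "normal"), a configurable
    fraction of extra "imageOnly" non-call records, and control-group
    records — the latter two exercising the exclusion rules downstream.
    """
    if not cfg.penetrance_truth:
        raise ValueError("penetrance_truth must be nonempty")
    rng = cfg.rng(_OP_OBS)
    records: list[ObservationRecord] = []
    pid = "IMPC_XRY_019_001"
    counter = 0

    def make(gene, group, category, sex):
        nonlocal counter
        counter += 1
        return ObservationRecord(
            animal_id=f"A{counter:06d}",
            gene_symbol=gene,
            parameter_id=pid,
            sample_group=group,
            category=category,
            sex=sex,
            zygosity="homozygote",
            life_stage="adult",
        )

    for gene, p in cfg.penetrance_truth.items():
        for sex in ("male", "female"):
            abnormal = rng.random(cfg.n_animals_per_stratum) < p
            for ab in abnormal:
                records.append(make(gene, "experimental", "abnormal" if ab else "normal", sex))
            n_noncall = int(round(cfg.noncall_fraction * cfg.n_animals_per_stratum))
            for _ in range(n_noncall):
                records.append(make(gene, "experimental", "imageOnly", sex))
            n_control = int(round(cfg.control_fraction * cfg.n_animals_per_stratum))
            for _ in range(n_control):
                cat = "abnormal" if rng.random() < 0.02 else "normal"
                records.append(make(gene, "control", cat, sex))
    truth = GroundTruth(stratum_penetrance=dict(cfg.penetrance_truth))
    return records, truth


#: Canonical stage-profile shapes (indexed over the six stages) used to plant
#: expression clusters; pairwise distinct after per-gene standardization.
STAGE_PROFILE_SHAPES = np.array(
    [
        [0, 1, 2, 3, 4, 5],   # monotone up
        [5, 4, 3, 2, 1, 0],   # monotone down
        [0, 4, 5, 4, 1, 0],   # mid peak
        [5, 1, 0, 1, 4, 5],   # mid valley
        [0, 5, 5, 0, 0, 0],   # early transient
        [0, 0, 0, 5, 5, 0],   # late transient
        [0, 0, 5, 5, 5, 5],   # step up
        [5, 5, 5, 0, 0, 0],   # step down
    ],
    dtype=float,
)

#: Maturation-pattern shapes over somite levels SI/SII/SIII.
MATURATION_SHAPES = np.array(
    [
        [2.0, 1.0, 0.0],  # highest in the newest somite, decreasing
        [0.0, 1.0, 2.0],  # increasing with maturation
        [0.0, 2.0, 0.0],  # transient in SII
    ]
)


def simulate_expression(
    cfg: SimConfig, genes: list[str] | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Somite expression matrix with planted DE structure.

    Samples are somite levels SI/SII/SIII at the six developmental stages,
    replicated.  Genes fall into four planted classes: stage-DE (one of
    `expression_cluster_count` canonical stage profiles), maturation-DE (one
    of three level patterns), flat expressed background, and not-expressed
    (values far below the expressed threshold).  Gaussian noise with
    `noise_sd` is added throughout.
    """
    if cfg.expression_cluster_count > len(STAGE_PROFILE_SHAPES):
        raise ValueError(
            f"expression_cluster_count must be <= {len(STAGE_PROFILE_SHAPES)}"
        )
    rng = cfg.rng(_OP_EXPR)
    if genes is None:
        genes = [_symbol(i) for i in range(cfg.n_genes)]
    n = len(genes)

    samples, stage_of, level_of = [], [], []
    for stage in STAGES:
        for level in SOMITE_LEVELS:
            for rep in range(1, cfg.n_expression_replicates + 1):
                samples.append(f"s{stage}_{level}_r{rep}")
                stage_of.append(stage)
                level_of.append(level)
    meta = pd.DataFrame(
        {"stage": stage_of, "somite_level": level_of},
        index=pd.Index(samples, name="sample"),
    )

    order = rng.permutation(n)
    n_not_expr = int(round(cfg.not_expressed_fraction * n))
    k = cfg.expression_cluster_count
    n_stage_de = min(max(10 * k, k), n - n_not_expr)
    n_mat_de = min(30, n - n_not_expr - n_stage_de)
    not_expr_idx = order[:n_not_expr]
    stage_idx = order[n_not_expr : n_not_expr + n_stage_de]
    mat_idx = order[n_not_expr + n_stage_de : n_not_expr + n_stage_de + n_mat_de]

    truth = GroundTruth()
    truth.not_expressed_genes = {genes[i] for i in not_expr_idx}

    baseline = rng.normal(5.0, 1.0, size=n)
    amplitude = 2.0
    values = np.tile(baseline[:, None], (1, len(samples)))
    values[not_expr_idx, :] = -4.0

    stage_arr = np.array(stage_of)
    level_arr = np.array(level_of)
    stage_pos = {s: i for i, s in enumerate(STAGES)}
    level_pos = {l: i for i, l in enumerate(SOMITE_LEVELS)}

    def zshape(v):
        return (v - v.mean()) / v.std()

    for j, gi in enumerate(stage_idx):
        cl = j % k
        shape = zshape(STAGE_PROFILE_SHAPES[cl])
        values[gi, :] += amplitude * shape[[stage_pos[s] for s in stage_arr]]
        truth.expression_cluster_assignment[genes[gi]] = cl + 1
        truth.de_stage_genes.add(genes[gi])
    for j, gi in enumerate(mat_idx):
        pat = j % len(MATURATION_SHAPES)
        shape = zshape(MATURATION_SHAPES[pat])
        values[gi, :] += amplitude * shape[[level_pos[l] for l in level_arr]]
        truth.maturation_pattern_assignment[genes[gi]] = pat + 1
        truth.de_maturation_genes.add(genes[gi])

    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_symbol"),
                            columns=samples),
        sample_meta=meta,
    )
    return matrix, truth


# -- full simulation and file export ------------------------------------------

def simulate_all(cfg: SimConfig) -> dict:
    """Run the whole generator; returns all artefacts plus merged truth."""
    loci = simulate_annotation(cfg)
    loci, targets, t1 = plant_clustered_targets(loci, cfg)
    stat_rows, t2 = simulate_stat_results(loci, cfg, significant_genes=targets)
    observations, t3 = simulate_observations(cfg)
    matrix, t4 = simulate_expression(cfg, genes=[l.symbol for l in loci])
    truth = t1.merge(t2).merge(t3).merge(t4)
    return {
        "loci": loci,
        "targets": targets,
        "stat_rows": stat_rows,
        "observations": observations,
        "expression": matrix,
        "truth": truth,
    }


def write_outputs(sim: dict, outdir: str | Path) -> dict[str, Path]:
    """Write all simulated inputs as plain-text files.

    Annotation goes out both as TSV (1-based inclusive) and 4-column BED
    (0-based half-open); ground truth as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    loci = sim["loci"]
    ann = pd.DataFrame(
        {
            "symbol": [l.symbol for l in loci],
            "chromosome": [l.chromosome for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
        }
    )
    paths["annotation_tsv"] = outdir / "annotation.tsv"
    ann.to_csv(paths["annotation_tsv"], sep="\t", index=False)
    paths["annotation_bed"] = outdir / "annotation.bed"
    bed = pd.DataFrame(
        {
            "chrom": ann["chromosome"],
            "start": ann["start"] - 1,
            "end": ann["end"],
            "name": ann["symbol"],
        }
    )
    bed.to_csv(paths["annotation_bed"], sep="\t", index=False, header=False)

    paths["targets"] = outdir / "targets.txt"
    paths["targets"].write_text("\n".join(sorted(sim["targets"])) + "\n")

    rows = sim["stat_rows"]
    stats = pd.DataFrame(
        {
            "gene_symbol": [r.gene_symbol for r in rows],
            "parameter_id": [r.parameter_id for r in rows],
            "parameter_name": [r.parameter_name for r in rows],
            "procedure_code": [r.procedure_code for r in rows],
            "zygosity": [r.zygosity for r in rows],
            "male_ko_p": [r.male_ko_p for r in rows],
            "female_ko_p": [r.female_ko_p for r in rows],
            "genotype_main_p": [r.genotype_main_p for r in rows],
            "interaction_p": [r.interaction_p for r in rows],
            "significant_flag": [r.significant_flag for r in rows],
        }
    )
    paths["stat_results"] = outdir / "stat_results.tsv"
    stats.to_csv(paths["stat_results"], sep="\t", index=False)

    obs = sim["observations"]
    odf = pd.DataFrame(
        {
            "animal_id": [o.animal_id for o in obs],
            "gene_symbol": [o.gene_symbol for o in obs],
            "parameter_id": [o.parameter_id for o in obs],
            "sample_group": [o.sample_group for o in obs],
            "category": [o.category for o in obs],
            "sex": [o.sex for o in obs],
            "zygosity": [o.zygosity for o in obs],
            "life_stage": [o.life_stage for o in obs],
        }
    )
    paths["observations"] = outdir / "observations.tsv"
    odf.to_csv(paths["observations"], sep="\t", index=False)

    matrix = sim["expression"]
    paths["expression"] = outdir / "expression.tsv"
    matrix.values.to_csv(paths["expression"], sep="\t")
    paths["expression_meta"] = outdir / "expression_samples.tsv"
    matrix.sample_meta.to_csv(paths["expression_meta"], sep="\t")

    truth = sim["truth"]
    paths["de_stage"] = outdir / "de_stage.txt"
    paths["de_stage"].write_text("\n".join(sorted(truth.de_stage_genes)) + "\n")
    paths["de_maturation"] = outdir / "de_maturation.txt"
    paths["de_maturation"].write_text("\n".join(sorted(truth.de_maturation_genes)) + "\n")
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(truth.to_json())
    return paths
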