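"""Somite expression cross-referencing for candidate genes.

Candidate genes are checked against a somite RNA-seq expression matrix:
samples are dissected somite trios (levels SI/SII/SIII, the three most
recently formed somites) at six developmental stages (8, 18, 21, 25, 27 and
35 somites).  The module calls genes expressed/not expressed, places them
relative to the genome-wide median expression level, cross-references them
against externally supplied differential-expression (DE) gene lists
(maturation = between somite levels; stage = between developmental stages),
and clusters the stage-DE genes' standardized stage profiles into k groups
(hierarchical clustering, correlation distance, average linkage; k = 8 for
stage dynamics, 3 for maturation patterns by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

STAGES = (8, 18, 21, 25, 27, 35)
SOMITE_LEVELS = ("SI", "SII", "SIII")
DEFAULT_K_STAGE = 8
DEFAULT_K_MATURATION = 3


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized (log-scale) expression.

    `sample_meta` is indexed like the matrix columns and carries `stage`
    (int) and `somite_level` (SI/SII/SIII) per sample.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("stage", "somite_level"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata missing column {col!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def stage_profiles(self) -> pd.DataFrame:
        """Per-gene mean expression within each stage (averaged over somite
        levels and replicates), columns ordered by stage."""
        stages = self.sample_meta.loc[self.values.columns, "stage"]
        prof = self.values.T.groupby(stages.values).mean().T
        return prof[sorted(prof.columns)]

    def level_profiles(self) -> pd.DataFrame:
        """Per-gene mean expression per somite maturation level SI/SII/SIII."""
        levels = self.sample_meta.loc[self.values.columns, "somite_level"]
        prof = self.values.T.groupby(levels.values).mean().T
        order = [l for l in SOMITE_LEVELS if l in prof.columns]
        return prof[order]


def call_expressed(
    matrix: ExpressionMatrix, genes, threshold: float = 0.0
) -> pd.DataFrame:
    """Expressed/not-expressed call per candidate gene.

    A gene is expressed when its mean expression across all samples exceeds
    `threshold` (strict >, on the matrix's log scale).  Genes absent from
    the matrix are reported not expressed with `absent=True`.
    """
    means = matrix.values.mean(axis=1)
    rows = []
    for g in genes:
        if g in means.index:
            m = float(means.loc[g])
            rows.append({"gene_symbol": g, "expressed": m > threshold,
                         "mean_expression": m, "absent": False})
        else:
            rows.append({"gene_symbol": g, "expressed": False,
                         "mean_expression": np.nan, "absent": True})
    return pd.DataFrame(rows).set_index("gene_symbol")


def fraction_above_median(matrix: ExpressionMatrix, genes) -> float:
    """Fraction of a gene subset expressed above the genome-wide median.

    The reference median is taken over the per-gene mean expression of ALL
    genes in the matrix; genes absent from the matrix are ignored.
    """
    genes = [g for g in genes if g in matrix.genes]
    if not genes:
        raise ValueError("no subset genes present in the matrix")
    means = matrix.values.mean(axis=1)
    global_median = float(means.median())
    return float((means.loc[genes] > global_median).mean())


def crossref_de(genes, de_maturation, de_stage) -> tuple[pd.DataFrame, dict]:
    """Flag candidate genes found in the maturation-DE and stage-DE lists.

    Returns per-gene boolean flags and summary counts; by inclusion-
    exclusion, n_either = n_maturation + n_stage - n_both over the candidate
    set.
    """
    de_maturation, de_stage = set(de_maturation), set(de_stage)
    df = pd.DataFrame(
        {
            "gene_symbol": list(genes),
            "de_maturation": [g in de_maturation for g in genes],
            "de_stage": [g in de_stage for g in genes],
        }
    ).set_index("gene_symbol")
    df["de_either"] = df["de_maturation"] | df["de_stage"]
    counts = {
        "n_maturation": int(df["de_maturation"].sum()),
        "n_stage": int(df["de_stage"].sum()),
        "n_both": int((df["de_maturation"] & df["de_stage"]).sum()),
        "n_either": int(df["de_either"].sum()),
    }
    return df, counts


def _standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize each gene's profile; flat profiles map to all-zeros."""
    centred = profiles.sub(profiles.mean(axis=1), axis=0)
    sd = profiles.std(axis=1, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return centred.div(sd, axis=0)


def cluster_dynamics(
    matrix: ExpressionMatrix,
    de_genes,
    k: int = DEFAULT_K_STAGE,
    axis: str = "stage",
    method: str = "average",
    metric: str = "correlation",
) -> pd.Series:
    """Cluster DE genes' expression dynamics into k groups.

    Profiles are per-gene stage means (axis="stage") or somite-level means
    (axis="maturation"), z-standardized per gene, then hierarchically
    clustered (default correlation distance, average linkage) and cut at k.
    Deterministic: no random initialization is involved.  Returns a Series
    of integer cluster ids (1..k) indexed by gene.
    """
    de_genes = list(de_genes)
    missing = sorted(set(de_genes) - set(matrix.genes))
    if missing:
        raise ValueError(f"DE genes absent from matrix: {missing}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(de_genes):
        raise ValueError(f"k={k} exceeds number of DE genes ({len(de_genes)})")
    profiles = (
        matrix.stage_profiles() if axis == "stage" else matrix.level_profiles()
    )
    if axis not in {"stage", "maturation"}:
        raise ValueError(f"unknown clustering axis {axis!r}")
    X = _standardize(profiles.loc[de_genes]).to_numpy()
    # correlation distance is undefined for constant rows; standardized flat
    # profiles are all-zero, nudge them to a tiny constant-free vector
    if metric == "correlation":
        flat = np.all(X == X[:, :1], axis=1)
        if flat.any():
            X = X.copy()
            X[flat, 0] += 1e-9
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=pd.Index(de_genes, name="gene_symbol"), name="cluster")


def cluster_profiles(
    matrix: ExpressionMatrix, assignments: pd.Series, axis: str = "stage"
) -> pd.DataFrame:
    """Mean standardized profile per cluster (cluster x stage/level table)."""
    profiles = (
        matrix.stage_profiles() if axis == "stage" else matrix.level_profiles()
    )
    std = _standardize(profiles.loc[assignments.index])
    return std.groupby(assignments).mean()


def annotate(
    matrix: ExpressionMatrix,
    genes,
    de_maturation,
    de_stage,
    k_stage: int = DEFAULT_K_STAGE,
    k_maturation: int = DEFAULT_K_MATURATION,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Full per-candidate-gene annotation table.

    Combines expressed calls, position relative to the genome-wide median,
    DE flags, and cluster ids for the DE genes.  DE flags are only honoured
    for expressed genes; cluster ids are assigned only to stage-DE
    (resp. maturation-DE) genes, and only when enough such genes exist for
    the requested k.
    """
    genes = list(genes)
    expr = call_expressed(matrix, genes, threshold)
    means = matrix.values.mean(axis=1)
    global_median = float(means.median())
    expr["above_global_median"] = [
        (not a) and float(means.loc[g]) > global_median
        for g, a in zip(expr.index, expr["absent"])
    ]
    de, _ = crossref_de(genes, de_maturation, de_stage)
    out = expr.join(de)
    out["de_maturation"] &= out["expressed"]
    out["de_stage"] &= out["expressed"]
    out["de_either"] = out["de_maturation"] | out["de_stage"]

    out["stage_cluster"] = pd.array([None] * len(out), dtype="Int64")
    out["maturation_pattern"] = pd.array([None] * len(out), dtype="Int64")
    stage_genes = [g for g in genes if out.loc[g, "de_stage"]]
    if len(stage_genes) >= k_stage:
        cl = cluster_dynamics(matrix, stage_genes, k=k_stage, axis="stage")
        out.loc[cl.index, "stage_cluster"] = cl.values
    mat_genes = [g for g in genes if out.loc[g, "de_maturation"]]
    if len(mat_genes) >= k_maturation:
        cl = cluster_dynamics(matrix, mat_genes, k=k_maturation, axis="maturation")
        out.loc[cl.index, "maturation_pattern"] = cl.values
    return out


# -- I/O ----------------------------------------------------------------------

def read_matrix(values_path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV (genes x samples, first column = gene id) plus
    a sample-metadata sidecar TSV (sample, stage, somite_level)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, sample_meta=meta)
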