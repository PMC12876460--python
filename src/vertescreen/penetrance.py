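"""Phenotype penetrance from per-animal categorical calls.

Penetrance of a knockout phenotype is the fraction of mutant animals in a
stratum scored "abnormal" among those scored "abnormal" or "normal".  Only
experimental (mutant) animals with a definitive call enter the denominator;
"imageOnly" and other non-call categories are excluded.  Strata are gene x
parameter x life stage x zygosity, optionally further split by sex; exact
95% binomial (Clopper-Pearson) intervals accompany every estimate, and
strata with fewer than `min_n` callable animals (default 3) are excluded
from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_N = 3
DEFAULT_CONF = 0.95
HIGH_PENETRANCE_THRESHOLDS = (0.5, 0.8)

#: Stratum granularities: field tuples used as group-by keys.
GRANULARITIES = {
    "per_sex": ("gene_symbol", "parameter_id", "life_stage", "zygosity", "sex"),
    "pooled": ("gene_symbol", "parameter_id", "life_stage", "zygosity"),
}


@dataclass(frozen=True)
class ObservationRecord:
    """One animal-level categorical observation."""

    animal_id: str
    gene_symbol: str
    parameter_id: str
    sample_group: str  # experimental | control
    category: str  # abnormal | normal | imageOnly | ...
    sex: str = "unknown"
    zygosity: str = "homozygote"
    life_stage: str = "adult"
    observation_type: str = "categorical"

    def __post_init__(self):
        if not self.category:
            raise ValueError("category must be nonempty")


def _norm_category(category: str) -> str:
    return category.strip().lower()


def filter_callable(records: list[ObservationRecord]) -> list[ObservationRecord]:
    """Keep only experimental animals with a definitive abnormal/normal call.

    Category matching is case-insensitive and whitespace-trimmed; anything
    that is not exactly "abnormal" or "normal" after normalization (e.g.
    "imageOnly") is a non-call and is dropped, as are control animals.
    """
    return [
        r
        for r in records
        if r.sample_group.strip().lower() == "experimental"
        and _norm_category(r.category) in {"abnormal", "normal"}
    ]


def aggregate(records: list[ObservationRecord], granularity: str = "pooled") -> pd.DataFrame:
    """Count abnormal/normal per stratum.

    `granularity` is "per_sex" or "pooled"; pooled counts are by construction
    the sums of the per-sex counts within the coarser stratum.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(
            f"unknown granularity {granularity!r}; expected one of {sorted(GRANULARITIES)}"
        )
    keys = GRANULARITIES[granularity]
    if not records:
        return pd.DataFrame(columns=[*keys, "n_abnormal", "n_normal"])
    df = pd.DataFrame(
        {
            **{k: [getattr(r, k) for r in records] for k in keys},
            "abnormal": [_norm_category(r.category) == "abnormal" for r in records],
        }
    )
    counts = (
        df.groupby(list(keys), sort=True)["abnormal"]
        .agg(n_abnormal="sum", n_total="count")
        .reset_index()
    )
    counts["n_normal"] = counts["n_total"] - counts["n_abnormal"]
    return counts.drop(columns="n_total")


def clopper_pearson(x: int, n: int, conf: float = DEFAULT_CONF) -> tuple[float, float]:
    """Exact binomial confidence interval by inverting the binomial tails.

    Bounds are the Beta-distribution quantiles Beta(x, n-x+1) and
    Beta(x+1, n-x) at (1-conf)/2 and 1-(1-conf)/2, with the conventional
    closures low=0 at x=0 and high=1 at x=n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not (0 < conf < 1):
        raise ValueError("conf must be in (0, 1)")
    tail = (1.0 - conf) / 2.0
    low = 0.0 if x == 0 else float(stats.beta.ppf(tail, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1.0 - tail, x + 1, n - x))
    return low, high


def estimate(
    records: list[ObservationRecord],
    granularity: str = "pooled",
    min_n: int = DEFAULT_MIN_N,
    conf: float = DEFAULT_CONF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Penetrance estimates per stratum with exact intervals.

    Returns (estimates, excluded): strata with at least `min_n` callable
    animals, and those excluded by the minimum-N rule.  Columns follow the
    pen_low95/pen_high95 naming convention of the source exports.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts = aggregate(filter_callable(records), granularity)
    if counts.empty:
        return counts.assign(penetrance=[], pen_low95=[], pen_high95=[]), counts
    n = counts["n_abnormal"] + counts["n_normal"]
    counts = counts.assign(penetrance=counts["n_abnormal"] / n)
    bounds = [
        clopper_pearson(int(x), int(tot), conf)
        for x, tot in zip(counts["n_abnormal"], n)
    ]
    counts["pen_low95"] = [b[0] for b in bounds]
    counts["pen_high95"] = [b[1] for b in bounds]
    keep = n >= min_n
    return counts[keep].reset_index(drop=True), counts[~keep].reset_index(drop=True)


def summarize(
    estimates: pd.DataFrame,
    thresholds: tuple[float, float] = HIGH_PENETRANCE_THRESHOLDS,
) -> dict:
    """Overall and per-parameter penetrance summaries.

    Median and IQR (Q3 - Q1) over all stratum estimates, counts of strata at
    or above each high-penetrance threshold (inclusive), and per-parameter
    median penetrance.
    """
    if estimates.empty:
        raise ValueError("summarize requires at least one penetrance estimate")
    pen = estimates["penetrance"].to_numpy()
    q1, med, q3 = np.percentile(pen, [25, 50, 75])
    per_param = (
        estimates.groupby("parameter_id")["penetrance"].median().sort_values(ascending=False)
    )
    return {
        "n_estimates": int(len(pen)),
        "n_genes": int(estimates["gene_symbol"].nunique()),
        "median": float(med),
        "iqr": float(q3 - q1),
        "n_at_or_above": {thr: int((pen >= thr).sum()) for thr in thresholds},
        "per_parameter_median": per_param.to_dict(),
    }


# -- tabular I/O --------------------------------------------------------------

OBS_COLUMNS = [
    "animal_id",
    "gene_symbol",
    "parameter_id",
    "sample_group",
    "category",
    "sex",
    "zygosity",
    "life_stage",
    "observation_type",
]


def records_from_frame(
    df: pd.DataFrame, column_map: dict[str, str] | None = None
) -> list[ObservationRecord]:
    if column_map:
        df = df.rename(columns=column_map)
    missing = [
        c
        for c in ("animal_id", "gene_symbol", "parameter_id", "sample_group", "category")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    defaults = {"sex": "unknown", "zygosity": "homozygote", "life_stage": "adult",
                "observation_type": "categorical"}
    out = []
    for rec in df.to_dict("records"):
        kwargs = {c: str(rec[c]) for c in ("animal_id", "gene_symbol", "parameter_id",
                                           "sample_group", "category")}
        for c, dflt in defaults.items():
            kwargs[c] = str(rec.get(c, dflt))
        out.append(ObservationRecord(**kwargs))
    return out


def read_observations(path, column_map: dict[str, str] | None = None) -> list[ObservationRecord]:
    path = str(path)
    if path.endswith(".jsonl"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path, sep="," if path.endswith(".csv") else "\t")
    return records_from_frame(df, column_map)
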