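"""Family-level conservation summaries and hypergeometric enrichment.

For one query/target species pair, every TE instance carries four flags:
expressed in the query, lifted to the target, TE-annotated at the lifted
locus, and expressed in the target. Per family these aggregate into the
counts behind a conservation-of-expression table: total instances i
expressed in the query, j of them with an ortholog that is also expressed,
and the proportion j/i. The hypergeometric survival function P(X >= j)
asks whether expression in the two species is associated among the family's
conserved instances: population N = conserved instances, successes K =
conserved instances expressed in the target, draws n = conserved instances
expressed in the query. An alternative parameterization (population = all
instances, successes = conserved) is available behind a flag; the exact
parameterization behind published tables of this kind is typically not
printed, so p-values are comparable only within one choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import ValidationError
from .repeat_catalog import FamilyAge

logger = logging.getLogger(__name__)

#: Classes used in family-level tables (the main interspersed repeat classes).
MAIN_TE_CLASSES = frozenset({"DNA", "SINE", "LINE", "LTR"})
#: Classes always excluded (GC-bias-prone annotation artifacts, not TEs).
EXCLUDED_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


@dataclass(frozen=True)
class InstanceFlags:
    """Per-instance flags for one query/target species pair."""

    instance_id: str
    family: str
    te_class: str
    expressed_query: bool
    lifted: bool
    te_annotated_in_target: bool
    expressed_in_target: bool

    @property
    def conserved(self) -> bool:
        return self.lifted and self.te_annotated_in_target


@dataclass
class FamilySummary:
    """Counts feeding one family row of the conservation table."""

    family: str
    te_class: str
    total: int
    n_expressed_query: int
    n_conserved: int
    n_query_expressed_conserved: int
    n_target_expressed: int
    n_both_expressed: int
    proportion: float | None = None
    p_value: float | None = None

    def __post_init__(self):
        if self.proportion is None and self.n_expressed_query > 0:
            self.proportion = self.n_both_expressed / self.n_expressed_query


def summarize_family(records: Iterable[InstanceFlags]) -> FamilySummary:
    """Aggregate one family's per-instance flags into table counts.

    With zero query-expressed instances the proportion is undefined and
    reported as None.
    """
    records = list(records)
    if not records:
        raise ValidationError("summarize_family requires at least one record")
    families = {r.family for r in records}
    if len(families) != 1:
        raise ValidationError(f"records span several families: {sorted(families)}")
    conserved = [r for r in records if r.conserved]
    return FamilySummary(
        family=records[0].family,
        te_class=records[0].te_class,
        total=len(records),
        n_expressed_query=sum(r.expressed_query for r in records),
        n_conserved=len(conserved),
        n_query_expressed_conserved=sum(r.expressed_query for r in conserved),
        n_target_expressed=sum(r.expressed_in_target for r in conserved),
        n_both_expressed=sum(r.expressed_query and r.expressed_in_target for r in conserved),
    )


def summarize_families(records: Iterable[InstanceFlags]) -> list[FamilySummary]:
    by_family: dict[str, list[InstanceFlags]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r)
    return [summarize_family(v) for _, v in sorted(by_family.items())]


def hypergeom_sf(N: int, K: int, n: int, j: int) -> float:
    """P(X >= j) for X ~ Hypergeometric(N, K, n), summed in log space.

    N = population size, K = successes in the population, n = draws,
    j = observed successes. j <= 0 returns exactly 1.0; j > min(K, n)
    returns exactly 0.0.
    """
    if not 0 <= K <= N:
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValidationError(f"need 0 <= n <= N, got n={n}, N={N}")
    if j < 0:
        raise ValidationError(f"need j >= 0, got j={j}")
    if j == 0:
        return 1.0
    upper = min(K, n)
    if j > upper:
        return 0.0
    ks = np.arange(j, upper + 1)
    return float(np.exp(logsumexp(stats.hypergeom.logpmf(ks, N, K, n))))


@dataclass
class EnrichmentFilters:
    """Family filters for the conservation table.

    Small families and simple/low-complexity repeats are excluded: tiny
    families produce unstable significant p-values and simple repeats sit in
    GC-rich regions where detection is biased.
    """

    min_total: int = 100
    min_expressed_query: int = 30
    min_conserved: int = 10
    class_whitelist: frozenset[str] = MAIN_TE_CLASSES
    exclude_classes: frozenset[str] = EXCLUDED_CLASSES

    def __post_init__(self):
        for name in ("min_total", "min_expressed_query", "min_conserved"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def admits(self, s: FamilySummary) -> bool:
        return (
            s.te_class in self.class_whitelist
            and s.te_class not in self.exclude_classes
            and s.total >= self.min_total
            and s.n_expressed_query >= self.min_expressed_query
        )


def attach_p_value(summary: FamilySummary, population: str = "conserved") -> float:
    """Compute and store the enrichment p-value for one family.

    ``population='conserved'`` (default): N = conserved instances,
    K = target-expressed among conserved, n = query-expressed among
    conserved, j = both-expressed. ``population='all'``: N = all instances,
    K = conserved, n = query-expressed, j = query-expressed-and-conserved.
    """
    if population == "conserved":
        p = hypergeom_sf(
            summary.n_conserved,
            summary.n_target_expressed,
            summary.n_query_expressed_conserved,
            summary.n_both_expressed,
        )
    elif population == "all":
        p = hypergeom_sf(
            summary.total,
            summary.n_conserved,
            summary.n_expressed_query,
            summary.n_query_expressed_conserved,
        )
    else:
        raise ValidationError(f"unknown population {population!r}")
    summary.p_value = p
    return p


def family_enrichment_table(
    summaries: Iterable[FamilySummary],
    filters: EnrichmentFilters | None = None,
    population: str = "conserved",
    bh_column: bool = False,
) -> pd.DataFrame:
    """Filtered, sorted conservation-of-expression table for one species pair.

    Sorted by proportion descending; ties broken by p-value ascending then
    family name. Raw p-values are reported; ``bh_column`` adds a
    Benjamini-Hochberg adjusted column.
    """
    filters = filters or EnrichmentFilters()
    kept = [s for s in summaries if filters.admits(s)]
    for s in kept:
        attach_p_value(s, population=population)
    rows = [
        {
            "family": s.family,
            "te_class": s.te_class,
            "total": s.total,
            "query_expressed": s.n_expressed_query,
            "conserved": s.n_conserved,
            "target_expressed": s.n_both_expressed,
            "proportion": s.proportion,
            "p_value": s.p_value,
        }
        for s in kept
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "family",
            "te_class",
            "total",
            "query_expressed",
            "conserved",
            "target_expressed",
            "proportion",
            "p_value",
        ],
    )
    if df.empty:
        return df
    df = df.sort_values(
        ["proportion", "p_value", "family"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if bh_column:
        df["p_bh"] = stats.false_discovery_control(df["p_value"].to_numpy())
    return df


def format_enrichment_table(df: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy with the proportion rounded to 2 decimals."""
    out = df.copy()
    out["proportion"] = out["proportion"].round(2)
    return out


def combined_conservation(
    summaries_by_target: Mapping[str, Sequence[FamilySummary]],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Sum each family's both-expressed count across all target species.

    A family missing from one target contributes 0 there (logged). The table
    is sorted by the summed count descending; ``top_k`` truncates it.
    """
    targets = list(summaries_by_target)
    families: dict[str, dict[str, int]] = {}
    classes: dict[str, str] = {}
    for target, summaries in summaries_by_target.items():
        for s in summaries:
            families.setdefault(s.family, {})[target] = s.n_both_expressed
            classes[s.family] = s.te_class
    rows = []
    for family, per_target in sorted(families.items()):
        missing = [t for t in targets if t not in per_target]
        if missing:
            logger.info("family %s missing from %s; counted as 0", family, missing)
        rows.append(
            {
                "family": family,
                "te_class": classes[family],
                **{t: per_target.get(t, 0) for t in targets},
                "combined_both_expressed": sum(per_target.values()),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["combined_both_expressed", "family"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df


def age_vs_conservation(
    ages: Iterable[FamilyAge],
    summaries: Iterable[FamilySummary],
    min_expressed_query: int = 30,
) -> pd.DataFrame:
    """Per-family (mean similarity score, conserved fraction) table.

    Conserved fraction = conserved / total instances. Families below the
    expressed-instance threshold or with zero instances are excluded. No
    trend is fitted; the table is the deliverable.
    """
    age_by_family = {a.family: a for a in ages}
    rows = []
    for s in summaries:
        if s.total == 0 or s.n_expressed_query < min_expressed_query:
            continue
        age = age_by_family.get(s.family)
        if age is None:
            continue
        rows.append(
            {
                "family": s.family,
                "te_class": s.te_class,
                "mean_scaled_score": age.mean_scaled_score,
                "total": s.total,
                "conserved_fraction": s.n_conserved / s.total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "te_class", "mean_scaled_score", "total", "conserved_fraction"],
    ).sort_values("mean_scaled_score").reset_index(drop=True)


def randomized_null_pit(
    summaries: Iterable[FamilySummary],
    rng: np.random.Generator,
    population: str = "conserved",
) -> np.ndarray:
    """Randomized probability-integral transform of family p-values.

    The hypergeometric statistic is discrete, so raw survival-function
    p-values are uniform only on their attainable levels; a direct KS test
    against Uniform(0,1) would reject purely from discreteness. The standard
    remedy is the randomized PIT u = sf(j+1) + U * pmf(j), which is exactly
    Uniform(0,1) under the null hypothesis of independence for any degree of
    discreteness. Used to audit null calibration of the enrichment test.
    """
    us = []
    for s in summaries:
        if population == "conserved":
            N, K, n, j = (
                s.n_conserved,
                s.n_target_expressed,
                s.n_query_expressed_conserved,
                s.n_both_expressed,
            )
        elif population == "all":
            N, K, n, j = (
                s.total,
                s.n_conserved,
                s.n_expressed_query,
                s.n_query_expressed_conserved,
            )
        else:
            raise ValidationError(f"unknown population {population!r}")
        hi = hypergeom_sf(N, K, n, j)
        lo = hypergeom_sf(N, K, n, j + 1)
        us.append(lo + rng.random() * (hi - lo))
    return np.asarray(us)
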