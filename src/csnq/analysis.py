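"""Cohort-level scoring and descriptive statistics.

:func:`score_cohort` runs the full metric pipeline over a parsed roster —
one :class:`~csnq.records.MetricsRecord` row per child — pooling the
intensity composite across the cohort before the per-child proportions are
formed.

The statistical helpers mirror a descriptive analysis of such a cohort:
Spearman rank correlations with Benjamini-Hochberg FDR adjustment (network
variables are skewed and collinear, so rank statistics are the default), a
square-root(+0.5) transform for the small-count network size, an OLS
regression of transformed size on age, out-of-home childcare and their
interaction, and a Wilcoxon rank-sum comparison between childcare groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import composition, diversity, structure
from .io import assemble_network
from .records import (
    AlterRecord,
    EgoRecord,
    MetricsRecord,
    PROTOCOL_MUSEUM,
    RosterError,
)

__all__ = [
    "StatResult",
    "spearman_rho",
    "fdr_adjust",
    "sqrt_half_transform",
    "regression_age_childcare",
    "rank_sum_test",
    "score_network",
    "score_cohort",
    "correlation_table",
    "summary_table",
    "METRIC_COLUMNS",
]

#: Metric columns reported in the cohort summary and correlation tables.
METRIC_COLUMNS = [
    "network_size",
    "n_low_intensity",
    "n_high_intensity",
    "prop_high_intensity",
    "prop_kin",
    "prop_adult",
    "density",
    "n_components",
    "component_ratio",
    "racial_entropy",
    "racial_ei",
    "language_entropy",
    "linguistic_ei",
]


@dataclass
class StatResult:
    """One test result: named statistic, p-value, optional FDR-adjusted p,
    and the number of observations actually used."""

    statistic: str
    value: float
    p_value: float
    n: int
    adjusted_p: Optional[float] = None
    extra: dict = field(default_factory=dict)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x, y) -> StatResult:
    """Spearman rank correlation with average ranks for ties and a
    two-sided p; pairs with a missing value are dropped listwise."""
    xs, ys = _paired(x, y)
    if xs.size < 3:
        return StatResult("rho", float("nan"), float("nan"), int(xs.size))
    res = sps.spearmanr(xs, ys)
    return StatResult("rho", float(res.statistic), float(res.pvalue), int(xs.size))


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def sqrt_half_transform(x):
    """sqrt(x + 0.5), the standard variance-stabilizer for small counts."""
    return np.sqrt(np.asarray(x, dtype=float) + 0.5)


def regression_age_childcare(
    metrics: pd.DataFrame, response: str = "network_size"
) -> dict[str, StatResult]:
    """OLS of sqrt(response + 0.5) on age, childcare, and their interaction.

    Returns per-term coefficient results plus an "r_squared" entry carrying
    the model F test. Raises ValueError naming any constant predictor.
    """
    import statsmodels.api as sm

    df = metrics[[response, "age_months", "childcare_out_of_home"]].dropna()
    y = sqrt_half_transform(df[response].to_numpy())
    age = df["age_months"].to_numpy(dtype=float)
    care = df["childcare_out_of_home"].astype(bool).to_numpy(dtype=float)
    for name, col in (("age_months", age), ("childcare_out_of_home", care)):
        if np.unique(col).size < 2:
            raise ValueError(f"predictor {name!r} is constant")
    X = sm.add_constant(
        np.column_stack([age, care, age * care]), prepend=True, has_constant="add"
    )
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "age_months", "childcare", "age_x_childcare"]
    out = {
        name: StatResult("beta", float(fit.params[i]), float(fit.pvalues[i]), int(fit.nobs))
        for i, name in enumerate(names)
    }
    out["r_squared"] = StatResult(
        "R2",
        float(fit.rsquared),
        float(fit.f_pvalue),
        int(fit.nobs),
        extra={"f_statistic": float(fit.fvalue), "df_model": int(fit.df_model),
               "df_resid": int(fit.df_resid)},
    )
    return out


def _rank_sum_exact_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating which pooled ranks belong to group A:
    P(|U - n_a*n_b/2| >= |u_obs - n_a*n_b/2|) over all assignments."""
    n = pooled_ranks.size
    n_b = n - n_a
    mu = n_a * n_b / 2.0
    threshold = abs(u_obs - mu) - 1e-12
    offset = n_a * (n_a + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        u = pooled_ranks[list(idx)].sum() - offset
        if abs(u - mu) >= threshold:
            count += 1
        total += 1
    return count / total


def rank_sum_test(group_a, group_b, method: str = "auto") -> StatResult:
    """Two-sample Wilcoxon rank-sum test.

    The statistic W is the rank-sum form of the Mann-Whitney U for the
    first group (sum of group-A ranks minus n_a(n_a+1)/2). For combined
    n <= 20 (or ``method="exact"``) the two-sided p comes from exhaustive
    enumeration of rank assignments; larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    n = n_a + n_b
    if method == "exact" or (method == "auto" and n <= 20):
        p = _rank_sum_exact_p(ranks, n_a, w)
    else:
        mu = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return StatResult("W", w, float(p), int(n))


def score_network(
    ego: EgoRecord,
    alters: Sequence[AlterRecord],
    taxonomy: Optional[Mapping[str, bool]] = None,
    intensity_labels: Optional[Mapping[tuple[str, str], composition.IntensityScore]] = None,
    strict_kin: bool = False,
) -> MetricsRecord:
    """All metrics for one child's roster.

    Density is reported only when the roster's context data was collected
    under the museum protocol (or the protocol is unlabeled); the intensity
    proportions require pooled cohort labels passed in ``intensity_labels``.
    """
    net = assemble_network(ego, alters)
    n = net.network_size
    n_comp = net.n_components

    dens = structure.density(net.n_ties, n)
    if ego.protocol is not None and ego.protocol != PROTOCOL_MUSEUM:
        dens = None  # context question not administered under the lab protocol

    comp = composition.composition_proportions(
        net, taxonomy=taxonomy, intensity_labels=intensity_labels, strict=strict_kin
    )

    race_prof = diversity.racial_profile([a for a in net.alters])
    lang_prof = diversity.language_profile([a for a in net.alters])
    racial_entropy = None if race_prof is None else diversity.shannon_entropy(race_prof)
    language_entropy = (
        None if lang_prof is None else diversity.shannon_entropy(lang_prof)
    )

    zero_prop = None
    typology = None
    if dens is not None:  # component attribute patterns need context data
        _, zero_prop = diversity.component_entropy_profile(net, attribute="race")
        typ = diversity.classify_diversity_type(racial_entropy, zero_prop)
        typology = None if typ is None else typ.label

    return MetricsRecord(
        ego_id=ego.ego_id,
        network_size=n,
        n_components=n_comp,
        component_ratio=structure.component_ratio(n_comp, n),
        age_months=ego.age_months,
        childcare_out_of_home=ego.childcare_out_of_home,
        urbanicity=ego.urbanicity,
        n_high_intensity=comp["n_high_intensity"],
        n_low_intensity=comp["n_low_intensity"],
        prop_high_intensity=comp["prop_high_intensity"],
        prop_kin=comp["prop_kin"],
        prop_adult=comp["prop_adult"],
        density=dens,
        racial_entropy=racial_entropy,
        language_entropy=language_entropy,
        racial_ei=diversity.attribute_ei(ego, net.alters, "race"),
        linguistic_ei=diversity.attribute_ei(ego, net.alters, "language"),
        neighborhood_racial_entropy=(
            None
            if ego.neighborhood_race_profile is None
            else diversity.neighborhood_entropy(ego.neighborhood_race_profile)
        ),
        neighborhood_language_entropy=(
            None
            if ego.neighborhood_language_profile is None
            else diversity.neighborhood_entropy(ego.neighborhood_language_profile)
        ),
        zero_entropy_component_prop=zero_prop,
        diversity_type=typology,
    )


def score_cohort(
    egos: Sequence[EgoRecord],
    alters: Sequence[AlterRecord],
    taxonomy: Optional[Mapping[str, bool]] = None,
    strict_kin: bool = False,
) -> pd.DataFrame:
    """Score every ego roster; returns one metric row per child.

    The intensity composite is pooled over all person alters in the cohort
    with complete intensity data before the per-child high/low proportions
    are computed, so the labels are relative to the cohort median.
    """
    by_ego: dict[str, list[AlterRecord]] = {}
    for a in alters:
        by_ego.setdefault(a.ego_id, []).append(a)
    known = {e.ego_id for e in egos}
    orphans = sorted(set(by_ego) - known)
    if orphans:
        raise RosterError(f"alter rows reference unknown egos: {orphans}")

    pool = [a for a in alters if not a.is_group and a.has_intensity]
    labels = composition.score_intensity(pool) if len(pool) >= 2 else None

    rows = []
    for ego in egos:
        if ego.ego_id not in by_ego:
            raise RosterError(f"ego {ego.ego_id}: network has no alters")
        rec = score_network(
            ego,
            by_ego[ego.ego_id],
            taxonomy=taxonomy,
            intensity_labels=labels,
            strict_kin=strict_kin,
        )
        rows.append(rec.as_dict())
    df = pd.DataFrame(rows)
    return df.astype({c: float for c in METRIC_COLUMNS if c in df.columns})


def correlation_table(
    metrics: pd.DataFrame,
    anchors: Sequence[str] = ("network_size", "age_months"),
    variables: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Spearman correlations of each metric against each anchor, with one
    BH-FDR family over every emitted cell.

    Rows are variables, and for each anchor the table carries the rank
    correlation, raw and adjusted p, and the pairwise n (listwise deletion
    per pair, so metrics defined only for a subset — density, intensity —
    use the rows where they exist). An anchor against itself is reported as
    1 with no test.
    """
    if variables is None:
        variables = [c for c in METRIC_COLUMNS if c in metrics.columns]
        variables = list(dict.fromkeys(list(anchors) + variables))
    cells: list[tuple[str, str, StatResult]] = []
    for var in variables:
        for anchor in anchors:
            if var == anchor:
                res = StatResult("rho", 1.0, float("nan"), int(metrics[var].notna().sum()))
            else:
                res = spearman_rho(metrics[var], metrics[anchor])
            cells.append((var, anchor, res))
    adjusted = fdr_adjust([res.p_value for _, _, res in cells])
    for (_, _, res), adj in zip(cells, adjusted):
        res.adjusted_p = float(adj) if not np.isnan(adj) else None
    table = pd.DataFrame(index=pd.Index(variables, name="variable"))
    for anchor in anchors:
        for attr, suffix in (("value", "rho"), ("p_value", "p"), ("adjusted_p", "p_fdr"), ("n", "n")):
            table[f"{anchor}_{suffix}"] = [
                getattr(res, attr)
                for var in variables
                for v, a, res in cells
                if v == var and a == anchor
            ]
    return table


def summary_table(
    metrics: pd.DataFrame, variables: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Mean, SD (ddof=1), range and n per metric, missing-aware."""
    if variables is None:
        variables = [c for c in METRIC_COLUMNS if c in metrics.columns]
    rows = []
    for var in variables:
        col = pd.to_numeric(metrics[var], errors="coerce").dropna()
        rows.append(
            {
                "variable": var,
                "mean": col.mean() if len(col) else float("nan"),
                "sd": col.std(ddof=1) if len(col) > 1 else (0.0 if len(col) else float("nan")),
                "min": col.min() if len(col) else float("nan"),
                "max": col.max() if len(col) else float("nan"),
                "n": int(len(col)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
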