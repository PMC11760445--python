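"""Group comparison pipeline for the cohort outcome table.

The analysis follows the standard small-sample biomechanics recipe:
Shapiro–Wilk (normality, per group) and Brown–Forsythe (equality of
variances, median-centred Levene) gate each variable at α = 0.05 into either
a one-way ANOVA with Holm–Šidák-adjusted pairwise t tests, or a
Kruskal–Wallis test with Dunn's pairwise z tests under Bonferroni
correction. Variability differences between groups are themselves compared
with Brown–Forsythe omnibus and pairwise tests (Holm-adjusted). Density–
micromotion association is Pearson's r per group, and observed power of
each ANOVA is the noncentral-F power at the sample effect size.

Significance is defined inclusively, p <= 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import FTestAnovaPower

__all__ = [
    "ALPHA",
    "StatsError",
    "PairwiseTest",
    "ComparisonResult",
    "VariabilityResult",
    "gate_and_compare",
    "compare_variability",
    "correlate",
    "observed_power",
    "dunn_test",
    "build_report",
]

ALPHA: float = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseTest:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    method: str


@dataclass
class ComparisonResult:
    variable: str
    test_used: str  # "anova" | "kruskal"
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairwiseTest]
    shapiro_p: dict[str, float]
    brown_forsythe_p: float
    observed_power: float | None = None

    @property
    def significant(self) -> bool:
        return self.omnibus_p <= ALPHA


@dataclass
class VariabilityResult:
    variable: str
    omnibus_p: float
    pairwise: list[PairwiseTest] = field(default_factory=list)


def _validate_groups(groups: dict[str, np.ndarray], min_n: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_n:
            raise StatsError(f"group {name!r}: need >= {min_n} values, got {arr.size}")
        out[name] = arr
    return out


def _brown_forsythe_p(samples: list[np.ndarray]) -> float:
    """Median-centred Levene p value; degenerate (zero-spread) data -> 1."""
    if all(np.ptp(np.abs(s - np.median(s))) == 0 for s in samples):
        warnings.warn("degenerate spread: variance comparison returns p = 1",
                      stacklevel=3)
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.levene(*samples, center="median")
    return float(p) if np.isfinite(p) else 1.0


def gate_and_compare(groups: dict[str, np.ndarray], variable: str = "value") -> ComparisonResult:
    """Normality/variance-gated omnibus comparison with post hoc tests.

    All groups normal (Shapiro–Wilk p > α) with equal variances
    (Brown–Forsythe p > α): one-way ANOVA + Holm–Šidák pairwise t tests.
    Otherwise: Kruskal–Wallis + Dunn–Bonferroni. Raw and adjusted pairwise
    p values are both returned.
    """
    groups = _validate_groups(groups)
    shapiro_p: dict[str, float] = {}
    for name, vals in groups.items():
        if vals.size < 3 or np.ptp(vals) == 0:
            shapiro_p[name] = np.nan  # cannot assess -> treated as failing
        else:
            shapiro_p[name] = float(sps.shapiro(vals).pvalue)
    samples = list(groups.values())
    names = list(groups)
    bf_p = _brown_forsythe_p(samples)
    normal = all(np.isfinite(p) and p > ALPHA for p in shapiro_p.values())
    parametric = normal and bf_p > ALPHA

    pairs = list(itertools.combinations(names, 2))
    if parametric:
        stat, p = sps.f_oneway(*samples)
        raw = [
            sps.ttest_ind(groups[a], groups[b]).pvalue for a, b in pairs
        ]
        adj = multipletests(raw, alpha=ALPHA, method="holm-sidak")[1]
        pairwise = [
            PairwiseTest(pair=pr, raw_p=float(r), adjusted_p=float(a), method="holm-sidak")
            for pr, r, a in zip(pairs, raw, adj)
        ]
        power = observed_power(groups)
        test_used = "anova"
    else:
        stat, p = sps.kruskal(*samples)
        pairwise = dunn_test(groups)
        power = None
        test_used = "kruskal"
    return ComparisonResult(
        variable=variable,
        test_used=test_used,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        shapiro_p=shapiro_p,
        brown_forsythe_p=bf_p,
        observed_power=power,
    )


def dunn_test(groups: dict[str, np.ndarray]) -> list[PairwiseTest]:
    """Dunn's post hoc rank comparison with Bonferroni correction.

    Pairwise z statistics on mean pooled ranks with the usual tie
    correction; adjusted p = min(1, m * p).
    """
    groups = _validate_groups(groups)
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks: dict[str, float] = {}
    start = 0
    for n in names:
        k = groups[n].size
        mean_ranks[n] = float(ranks[start : start + k].mean())
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:
            raw = 1.0
        else:
            z = abs(mean_ranks[a] - mean_ranks[b]) / se
            raw = float(2.0 * sps.norm.sf(z))
        out.append(
            PairwiseTest(
                pair=(a, b),
                raw_p=raw,
                adjusted_p=min(1.0, raw * len(pairs)),
                method="dunn-bonferroni",
            )
        )
    return out


def compare_variability(groups: dict[str, np.ndarray], variable: str = "value") -> VariabilityResult:
    """Brown–Forsythe comparison of group variability: omnibus over all
    groups plus Holm-adjusted pairwise tests."""
    groups = _validate_groups(groups)
    names = list(groups)
    omnibus = _brown_forsythe_p(list(groups.values()))
    pairs = list(itertools.combinations(names, 2))
    raw = [_brown_forsythe_p([groups[a], groups[b]]) for a, b in pairs]
    adj = multipletests(raw, alpha=ALPHA, method="holm")[1]
    pairwise = [
        PairwiseTest(pair=pr, raw_p=float(r), adjusted_p=float(a), method="brown-forsythe-holm")
        for pr, r, a in zip(pairs, raw, adj)
    ]
    return VariabilityResult(variable=variable, omnibus_p=omnibus, pairwise=pairwise)


def correlate(
    x_by_group: dict[str, np.ndarray], y_by_group: dict[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Pearson r and two-sided p per group between paired variables."""
    out: dict[str, tuple[float, float]] = {}
    for name in x_by_group:
        x = np.asarray(x_by_group[name], dtype=float)
        y = np.asarray(y_by_group[name], dtype=float)
        if x.size != y.size or x.size < 3:
            raise StatsError(f"group {name!r}: need >= 3 paired values")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise StatsError(f"group {name!r}: zero variance, correlation undefined")
        r, p = sps.pearsonr(x, y)
        out[name] = (float(r), float(p))
    return out


def observed_power(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> float:
    """Post hoc power of the one-way ANOVA at the sample effect size.

    Uses the noncentral-F distribution with Cohen's f estimated from the
    between/within sum-of-squares decomposition of the data themselves.
    """
    groups = _validate_groups(groups)
    samples = list(groups.values())
    n_total = sum(s.size for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ss_within == 0:
        warnings.warn("zero residual variance: observed power reported as 1",
                      stacklevel=2)
        return 1.0
    f = float(np.sqrt(ss_between / ss_within))
    return float(
        FTestAnovaPower().power(
            effect_size=f, nobs=n_total, alpha=alpha, k_groups=len(samples)
        )
    )


# ---------------------------------------------------------------------------
# report assembly

DENSITY_VARIABLES = [
    ("subchondral_bmd", "Subchondral Cylinder BMD [mgHA/cm^3]"),
    ("vault_bmd", "Glenoid Cylinder [mgHA/cm^3]"),
    ("global_bmd", "Glenoid Global [mgHA/cm^3]"),
    ("subchondral_bvtv", "Subchondral Cylinder BV/TV"),
    ("vault_bvtv", "Glenoid Cylinder BV/TV"),
    ("global_bvtv", "Glenoid Global BV/TV"),
]

OUTCOME_VARIABLES = [
    "micromotion_pre_um",
    "micromotion_post_um",
    "micromotion_delta_um",
    "rotation_pre_deg",
    "rotation_post_deg",
    "rotation_delta_deg",
]


def _by_group(df: pd.DataFrame, col: str, group_col: str = "group") -> dict[str, np.ndarray]:
    return {str(g): sub[col].to_numpy(dtype=float) for g, sub in df.groupby(group_col, sort=True)}


def build_report(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Assemble the cohort report tables from a flat specimen table.

    Returns a dict of tidy DataFrames: ``density`` (mean ± SD per group with
    pairwise p values), ``outcomes`` (group comparisons of the stability
    variables, overall and stratified by correction degree),
    ``variability`` (Brown–Forsythe spread comparisons) and ``correlation``
    (Pearson r/p of subchondral density vs micromotion per group). For a
    single-group cohort only descriptives are produced.
    """
    if cohort.empty:
        raise StatsError("empty cohort")
    n_groups = cohort["group"].nunique()
    tables: dict[str, pd.DataFrame] = {}

    def summary_rows(variables: list[str], labels: dict[str, str] | None = None):
        rows = []
        for var in variables:
            if var not in cohort.columns:
                continue
            groups = _by_group(cohort, var)
            row: dict[str, object] = {"variable": (labels or {}).get(var, var)}
            for g, vals in groups.items():
                row[f"{g}_mean"] = vals.mean()
                row[f"{g}_sd"] = vals.std(ddof=1)
            if n_groups >= 2 and all(v.size >= 2 for v in groups.values()):
                res = gate_and_compare(groups, variable=var)
                row["test"] = res.test_used
                row["omnibus_p"] = res.omnibus_p
                for pw in res.pairwise:
                    row[f"{pw.pair[0]}_vs_{pw.pair[1]}_p"] = pw.adjusted_p
                if res.observed_power is not None:
                    row["observed_power"] = res.observed_power
            rows.append(row)
        return pd.DataFrame(rows)

    labels = dict(DENSITY_VARIABLES)
    tables["density"] = summary_rows([v for v, _ in DENSITY_VARIABLES], labels)
    tables["outcomes"] = summary_rows(OUTCOME_VARIABLES)

    # stratified by correction degree (augment cells vs reference)
    strat_rows = []
    if "correction_deg" in cohort.columns and n_groups >= 2:
        strat = cohort.copy()
        strat["cell"] = np.where(
            strat["group"] == "Reference",
            "Reference",
            strat["group"].astype(str) + strat["correction_deg"].astype(int).astype(str),
        )
        for var in OUTCOME_VARIABLES:
            if var not in strat.columns:
                continue
            groups = _by_group(strat, var, group_col="cell")
            if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
                continue
            res = gate_and_compare(groups, variable=var)
            row = {"variable": var, "test": res.test_used, "omnibus_p": res.omnibus_p}
            for pw in res.pairwise:
                row[f"{pw.pair[0]}_vs_{pw.pair[1]}_p"] = pw.adjusted_p
            strat_rows.append(row)
    tables["outcomes_by_correction"] = pd.DataFrame(strat_rows)

    if n_groups >= 2:
        var_rows = []
        for var in OUTCOME_VARIABLES:
            if var not in cohort.columns:
                continue
            res = compare_variability(_by_group(cohort, var), variable=var)
            row = {"variable": var, "omnibus_p": res.omnibus_p}
            for pw in res.pairwise:
                row[f"{pw.pair[0]}_vs_{pw.pair[1]}_p"] = pw.adjusted_p
            var_rows.append(row)
        tables["variability"] = pd.DataFrame(var_rows)

    corr_rows = []
    if {"subchondral_bmd", "micromotion_post_um"} <= set(cohort.columns):
        for g, sub in cohort.groupby("group", sort=True):
            if len(sub) < 3:
                continue
            try:
                res = correlate(
                    {str(g): sub["subchondral_bmd"].to_numpy()},
                    {str(g): sub["micromotion_post_um"].to_numpy()},
                )
            except StatsError:
                continue
            r, p = res[str(g)]
            corr_rows.append(
                {"group": g, "x": "subchondral_bmd", "y": "micromotion_post_um",
                 "pearson_r": r, "p": p, "n": len(sub)}
            )
    tables["correlation"] = pd.DataFrame(corr_rows)
    return tables
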