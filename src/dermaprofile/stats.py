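"""Inferential layer: mutation-burden ANOVA and gene-environment interactions.

Ordinal severity grades are analysed as equally spaced numeric scores (a
documented modeling assumption). One-way ANOVA compares severity across the
three burden groups (none / single / double); post-hoc pairwise t-tests use
pooled variance and are two-sided. Gene x lifestyle interactions are tested
with a two-way Type II sum-of-squares ANOVA on binarized genotype (carrier
vs non-carrier) and median-binned lifestyle, computed by nested least-squares
model comparison so unbalanced designs are handled correctly. No
multiple-comparison correction is applied; results carry an
``uncorrected: true`` flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import BURDEN_LABELS, CohortTable, ManifestError

logger = logging.getLogger(__name__)

BURDEN_PAIRS = (("none", "single"), ("none", "double"), ("single", "double"))


class SparseSubgroupError(ValueError):
    """A design cell required for the interaction term is empty."""


@dataclass(frozen=True)
class InteractionSpec:
    """A (gene, lifestyle factor, phenotype outcome) interaction hypothesis."""

    gene: str
    lifestyle: str
    outcome: str


#: the five biologically motivated gene x lifestyle -> phenotype hypotheses
DEFAULT_INTERACTIONS = (
    InteractionSpec("FLG", "Scrub.Usage", "Sensitivity"),
    InteractionSpec("MMP-3", "City_Living", "Redness"),
    InteractionSpec("SOD2", "Stress", "Acne"),
    InteractionSpec("AQP3", "Is_Winter", "Dryness"),
    InteractionSpec("GPX", "Medication", "Pigmentation"),
)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
            **self.flags,
        }


@dataclass
class TTestResult:
    pair: tuple[str, str]
    t: float
    df: int
    p: float
    flags: dict = field(default_factory=dict)


def burden_group(burden_code: int) -> str:
    """Map burden code 0/1/2 to its group label none/single/double."""
    try:
        return BURDEN_LABELS[int(burden_code)]
    except (KeyError, ValueError):
        raise ValueError(f"invalid burden code {burden_code!r}; expected 0, 1 or 2")


def oneway_anova(severity, group) -> AnovaResult:
    """One-way ANOVA of severity across groups; empty groups are dropped."""
    severity = np.asarray(severity, dtype=float)
    group = np.asarray(group)
    if severity.shape != group.shape:
        raise ValueError("severity and group must have equal length")
    samples = [severity[group == g] for g in np.unique(group)]
    samples = [s for s in samples if len(s) > 0]
    g = len(samples)
    n = sum(len(s) for s in samples)
    if g < 2:
        raise ValueError("need at least 2 nonempty groups")
    if n <= g:
        raise ValueError("need more observations than groups")
    means = [s.mean() for s in samples]
    if np.ptp(means) == 0:
        return AnovaResult("group", 0.0, g - 1, n - g, 1.0)
    f_stat, p = sps.f_oneway(*samples)
    return AnovaResult("group", float(f_stat), g - 1, n - g, float(p))


def pairwise_t_tests(severity, group) -> list[TTestResult]:
    """Two-sided pooled-variance t-tests for the three burden-group pairs.

    ``group`` may hold burden codes 0/1/2 or the labels none/single/double.
    A degenerate pair (either side with n < 2) is skipped with a warning flag.
    """
    severity = np.asarray(severity, dtype=float)
    group = np.asarray(group)
    if np.issubdtype(group.dtype, np.number):
        group = np.array([burden_group(c) for c in group])
    out: list[TTestResult] = []
    for ga, gb in BURDEN_PAIRS:
        xa, xb = severity[group == ga], severity[group == gb]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("skipping %s vs %s: a group has n < 2", ga, gb)
            out.append(
                TTestResult((ga, gb), math.nan, 0, math.nan, {"skipped": True})
            )
            continue
        df = len(xa) + len(xb) - 2
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            if xa.mean() == xb.mean():
                out.append(TTestResult((ga, gb), 0.0, df, 1.0))
            else:
                out.append(
                    TTestResult((ga, gb), math.inf, df, 0.0, {"zero_variance": True})
                )
            continue
        t, p = sps.ttest_ind(xa, xb, equal_var=True)
        out.append(TTestResult((ga, gb), float(t), df, float(p)))
    return out


def binarize_lifestyle(values) -> np.ndarray:
    """Median split into Low (0) / High (1); values at the median go Low.

    Already-binary columns pass through unchanged; constant columns are an
    error because no split exists.
    """
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("constant column cannot be binarized")
    if set(distinct.tolist()) <= {0.0, 1.0}:
        return values.astype(np.int64)
    return (values > np.median(values)).astype(np.int64)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def twoway_anova_typeII(outcome, genotype, lifestyle) -> list[AnovaResult]:
    """Two-way Type II ANOVA with binary factors, via model comparison.

    Each main-effect sum of squares is the RSS reduction from adding that
    factor to the other main effect; the interaction SS is the reduction
    from adding G x L to both mains. F uses the full-model residual on
    n - 4 degrees of freedom.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(genotype, dtype=float)
    l = np.asarray(lifestyle, dtype=float)
    if not (y.shape == g.shape == l.shape):
        raise ValueError("outcome, genotype and lifestyle must be equal length")
    if not set(np.unique(g)) <= {0.0, 1.0} or not set(np.unique(l)) <= {0.0, 1.0}:
        raise ValueError("genotype and lifestyle must be binary 0/1")
    n = y.size
    cells = {(a, b): np.sum((g == a) & (l == b)) for a in (0, 1) for b in (0, 1)}
    if min(cells.values()) == 0:
        raise SparseSubgroupError(
            f"interaction not estimable: empty design cell(s) "
            f"{[c for c, m in cells.items() if m == 0]}"
        )
    ones = np.ones(n)
    X_full = np.column_stack([ones, g, l, g * l])
    X_mains = np.column_stack([ones, g, l])
    rss_full = _rss(y, X_full)
    rss_mains = _rss(y, X_mains)
    rss_g = _rss(y, np.column_stack([ones, g]))
    rss_l = _rss(y, np.column_stack([ones, l]))
    df_den = n - 4
    mse = rss_full / df_den

    def term(name: str, ss: float) -> AnovaResult:
        ss = max(ss, 0.0)  # guard tiny negative round-off
        if mse <= 1e-12 * max(1.0, float(y @ y)):
            # saturated / noiseless fit: no residual variance to test against
            return AnovaResult(
                name, 0.0, 1, df_den, 1.0, {"residual_zero": True}
            )
        f_stat = ss / mse
        return AnovaResult(name, f_stat, 1, df_den, float(sps.f.sf(f_stat, 1, df_den)))

    return [
        term("genotype", rss_l - rss_mains),
        term("lifestyle", rss_g - rss_mains),
        term("interaction", rss_mains - rss_full),
    ]


def run_interaction_battery(
    cohort: CohortTable, specs=DEFAULT_INTERACTIONS
) -> pd.DataFrame:
    """Run the two-way Type II ANOVA for each interaction hypothesis.

    Genotype is binarized as carrier (burden > 0) vs non-carrier; ordinal
    lifestyle factors are median-binned. Results are uncorrected for
    multiple testing, and an inestimable interaction (empty design cell) is
    reported as a flagged sparse-subgroup row rather than an error.
    """
    rows = []
    for spec in specs:
        for name, modality in (
            (spec.gene, "genetics"),
            (spec.lifestyle, "lifestyle"),
            (spec.outcome, "phenotype"),
        ):
            actual = cohort.spec(name).modality
            if actual != modality:
                raise ManifestError(
                    f"{name!r} has modality {actual!r}, expected {modality!r} "
                    f"in interaction {spec}"
                )
        genotype = (cohort.data[spec.gene].to_numpy() > 0).astype(np.int64)
        lifestyle = binarize_lifestyle(cohort.data[spec.lifestyle].to_numpy())
        outcome = cohort.data[spec.outcome].to_numpy(dtype=float)
        base = {
            "gene": spec.gene,
            "lifestyle": spec.lifestyle,
            "outcome": spec.outcome,
            "uncorrected": True,
        }
        try:
            results = twoway_anova_typeII(outcome, genotype, lifestyle)
        except SparseSubgroupError:
            rows.append(
                {
                    **base,
                    "effect": "interaction",
                    "F": math.nan,
                    "df_num": 1,
                    "df_den": len(outcome) - 4,
                    "p": math.nan,
                    "sparse_subgroup": True,
                }
            )
            continue
        for res in results:
            rows.append({**base, **res.to_dict(), "sparse_subgroup": False})
    return pd.DataFrame(rows)


def interaction_cell_means(
    cohort: CohortTable, spec: InteractionSpec
) -> pd.DataFrame:
    """Mean outcome per genotype x lifestyle cell (interaction-plot data)."""
    genotype = (cohort.data[spec.gene].to_numpy() > 0).astype(np.int64)
    lifestyle = binarize_lifestyle(cohort.data[spec.lifestyle].to_numpy())
    outcome = cohort.data[spec.outcome].to_numpy(dtype=float)
    frame = pd.DataFrame(
        {"carrier": genotype, "exposure_high": lifestyle, "severity": outcome}
    )
    return (
        frame.groupby(["carrier", "exposure_high"])["severity"]
        .agg(["mean", "count"])
        .reset_index()
    )


def burden_anova_battery(cohort: CohortTable) -> pd.DataFrame:
    """One-way burden ANOVA + post-hoc t-tests per gene x phenotype pair."""
    rows = []
    genes = cohort.columns_for({"genetics"})
    phenos = cohort.columns_for({"phenotype"})
    for gene in genes:
        group = cohort.data[gene].to_numpy()
        for pheno in phenos:
            severity = cohort.data[pheno].to_numpy(dtype=float)
            res = oneway_anova(severity, group)
            rows.append(
                {
                    "gene": gene,
                    "phenotype": pheno,
                    "test": "oneway_anova",
                    "statistic": res.F,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "p": res.p,
                }
            )
            for tt in pairwise_t_tests(severity, group):
                rows.append(
                    {
                        "gene": gene,
                        "phenotype": pheno,
                        "test": f"t_{tt.pair[0]}_vs_{tt.pair[1]}",
                        "statistic": tt.t,
                        "df_num": 1,
                        "df_den": tt.df,
                        "p": tt.p,
                    }
                )
    return pd.DataFrame(rows)
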