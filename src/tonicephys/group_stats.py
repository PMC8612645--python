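"""Group comparisons, correlations and the multiple-regression ledger.

The statistical layer mirrors a conventional slice-physiology analysis:
omnibus tests (one-way ANOVA with Tukey post hocs, Kruskal-Wallis with
Bonferroni-adjusted Dunn post hocs, Student/Welch t tests, two-way
ANOVA with Type II sums of squares for unbalanced designs), Pearson
correlation with a least-squares line, and a ledger of ordinary
least-squares models predicting the tonic current from cell-type labels
and patient covariates (age, sex, pathology, seizure history,
dexamethasone and levetiracetam treatment, hemisphere and lobe), with
explicit dummy coding and reference categories.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "RegressionLedger",
    "omnibus_and_posthoc",
    "correlate",
    "fit_regression_ledger",
    "DEFAULT_MODEL_SPECS",
    "build_cell_table",
]

P_FLOOR = 1e-300


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    df: tuple
    p: float
    post_hoc: list = field(default_factory=list)   # (pair, p)
    effect: dict = field(default_factory=dict)


@dataclass
class RegressionLedger:
    model_id: str
    dependent: str
    coefficients: dict            # term -> (estimate, SE, p)
    df: int
    residual_ss: float
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    n: int
    reference_categories: dict = field(default_factory=dict)
    dropped_terms: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": self.model_id, "term": t, "estimate": e, "se": s, "p": p}
            for t, (e, s, p) in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def _clip_p(p: float) -> float:
    return float(min(1.0, max(P_FLOOR, p)))


def _dunn_posthoc(groups: dict, adjust: str = "bonferroni") -> list:
    """Dunn's z-test on mean ranks with tie correction, Bonferroni-adjusted."""
    labels = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    ranks = stats.rankdata(all_vals)
    n = len(all_vals)
    # tie correction for the rank variance
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = {}
    pos = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[pos:pos + k].mean()
        pos += k
    out = []
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        if se < 1e-300:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        out.append(((a, b), _clip_p(p)))
    return out


def omnibus_and_posthoc(
    values: Sequence[float],
    groups: Sequence,
    family: str = "anova+tukey",
) -> GroupTestResult:
    """Omnibus group comparison with post hoc pairwise tests.

    ``family`` is one of ``anova+tukey``, ``kruskal+dunn``, ``welch_t``,
    ``student_t`` or ``two_way_anova`` (for the latter, ``groups`` must
    be a sequence of (factor_a, factor_b) pairs).  Constant input across
    all groups returns statistic 0 and p = 1 rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    if family == "two_way_anova":
        return _two_way_anova(values, groups)
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    gvals = {g: values[labels == g] for g in uniq}
    for g, v in gvals.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if np.ptp(values) < 1e-300:
        return GroupTestResult(test=family, statistic=0.0, df=(len(uniq) - 1,
                               len(values) - len(uniq)), p=1.0)

    if family == "anova+tukey":
        f, p = stats.f_oneway(*gvals.values())
        if not np.isfinite(f):  # zero within-group variance, distinct means
            f, p = float("inf"), P_FLOOR
        res = GroupTestResult(
            test="one_way_anova",
            statistic=float(f),
            df=(len(uniq) - 1, len(values) - len(uniq)),
            p=_clip_p(p),
        )
        if len(uniq) > 2 and np.isfinite(f):
            tk = stats.tukey_hsd(*gvals.values())
            for i, j in itertools.combinations(range(len(uniq)), 2):
                res.post_hoc.append(((uniq[i], uniq[j]), _clip_p(tk.pvalue[i, j])))
        return res
    if family == "kruskal+dunn":
        h, p = stats.kruskal(*gvals.values())
        res = GroupTestResult(
            test="kruskal_wallis", statistic=float(h),
            df=(len(uniq) - 1,), p=_clip_p(p),
        )
        if len(uniq) > 2:
            res.post_hoc = _dunn_posthoc(gvals)
        return res
    if family in ("welch_t", "student_t"):
        if len(uniq) != 2:
            raise ValueError("t tests require exactly 2 groups")
        a, b = (gvals[g] for g in uniq)
        t, p = stats.ttest_ind(a, b, equal_var=(family == "student_t"))
        if not np.isfinite(t):
            t, p = 0.0, 1.0
        df = (len(a) + len(b) - 2,) if family == "student_t" else (
            float(stats.ttest_ind(a, b, equal_var=False).df),
        )
        return GroupTestResult(test=family, statistic=float(t), df=df, p=_clip_p(p))
    raise ValueError(f"unknown test family {family!r}")


def _two_way_anova(values: np.ndarray, groups: Sequence) -> GroupTestResult:
    """Type II two-way ANOVA (unbalanced designs) via statsmodels."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa = [str(g[0]) for g in groups]
    fb = [str(g[1]) for g in groups]
    df = pd.DataFrame({"y": values, "a": fa, "b": fb})
    if np.ptp(values) < 1e-300:
        return GroupTestResult(test="two_way_anova", statistic=0.0, df=(0, 0), p=1.0)
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    res = GroupTestResult(
        test="two_way_anova",
        statistic=float(table.loc["C(a)", "F"]),
        df=(int(table.loc["C(a)", "df"]), int(table.loc["Residual", "df"])),
        p=_clip_p(table.loc["C(a)", "PR(>F)"]),
    )
    res.effect = {
        "factor_a": (float(table.loc["C(a)", "F"]), _clip_p(table.loc["C(a)", "PR(>F)"])),
        "factor_b": (float(table.loc["C(b)", "F"]), _clip_p(table.loc["C(b)", "PR(>F)"])),
        "interaction": (
            float(table.loc["C(a):C(b)", "F"]),
            _clip_p(table.loc["C(a):C(b)", "PR(>F)"]),
        ),
    }
    return res


def correlate(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Pearson correlation with least-squares line and t-distributed test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) < 1e-300:
        raise ValueError("zero-variance predictor")
    lr = stats.linregress(x, y)
    t = (
        lr.rvalue * math.sqrt((len(x) - 2) / max(1.0 - lr.rvalue ** 2, 1e-300))
        if abs(lr.rvalue) < 1.0 else float("inf")
    )
    return GroupTestResult(
        test="pearson",
        statistic=float(lr.rvalue),
        df=(len(x) - 2,),
        p=_clip_p(lr.pvalue),
        effect={
            "slope": float(lr.slope),
            "intercept": float(lr.intercept),
            "t": float(t),
            "r": float(lr.rvalue),
        },
    )


# ---------------------------------------------------------------------------
# regression ledger
# ---------------------------------------------------------------------------

# Dummy-coded terms available to the model specifications.  Reference
# categories: firing cluster = highest-numbered cluster; axonal class =
# pooled other/not-recovered; pathology = all non-listed pathologies;
# seizure history = none; dexamethasone = none; lobe = temporal/other.
TERM_BUILDERS = {
    "age": lambda t: t["age"].astype(float),
    "sex_male": lambda t: (t["sex"] == "M").astype(float),
    "hemisphere_left": lambda t: (t["hemisphere"] == "left").astype(float),
    "pathology_tle": lambda t: (t["pathology"] == "temporal lobe epilepsy").astype(float),
    "pathology_glioblastoma": lambda t: (t["pathology"] == "glioblastoma").astype(float),
    "cortical_infiltration": lambda t: t.get(
        "cortical_infiltration", pd.Series(0.0, index=t.index)
    ).astype(float),
    "lobe_frontal": lambda t: (t["lobe"] == "frontal").astype(float),
    "lobe_parietal": lambda t: (t["lobe"] == "parietal").astype(float),
    "seizures_within_1y": lambda t: (t["seizure_history"] == "within_1y").astype(float),
    "seizures_over_1y": lambda t: (t["seizure_history"] == "more_than_1y_ago").astype(float),
    "dex_presurgery": lambda t: (t["dexamethasone"] == "presurgery").astype(float),
    "dex_at_surgery": lambda t: (t["dexamethasone"] == "at_surgery").astype(float),
    "levetiracetam": lambda t: t["levetiracetam"].astype(float),
    "axon_rosehip": lambda t: (t["axonal_class"] == "rosehip").astype(float),
    "axon_neurogliaform": lambda t: (t["axonal_class"] == "neurogliaform").astype(float),
    "axon_l23": lambda t: (t["axonal_class"] == "L2-3").astype(float),
    "axon_stalked": lambda t: (t["axonal_class"] == "stalked").astype(float),
    "axon_other": lambda t: (t["axonal_class"] == "other").astype(float),
    "axon_not_recovered": lambda t: (t["axonal_class"] == "not_recovered").astype(float),
}

_CLINICAL = [
    "seizures_within_1y", "seizures_over_1y",
    "dex_presurgery", "dex_at_surgery", "levetiracetam",
]
_REGION = ["cortical_infiltration", "hemisphere_left", "lobe_frontal", "lobe_parietal"]

# Thirteen model specifications: 1-6 use firing-cluster labels, 7-13
# axonal classes, with increasing covariate sets.
DEFAULT_MODEL_SPECS: dict[str, list[str]] = {
    "model01": ["age", "sex_male"],
    "model02": ["age", "sex_male", "cluster:1,2,3,4"],
    "model03": ["age", "sex_male", "cluster:1,2,4,5"],
    "model04": ["age", "sex_male", "cluster:1,2,3,4",
                "pathology_tle", "pathology_glioblastoma"],
    "model05": ["age", "sex_male", "cluster:1,2,3,4"] + _REGION,
    "model06": ["age", "sex_male", "cluster:1,2,3,4"] + _CLINICAL,
    "model07": ["axon_rosehip", "axon_neurogliaform", "axon_l23", "axon_stalked"],
    "model08": ["age", "sex_male",
                "axon_rosehip", "axon_neurogliaform", "axon_l23", "axon_stalked"],
    "model09": ["age", "sex_male",
                "axon_rosehip", "axon_l23", "axon_stalked",
                "axon_other", "axon_not_recovered"],
    "model10": ["age", "sex_male",
                "axon_rosehip", "axon_neurogliaform", "axon_l23", "axon_stalked",
                "pathology_tle", "pathology_glioblastoma"],
    "model11": ["age", "sex_male",
                "axon_rosehip", "axon_neurogliaform", "axon_l23", "axon_stalked"]
               + _REGION,
    "model12": ["age", "sex_male",
                "axon_rosehip", "axon_neurogliaform", "axon_l23", "axon_stalked"]
               + _CLINICAL,
    "model13": ["age", "sex_male",
                "axon_rosehip", "axon_neurogliaform", "axon_l23", "axon_stalked",
                "pathology_tle", "pathology_glioblastoma"]
               + _REGION + _CLINICAL,
}


def _design_matrix(table: pd.DataFrame, terms: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    cols: dict[str, pd.Series] = {}
    refs: dict[str, str] = {}
    for term in terms:
        if term.startswith("cluster:"):
            wanted = term.split(":", 1)[1].split(",")
            all_clusters = sorted({str(c) for c in table["firing_cluster"]})
            refs["firing_cluster"] = ",".join(
                c for c in all_clusters if c not in wanted
            )
            for c in wanted:
                cols[f"cluster_{c}"] = (
                    table["firing_cluster"].astype(str) == c
                ).astype(float)
        elif term in TERM_BUILDERS:
            cols[term] = TERM_BUILDERS[term](table)
        else:
            raise KeyError(f"unknown model term {term!r}")
    if any(t.startswith("axon_") for t in terms):
        present = {t for t in terms if t.startswith("axon_")}
        all_axon = {"axon_rosehip", "axon_neurogliaform", "axon_l23",
                    "axon_stalked", "axon_other", "axon_not_recovered"}
        refs["axonal_class"] = ",".join(sorted(all_axon - present))
    return pd.DataFrame(cols, index=table.index), refs


def fit_regression_ledger(
    cell_table: pd.DataFrame,
    model_specs: Optional[dict] = None,
    dependent: str = "I_tonic",
) -> list[RegressionLedger]:
    """Fit the OLS model family and return one ledger entry per model.

    ``cell_table`` must contain the dependent column plus whatever
    covariates the specs reference (``firing_cluster``, ``axonal_class``
    and the patient columns).  Rank-deficient designs drop aliased
    columns with an explicit record, never silently.
    """
    import statsmodels.api as sm

    specs = model_specs if model_specs is not None else DEFAULT_MODEL_SPECS
    ledgers: list[RegressionLedger] = []
    for model_id, terms in specs.items():
        X, refs = _design_matrix(cell_table, terms)
        y = cell_table[dependent].astype(float)
        mask = y.notna() & X.notna().all(axis=1)
        Xm, ym = X[mask], y[mask]
        dropped: list[str] = []
        # drop aliased columns (exactly collinear) with a report: a
        # column is redundant when removing it leaves the rank unchanged
        Xc = sm.add_constant(Xm, has_constant="add")
        while np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            rank = np.linalg.matrix_rank(Xc.to_numpy())
            for col in list(Xm.columns)[::-1]:
                trial = sm.add_constant(Xm.drop(columns=[col]), has_constant="add")
                if np.linalg.matrix_rank(trial.to_numpy()) == rank:
                    dropped.append(col)
                    Xm = Xm.drop(columns=[col])
                    Xc = trial
                    break
            else:  # pragma: no cover - cannot reduce further
                break
        fit = sm.OLS(ym, Xc).fit()
        coeffs = {
            ("intercept" if name == "const" else name):
                (float(fit.params[name]), float(fit.bse[name]),
                 _clip_p(float(fit.pvalues[name])))
            for name in Xc.columns
        }
        f_stat = float(fit.fvalue) if Xm.shape[1] > 0 else 0.0
        f_p = _clip_p(float(fit.f_pvalue)) if Xm.shape[1] > 0 else 1.0
        ledgers.append(
            RegressionLedger(
                model_id=model_id,
                dependent=dependent,
                coefficients=coeffs,
                df=int(fit.df_resid),
                residual_ss=float(fit.ssr),
                r2=float(fit.rsquared) if Xm.shape[1] > 0 else 0.0,
                adj_r2=float(fit.rsquared_adj) if Xm.shape[1] > 0 else 0.0,
                f_stat=f_stat,
                f_p=f_p,
                n=int(mask.sum()),
                reference_categories=refs,
                dropped_terms=dropped,
            )
        )
    return ledgers


def build_cell_table(
    tonic_results: pd.DataFrame,
    cluster_labels: pd.DataFrame,
    cell_meta: pd.DataFrame,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Join tonic measurements, firing-cluster labels, per-cell metadata
    (axonal class, patient link) and the patient covariate table into
    the analysis table the regression ledger consumes."""
    t = tonic_results.merge(cluster_labels, on="cell_id", how="left")
    t = t.merge(cell_meta, on="cell_id", how="left")
    t = t.merge(patients, on="patient_id", how="left")
    return t
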