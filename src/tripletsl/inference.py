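"""Group-level statistics for the SL pipeline.

Implements the study-level analyses: one-sample learning tests (negative
RT slope; above-chance 2-AFC accuracy), the three mixed-effects model
specifications (hit-level z-RT, trial-level 2-AFC logistic, task-level
composite), the developmental analysis (continuous age interaction plus a
median-split follow-up), correlation analyses (pairwise and partial,
multiplicity-adjusted), the Fisher-z comparison of independent
correlations, bias-corrected effect sizes (Hedges g*), Welch two-sample
tests, and Cousineau–Morey within-group standard errors.

Conventions
-----------
Factors are sum-to-zero coded at ±0.5 (TD, linguistic, visual, female on
the positive side), so a two-way product column equals the
difference-in-differences contrast and lower-order terms stay
interpretable under interactions.  Trial order is centered within task.
Fixed-effect p-values for the linear mixed models use the Wald normal
approximation; the logistic mixed model is estimated by variational Bayes
(statsmodels ``BinomialBayesMixedGLM``) and reports posterior mean/SD.
Sex is included as a covariate in every group-difference model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.stats.multitest import multipletests

from .errors import FitError

__all__ = [
    "ModelFit",
    "TestResult",
    "CorrelationResult",
    "add_effect_codes",
    "one_sample_learning_tests",
    "fit_rt_mixed_model",
    "fit_accuracy_mixed_logistic",
    "fit_composite_model",
    "development_analysis",
    "DevelopmentResult",
    "median_split_ages",
    "partial_correlation",
    "correlation_suite",
    "compare_correlations",
    "effect_size_g",
    "welch_test",
    "morey_within_se",
    "plot_group_task_means",
]

GROUP_CODE = {"TD": 0.5, "ASD": -0.5}
DOMAIN_CODE = {"linguistic": 0.5, "nonlinguistic": -0.5}
MODALITY_CODE = {"visual": 0.5, "auditory": -0.5}
SEX_CODE = {"F": 0.5, "M": -0.5}


@dataclass
class ModelFit:
    """Coefficient table and fit diagnostics of one mixed model."""

    model_name: str
    formula: str
    coef: pd.DataFrame  # index: term; columns: estimate, se, stat, p
    converged: bool
    n_obs: int
    n_groups: int
    singular: bool = False
    fallback: str | None = None
    notes: str = ""

    def term(self, name: str) -> pd.Series:
        return self.coef.loc[name]

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "formula": self.formula,
            "coef": self.coef.reset_index().to_dict(orient="records"),
            "converged": self.converged,
            "singular": self.singular,
            "fallback": self.fallback,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "notes": self.notes,
        }


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float
    p: float
    sidedness: str  # 'two-sided' | 'less' | 'greater'
    n: int
    effect_size_g: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "sidedness": self.sidedness,
            "n": self.n,
        }
        if self.effect_size_g is not None:
            d["g_star"] = self.effect_size_g
        d.update(self.extra)
        return d


@dataclass
class CorrelationResult:
    measure_x: str
    measure_y: str
    r: float
    n: int
    p: float
    p_adjusted: float | None = None
    controls: tuple = ()
    group: str | None = None

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "measure_x": self.measure_x,
            "measure_y": self.measure_y,
            "r": self.r,
            "n": self.n,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "controls": list(self.controls),
        }


def add_effect_codes(df: pd.DataFrame, order_centering: str = "task") -> pd.DataFrame:
    """Attach sum-to-zero (±0.5) codes and a centered trial-order column."""
    out = df.copy()
    for col, codes in (
        ("group", GROUP_CODE),
        ("domain", DOMAIN_CODE),
        ("modality", MODALITY_CODE),
        ("sex", SEX_CODE),
    ):
        if col in out.columns:
            out[col + "_c"] = out[col].map(codes)
            if out[col + "_c"].isna().any():
                bad = sorted(set(out.loc[out[col + "_c"].isna(), col]))
                raise FitError(f"unknown {col} level(s): {bad}")
    if "order" in out.columns:
        if order_centering == "task" and "n_targets" in out.columns:
            out["order_c"] = out["order"] - (out["n_targets"] + 1) / 2.0
        elif order_centering == "global":
            out["order_c"] = out["order"] - out["order"].mean()
        else:
            out["order_c"] = out["order"]
    return out


# ---------------------------------------------------------------------------
# one-sample learning tests


def one_sample_learning_tests(measures: pd.DataFrame, participants: pd.DataFrame) -> list[TestResult]:
    """Did each group learn in each task?

    RT slopes are tested against 0 (one-tailed, alternative 'less': learning
    means acceleration); 2-AFC accuracies against chance 0.5 (one-tailed,
    alternative 'greater').
    """
    df = measures.merge(participants[["participant_id", "group"]], on="participant_id")
    results = []
    for (group, task), sub in df.groupby(["group", "task"], observed=True):
        for col, popmean, alt in (("rt_slope", 0.0, "less"), ("afc_accuracy", 0.5, "greater")):
            x = sub[col].dropna().to_numpy(dtype=float)
            if len(x) < 2:
                continue
            if x.std(ddof=1) == 0:
                # every value at the null point is exactly chance performance;
                # zero variance away from it leaves the t undefined
                if x[0] != popmean:
                    raise FitError(
                        f"degenerate one-sample test: zero variance in {col} for {group}/{task}"
                    )
                stat, p = 0.0, 0.5
            else:
                t = stats.ttest_1samp(x, popmean, alternative=alt)
                stat, p = float(t.statistic), float(t.pvalue)
            results.append(
                TestResult(
                    test_name=f"{group}:{task}:{col}",
                    statistic=stat,
                    df=float(len(x) - 1),
                    p=p,
                    sidedness=alt,
                    n=len(x),
                    extra={"mean": float(x.mean()), "popmean": popmean},
                )
            )
    return results


# ---------------------------------------------------------------------------
# mixed models


def _mixedlm_fit(formula: str, data: pd.DataFrame, vc: dict, groups: str):
    """Fit one random-effects structure.

    Alternate optimizers (bfgs, cg) are tried only when the primary (lbfgs)
    raises; a clean non-converged lbfgs result is returned as-is — on the
    boundary-flat likelihoods these models produce, the alternates fail the
    same way at several times the cost.
    """
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data[groups], re_formula="~1", vc_formula=vc or None
        )
        for method in ("lbfgs", "bfgs", "cg"):
            try:
                res = model.fit(reml=True, method=[method], maxiter=300)
            except Exception:
                continue
            last = res
            break
    if last is None:
        raise FitError(f"mixed model could not be estimated: {formula}")
    return last


def _is_singular(res) -> bool:
    """Random-effect variance estimated at (numerically) zero."""
    tol = 1e-8 * max(float(res.scale), 1e-12)
    comps = [float(np.asarray(res.cov_re).ravel()[0])] if np.asarray(res.cov_re).size else []
    comps.extend(np.asarray(res.vcomp, dtype=float).tolist())
    return any(c <= tol for c in comps)


def _coef_table(res, fe_names) -> pd.DataFrame:
    params = res.params[fe_names]
    bse = res.bse[fe_names]
    stat = params / bse
    p = 2 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {"estimate": params, "se": bse, "stat": stat, "p": p},
        index=pd.Index(fe_names, name="term"),
    )


#: random-effects fallback ladder for the RT model: by-participant
#: intercept plus uncorrelated domain and modality slopes; on a singular or
#: failed fit the modality slope is dropped first, then the domain slope.
RT_RE_LADDER = (
    ({"domain": "0 + domain_c", "modality": "0 + modality_c"}, "intercept+domain+modality"),
    ({"domain": "0 + domain_c"}, "intercept+domain"),
    ({}, "intercept"),
)


def _fit_lmm_with_ladder(model_name, formula, data, groups, ladder) -> ModelFit:
    """Fit a linear mixed model, walking down a random-effects fallback
    ladder (deterministic, documented order) on convergence failure or a
    boundary (zero-variance) random-effects estimate.

    When a failed rung estimates some random-slope variances essentially at
    zero (< 1e-3 × residual variance), later rungs still containing those
    components are skipped — they would stall on the same flat boundary.
    """
    last_exc = None
    boundary: set = set()
    for step, (vc, label) in enumerate(ladder):
        if step > 0 and step < len(ladder) - 1 and boundary & set(vc):
            continue
        try:
            res = _mixedlm_fit(formula, data, vc, groups)
        except Exception as exc:  # FitError, LinAlgError, ...
            last_exc = exc
            continue
        singular = _is_singular(res)
        if not (res.converged and not singular):
            tol = 1e-3 * max(float(res.scale), 1e-12)
            names = list(res.model.exog_vc.names) if vc else []
            boundary |= {n for n, v in zip(names, np.asarray(res.vcomp, dtype=float)) if v < tol}
        if (res.converged and not singular) or step == len(ladder) - 1:
            fe_names = list(res.model.exog_names)
            return ModelFit(
                model_name=model_name,
                formula=f"{formula} | re: {label}",
                coef=_coef_table(res, fe_names),
                converged=bool(res.converged),
                singular=singular,
                fallback=label if step > 0 else None,
                n_obs=int(res.nobs),
                n_groups=int(data[groups].nunique()),
                notes="Wald normal-approximation p-values",
            )
    raise FitError(f"{model_name}: all random-effect structures failed ({last_exc})")


def fit_rt_mixed_model(rt_table: pd.DataFrame, order_centering: str = "task") -> ModelFit:
    """Hit-level z-RT mixed model.

    Fixed effects: full factorial group × domain × modality × trial order
    (up to the 4-way interaction) plus sex.  Random effects: by-participant
    intercepts and (uncorrelated) slopes of domain and modality; singular
    or failed fits walk down :data:`RT_RE_LADDER`.
    """
    data = add_effect_codes(rt_table, order_centering=order_centering)
    if data["participant_id"].nunique() < 2:
        raise FitError("RT mixed model needs at least 2 participants")
    formula = "z_rt ~ group_c * domain_c * modality_c * order_c + sex_c"
    return _fit_lmm_with_ladder("rt_mixed_model", formula, data, "participant_id", RT_RE_LADDER)


def fit_composite_model(composite_table: pd.DataFrame) -> ModelFit:
    """Task-level composite-score mixed model (group × domain × modality).

    Random effects mirror the RT model: by-participant intercepts plus
    uncorrelated domain and modality slopes (the slopes absorb the
    modality- and domain-specific reliability of the composites; without
    them the interaction SEs are visibly anticonservative in null
    simulations), with the same fallback ladder.
    """
    data = add_effect_codes(composite_table)
    if data["participant_id"].nunique() < 2:
        raise FitError("composite model needs at least 2 participants")
    formula = "composite ~ group_c * domain_c * modality_c + sex_c"
    return _fit_lmm_with_ladder("composite_model", formula, data, "participant_id", RT_RE_LADDER)


def fit_accuracy_mixed_logistic(afc_table: pd.DataFrame, fit_method: str = "vb") -> ModelFit:
    """Trial-level 2-AFC mixed logistic model.

    Fixed effects group × domain × modality (+ sex); random intercepts for
    participants and test items, random by-participant slopes of domain
    and modality.  Estimated by variational Bayes; the coefficient table
    reports posterior means and SDs on the log-odds scale, with z = mean/SD.
    A constant outcome (e.g. all responses correct) is complete separation
    and returns a flagged, unestimated fit.
    """
    data = add_effect_codes(afc_table)
    y = data["correct"].astype(int)
    if y.nunique() < 2:
        coef = pd.DataFrame(columns=["estimate", "se", "stat", "p"])
        coef.index.name = "term"
        return ModelFit(
            model_name="afc_mixed_logistic",
            formula="correct ~ group_c * domain_c * modality_c + sex_c",
            coef=coef,
            converged=False,
            singular=True,
            n_obs=len(data),
            n_groups=int(data["participant_id"].nunique()),
            notes="complete separation: constant outcome; model not estimated",
        )
    formula = "correct ~ group_c * domain_c * modality_c + sex_c"
    vc = {
        "participant": "0 + C(participant_id)",
        "item": "0 + C(item_id)",
        "participant_domain": "0 + C(participant_id):domain_c",
        "participant_modality": "0 + C(participant_id):modality_c",
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(formula, vc, data)
        res = model.fit_vb() if fit_method == "vb" else model.fit_map()
    k = len(model.exog_names)
    est = np.asarray(res.fe_mean)[:k]
    sd = np.asarray(res.fe_sd)[:k]
    stat = est / sd
    coef = pd.DataFrame(
        {"estimate": est, "se": sd, "stat": stat, "p": 2 * stats.norm.sf(np.abs(stat))},
        index=pd.Index(model.exog_names, name="term"),
    )
    return ModelFit(
        model_name="afc_mixed_logistic",
        formula=formula + " | re: participant + item intercepts, participant domain/modality slopes",
        coef=coef,
        converged=True,
        n_obs=len(data),
        n_groups=int(data["participant_id"].nunique()),
        notes=f"variational Bayes posterior mean/SD ({fit_method}); log-odds scale",
    )


# ---------------------------------------------------------------------------
# development


@dataclass
class DevelopmentResult:
    continuous: ModelFit
    median_age: float
    subgroup_sizes: dict
    subgroup_fits: dict  # 'younger' / 'older' -> ModelFit

    def to_dict(self) -> dict:
        return {
            "continuous": self.continuous.to_dict(),
            "median_age": self.median_age,
            "subgroup_sizes": self.subgroup_sizes,
            "subgroup_fits": {
                k: (v.to_dict() if v is not None else None) for k, v in self.subgroup_fits.items()
            },
        }


def median_split_ages(ages: pd.Series) -> pd.Series:
    """Deterministic median split: age ≤ pooled median → 'younger'.

    Ties at the median always land in the younger half, so duplicated
    median ages never split across halves.
    """
    if ages.nunique() < 2:
        raise FitError("median split undefined: all ages identical")
    med = float(ages.median())
    return pd.Series(np.where(ages <= med, "younger", "older"), index=ages.index)


def development_analysis(domain_scores: pd.DataFrame, participants: pd.DataFrame) -> DevelopmentResult:
    """Does the group × domain gap change with age?

    First a continuous model (group × domain × standardized age, random
    intercept per participant), then a median split on pooled age
    (age ≤ median → younger; deterministic on ties) with per-subgroup
    group × domain models that keep age as a continuous covariate.
    """
    df = domain_scores.merge(
        participants[["participant_id", "group", "sex", "age_years"]], on="participant_id"
    )
    if df["age_years"].isna().any():
        raise FitError("development analysis requires age for every participant")
    ages = df.drop_duplicates("participant_id")["age_years"]
    df = add_effect_codes(df)
    df["age_z"] = (df["age_years"] - df["age_years"].mean()) / df["age_years"].std(ddof=1)

    cont = _fit_lmm_with_ladder(
        "development_continuous",
        "score ~ group_c * domain_c * age_z + sex_c",
        df,
        "participant_id",
        (({}, "intercept"),),
    )

    median_age = float(ages.median())
    df["age_half"] = median_split_ages(df["age_years"]).to_numpy()
    sizes, fits = {}, {}
    for half, sub in df.groupby("age_half", observed=True):
        sub = sub.copy()
        sub["age_z"] = (sub["age_years"] - sub["age_years"].mean()) / max(
            sub["age_years"].std(ddof=1), 1e-12
        )
        sizes[half] = {
            g: int(sub[sub["group"] == g]["participant_id"].nunique()) for g in ("TD", "ASD")
        }
        try:
            fits[half] = _fit_lmm_with_ladder(
                f"development_{half}",
                "score ~ group_c * domain_c + age_z + sex_c",
                sub,
                "participant_id",
                (({}, "intercept"),),
            )
        except FitError as exc:
            # tiny subgroups can leave a factor constant (e.g. one sex)
            warnings.warn(f"{half} subgroup model not estimable: {exc}", stacklevel=2)
            fits[half] = None
    return DevelopmentResult(
        continuous=cont, median_age=median_age, subgroup_sizes=sizes, subgroup_fits=fits
    )


# ---------------------------------------------------------------------------
# correlations


def partial_correlation(x, y, controls=None) -> tuple[float, int, float]:
    """Pearson correlation of ``x`` and ``y``, optionally partialling out
    ``controls`` by the residual method (OLS with intercept).

    Returns (r, n_complete, two-sided p); p uses t with n − 2 − k df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "shape") and np.size(controls) == 0):
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[mask], y[mask], Z[mask]
    n, k = len(x), Z.shape[1]
    if n < 4:
        raise FitError(f"partial correlation needs n >= 4 complete cases; got {n}")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise FitError("partial correlation undefined: constant residuals")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    if dof <= 0:
        raise FitError("not enough observations for the requested controls")
    r_ = min(max(r, -0.999999999999), 0.999999999999)
    t = r_ * np.sqrt(dof / (1 - r_**2))
    p = float(2 * stats.t.sf(abs(t), dof))
    return r, n, p


def correlation_suite(
    wide: pd.DataFrame,
    participants: pd.DataFrame,
    columns=None,
    controls: tuple = (),
    adjust: str = "holm",
) -> list[CorrelationResult]:
    """All pairwise (partial) Pearson correlations within each group.

    ``wide`` is one row per participant with measure columns (e.g. one
    composite per task); ``controls`` names participant columns (e.g.
    ``('age_years',)``).  p-values are adjusted per group across pairs
    (``holm``, ``bonferroni`` or ``fdr_bh``).
    """
    meta = participants.set_index("participant_id")
    df = wide.copy()
    if df.index.name != "participant_id":
        df = df.set_index("participant_id")
    df["group"] = df.index.map(meta["group"])
    for c in controls:
        df[c] = df.index.map(meta[c])
    if columns is None:
        columns = [c for c in wide.columns if c not in ("participant_id", "group")]

    out = []
    for group, sub in df.groupby("group", observed=True):
        results = []
        for i, cx in enumerate(columns):
            for cy in columns[i + 1 :]:
                ctrl = sub[list(controls)].to_numpy() if controls else None
                try:
                    r, n, p = partial_correlation(sub[cx], sub[cy], ctrl)
                except FitError:
                    continue
                results.append(
                    CorrelationResult(cx, cy, r, n, p, controls=tuple(controls), group=group)
                )
        if results:
            padj = multipletests([c.p for c in results], method=adjust)[1]
            for c, pa in zip(results, padj):
                c.p_adjusted = float(pa)
        out.extend(results)
    return out


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Fisher-z test for a difference between two independent correlations."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise FitError("|r| = 1: Fisher transform is infinite")
        if n < 4:
            raise FitError("need n >= 4 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return TestResult(
        test_name="fisher_z_correlation_difference",
        statistic=float(z),
        df=float("inf"),
        p=float(2 * stats.norm.sf(abs(z))),
        sidedness="two-sided",
        n=n1 + n2,
    )


# ---------------------------------------------------------------------------
# effect sizes and two-sample tests


def effect_size_g(a, b) -> float:
    """Bias-corrected standardized mean difference (Hedges g*).

    Cohen's d with pooled SD times the small-sample correction
    1 − 3 / (4·df − 1), df = n1 + n2 − 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise FitError("effect size needs at least 2 observations per group")
    df = n1 + n2 - 2
    pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
    if pooled == 0:
        raise FitError("zero pooled SD")
    d = (a.mean() - b.mean()) / pooled
    return float(d * (1 - 3.0 / (4 * df - 1)))


def welch_test(a, b, alternative: str = "two-sided", name: str = "welch_t") -> TestResult:
    """Welch two-sample t-test (unequal variances), with Hedges g*."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        sidedness=alternative,
        n=len(a) + len(b),
        effect_size_g=effect_size_g(a, b),
    )


# ---------------------------------------------------------------------------
# within-group error bars


def morey_within_se(
    data: pd.DataFrame,
    participant_col: str = "participant_id",
    condition_col: str = "task",
    value_col: str = "value",
) -> pd.Series:
    """Cousineau–Morey within-group standard error per condition.

    Values are participant-mean centered and grand-mean restored, the
    per-condition SE of the normalized values is then inflated by
    sqrt(M / (M − 1)) for M conditions.  With a single condition the
    correction is undefined and the ordinary SE is returned with a warning.
    """
    pivot = data.pivot_table(index=participant_col, columns=condition_col, values=value_col)
    M = pivot.shape[1]
    if M == 1:
        warnings.warn("only one condition: Morey correction undefined, returning plain SE", stacklevel=2)
        return pivot.std(ddof=1) / np.sqrt(pivot.count())
    grand = np.nanmean(pivot.to_numpy())
    normalized = pivot.sub(pivot.mean(axis=1, skipna=True), axis=0) + grand
    se = normalized.std(ddof=1) / np.sqrt(normalized.count())
    return se * np.sqrt(M / (M - 1.0))


def plot_group_task_means(
    measures: pd.DataFrame,
    participants: pd.DataFrame,
    value_col: str = "composite",
    out_path=None,
):
    """Bar chart of group × task means with Morey within-group error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = measures.merge(participants[["participant_id", "group"]], on="participant_id")
    tasks = sorted(df["task"].unique())
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.38
    xs = np.arange(len(tasks))
    for off, group in ((-width / 2, "TD"), (width / 2, "ASD")):
        sub = df[df["group"] == group]
        means = sub.groupby("task")[value_col].mean().reindex(tasks)
        se = morey_within_se(sub, condition_col="task", value_col=value_col).reindex(tasks)
        ax.bar(xs + off, means, width, yerr=se, capsize=3, label=group)
    ax.set_xticks(xs, tasks)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel(value_col)
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
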