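"""Group comparisons: fold change against a reference mean, t-tests, ANOVA.

Mutant-vs-wildtype comparisons are expressed as fold change: each
patch's property value is divided by the (published) wildtype group
mean of the same property, and the per-patch folds are tested against
the hypothetical value 1.0 with a two-tailed one-sample t-test.
Reference means are supplied as configuration scalars.  Two-way ANOVA
uses Type II sums of squares (tolerant of unbalanced designs) with
Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .qc import PatchSummary

__all__ = [
    "FoldChangeResult",
    "fold_change_test",
    "one_sample_t",
    "unpaired_t",
    "two_way_anova",
    "group_comparison",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """The conventional star code: * / ** / *** / **** at 0.05..0.0001."""
    if p is None or np.isnan(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


@dataclass
class FoldChangeResult:
    property_name: str
    fold_values: np.ndarray
    reference_mean: float
    mean_fold: float
    sem_fold: float
    t_statistic: float | None
    df: int
    p_value: float | None
    n_patches: int
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value) if self.p_value is not None else ""

    def summary(self) -> str:
        if self.degenerate:
            tail = "degenerate variance; t-test omitted"
        else:
            tail = (
                f"t = {self.t_statistic:.3f}, df = {self.df}, "
                f"p = {self.p_value:.4g} {self.stars}"
            )
        return (
            f"{self.property_name}: fold change {self.mean_fold:.3f} "
            f"+/- {self.sem_fold:.3f} (n = {self.n_patches}; {tail})"
        )


def fold_change_test(
    patch_values, reference_mean: float, property_name: str = ""
) -> FoldChangeResult:
    """Per-patch fold change vs a wildtype reference mean, tested vs 1.0."""
    values = np.asarray(patch_values, dtype=float)
    if reference_mean <= 0:
        raise ValueError("reference_mean must be > 0")
    if values.size < 2:
        raise ValueError("need >= 2 patches for a fold-change test")
    folds = values / reference_mean
    mean = float(folds.mean())
    sd = float(folds.std(ddof=1))
    sem = sd / np.sqrt(folds.size)
    df = folds.size - 1
    if sd == 0.0:
        return FoldChangeResult(
            property_name=property_name,
            fold_values=folds,
            reference_mean=reference_mean,
            mean_fold=mean,
            sem_fold=0.0,
            t_statistic=None,
            df=df,
            p_value=None,
            n_patches=folds.size,
            degenerate=True,
        )
    res = sps.ttest_1samp(folds, 1.0)
    return FoldChangeResult(
        property_name=property_name,
        fold_values=folds,
        reference_mean=reference_mean,
        mean_fold=mean,
        sem_fold=sem,
        t_statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        n_patches=folds.size,
    )


def one_sample_t(values, mu: float) -> dict:
    """Two-tailed one-sample Student t-test."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    if values.std(ddof=1) == 0.0:
        return {"t": None, "df": values.size - 1, "p": None, "degenerate": True}
    res = sps.ttest_1samp(values, mu)
    return {
        "t": float(res.statistic),
        "df": values.size - 1,
        "p": float(res.pvalue),
        "degenerate": False,
    }


def unpaired_t(a, b) -> dict:
    """Two-tailed unpaired Student t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    df = a.size + b.size - 2
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": df, "p": 1.0, "degenerate": True}
        return {"t": None, "df": df, "p": None, "degenerate": True}
    res = sps.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(res.statistic),
        "df": df,
        "p": float(res.pvalue),
        "degenerate": False,
    }


def two_way_anova(values, factor_a, factor_b, tukey: bool = True) -> dict:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Returns the ANOVA table (F, df, p per main effect and interaction)
    and Tukey HSD pairwise results over the crossed cells.  Raises on
    empty cells, names the cell; flags the degenerate zero-residual
    case instead of reporting infinite F.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (values.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    levels_a, levels_b = np.unique(fa), np.unique(fb)
    if levels_a.size < 2 or levels_b.size < 2:
        raise ValueError("each factor needs >= 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((fa == la) & (fb == lb)):
                raise ValueError(f"empty cell: ({la!r}, {lb!r})")
    df = pd.DataFrame({"y": values, "A": fa.astype(str), "B": fb.astype(str)})
    n_cells = levels_a.size * levels_b.size
    resid_df = values.size - n_cells

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    degenerate = model.ssr <= 1e-12 * max(np.var(values) * values.size, 1.0)
    if degenerate:
        table = None
    else:
        table = sm.stats.anova_lm(model, typ=2)
    out = {
        "anova": table,
        "residual_df": int(resid_df),
        "degenerate": degenerate,
        "model": model,
    }
    if tukey and not degenerate:
        cell = df["A"] + ":" + df["B"]
        out["tukey"] = pairwise_tukeyhsd(df["y"], cell)
    return out


def group_comparison(
    summaries: list[PatchSummary],
    reference_means: dict[str, float],
) -> pd.DataFrame:
    """Fold-change table for a mutant group against wildtype references.

    One row per property shared between the patch summaries and the
    reference map, mirroring the published table layout (mean +/- SEM,
    fold change +/- SEM, t, df, stars).  Excluded patches are skipped;
    properties without a reference are skipped with a warning column.
    """
    import warnings as _warnings

    active = [s for s in summaries if not s.excluded]
    props = sorted({p for s in active for p in s.properties})
    rows = []
    for prop in props:
        values = np.array(
            [s.properties[prop] for s in active if prop in s.properties],
            dtype=float,
        )
        values = values[~np.isnan(values)]
        if prop not in reference_means:
            _warnings.warn(f"no reference mean for property {prop!r}; skipped")
            continue
        if values.size < 2:
            _warnings.warn(f"property {prop!r} has n < 2; skipped")
            continue
        fc = fold_change_test(values, reference_means[prop], property_name=prop)
        rows.append(
            {
                "property": prop,
                "n": fc.n_patches,
                "mean": values.mean(),
                "sem": values.std(ddof=1) / np.sqrt(values.size),
                "fold_change": fc.mean_fold,
                "fold_sem": fc.sem_fold,
                "t": fc.t_statistic,
                "df": fc.df,
                "p": fc.p_value,
                "stars": fc.stars,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "property", "n", "mean", "sem", "fold_change", "fold_sem",
            "t", "df", "p", "stars",
        ],
    )
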