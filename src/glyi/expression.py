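"""Relative qPCR quantification (2^-ddCt) and group-comparison statistics.

Quantification follows the Livak 2^-ddCt method generalized to several
reference genes: per sample, technical replicates are averaged, the
target Ct is normalized against the arithmetic mean of the reference-gene
Cts (equivalent to a geometric mean of their linear quantities), and the
resulting dCt is referenced to the mean dCt of a calibrator group, whose
mean fold is therefore exactly 1.  Amplification efficiency is fixed at
2.0 by default (plain 2^-ddCt); an efficiency-corrected base is available.

Group comparison mirrors the field's standard workflow: fixed-effects
one- or two-factor ANOVA, pairwise decisions by Duncan's multiple range
test (studentized-range critical values with per-range protection level
alpha_p = 1 - (1 - alpha)^(p-1)), summarized as letter groups; two groups
fall back to a pooled-variance t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "ExpressionError",
    "FoldChangeResult",
    "GroupComparison",
    "delta_delta_ct",
    "duncan_letters",
    "compare_groups",
]

DEFAULT_REFERENCE_GENES = ("CDC", "RLI")


class ExpressionError(ValueError):
    pass


@dataclass
class FoldChangeResult:
    """Per-sample and per-group fold changes for one quantification run."""

    per_sample: pd.DataFrame     # sample, gene, grouping cols, dct, ddct, fold
    per_group: pd.DataFrame      # gene + grouping cols, mean fold, sd, n
    reference_genes: tuple[str, ...]
    calibrator: dict[str, str]


def _validate_ct(table: pd.DataFrame, reference_genes) -> None:
    required = {"sample", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ExpressionError(f"Ct table lacks column(s) {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ExpressionError("Ct values must be positive")
    for sample, group in table.groupby("sample"):
        absent = set(reference_genes) - set(group["gene"])
        if absent:
            raise ExpressionError(
                f"sample {sample!r} lacks reference gene(s) {sorted(absent)}"
            )


def delta_delta_ct(table: pd.DataFrame,
                   calibrator: dict[str, str],
                   reference_genes=DEFAULT_REFERENCE_GENES,
                   efficiency_base: float = 2.0) -> FoldChangeResult:
    """Relative expression by the 2^-ddCt method with multi-gene reference.

    ``table`` columns: sample, gene, ct, plus grouping columns such as
    condition and tissue (and optionally rep for technical replicates,
    averaged first).  ``calibrator`` names the reference group as
    {column: value}, e.g. {"condition": "control"}; the calibrator mean
    dCt is taken per gene within each combination of the remaining
    grouping columns, so e.g. shoots are calibrated against control
    shoots and roots against control roots.
    """
    reference_genes = tuple(reference_genes)
    _validate_ct(table, reference_genes)
    group_cols = [c for c in table.columns
                  if c not in ("sample", "gene", "ct", "rep")]
    for col in calibrator:
        if col not in group_cols:
            raise ExpressionError(f"calibrator column {col!r} not in table")
    strata = [c for c in group_cols if c not in calibrator]

    # average technical replicates
    ct = (table.groupby(["sample", "gene"] + group_cols, as_index=False)["ct"]
          .mean())

    ref = (ct[ct["gene"].isin(reference_genes)]
           .groupby("sample")["ct"].mean().rename("ref_ct"))
    targets = ct[~ct["gene"].isin(reference_genes)].merge(ref, on="sample")
    targets["dct"] = targets["ct"] - targets["ref_ct"]

    is_cal = np.ones(len(targets), dtype=bool)
    for col, value in calibrator.items():
        is_cal &= (targets[col] == value).to_numpy()
    if not is_cal.any():
        raise ExpressionError(f"no rows match calibrator {calibrator}")
    cal_keys = ["gene"] + strata
    cal_mean = (targets[is_cal].groupby(cal_keys)["dct"].mean()
                .rename("cal_dct").reset_index())
    merged = targets.merge(cal_mean, on=cal_keys, how="left")
    if merged["cal_dct"].isna().any():
        bad = merged.loc[merged["cal_dct"].isna(), cal_keys].drop_duplicates()
        raise ExpressionError(f"calibrator missing for strata:\n{bad}")
    merged["ddct"] = merged["dct"] - merged["cal_dct"]
    merged["fold"] = efficiency_base ** (-merged["ddct"])
    merged["log2_fold"] = np.log2(merged["fold"])

    per_group = (merged.groupby(["gene"] + group_cols, as_index=False)
                 .agg(fold_mean=("fold", "mean"), fold_sd=("fold", "std"),
                      log2_fold_mean=("log2_fold", "mean"), n=("fold", "size")))
    return FoldChangeResult(
        per_sample=merged, per_group=per_group,
        reference_genes=reference_genes, calibrator=dict(calibrator),
    )


# ---------------------------------------------------------------------------
# ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    anova: pd.DataFrame | None
    letters: dict[str, str]
    means: dict[str, float]
    p_value: float | None = None       # t-test p for the 2-group case
    method: str = "duncan"


def duncan_letters(values: dict[str, np.ndarray], alpha: float = 0.05,
                   mse: float | None = None, df_resid: float | None = None,
                   ) -> dict[str, str]:
    """Duncan's multiple range test, summarized as letter groups.

    Means are ranked; the range spanning p ordered means is significant
    when it exceeds q(1 - alpha_p, p, df) * sqrt(MSE / n_h) with the
    protection level alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic
    mean group size.  A range nested inside a non-significant wider range
    is never declared significant (standard step-down protection).  Groups
    sharing a letter are not significantly different.
    """
    names = list(values)
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if any(a.size < 2 for a in arrays.values()) and mse is None:
        raise ExpressionError("need >= 2 replicates per group (or external MSE)")
    if mse is None:
        df_resid = sum(a.size - 1 for a in arrays.values())
        if df_resid <= 0:
            raise ExpressionError("no residual degrees of freedom")
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_resid
    if mse <= 0:
        raise ExpressionError("degenerate zero within-group variance")
    n_h = len(arrays) / sum(1.0 / a.size for a in arrays.values())
    sem = np.sqrt(mse / n_h)

    order = sorted(names, key=lambda k: arrays[k].mean(), reverse=True)
    means = [arrays[k].mean() for k in order]
    k = len(order)

    def critical(p: int) -> float:
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        return stats.studentized_range.ppf(1.0 - alpha_p, p, df_resid) * sem

    # step-down: significant[i][j] for ordered means i < j
    sig = np.zeros((k, k), dtype=bool)
    nonsig_span = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            covered = any(
                nonsig_span[l2, h2]
                for l2 in range(0, lo + 1) for h2 in range(hi, k)
                if (l2, h2) != (lo, hi) and h2 - l2 + 1 > span - 1
            )
            if covered:
                nonsig_span[lo, hi] = True
                continue
            if means[lo] - means[hi] > critical(span):
                sig[lo, hi] = True
            else:
                nonsig_span[lo, hi] = True

    # letters: maximal runs of consecutive ordered groups with no
    # significant pair inside
    runs: list[tuple[int, int]] = []
    lo = 0
    while lo < k:
        hi = lo
        while hi + 1 < k and not any(
            sig[a, b] for a in range(lo, hi + 2) for b in range(a + 1, hi + 2)
        ):
            hi += 1
        runs.append((lo, hi))
        lo += 1
    # drop runs contained in another
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters = {name: "" for name in order}
    for idx, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for pos in range(lo, hi + 1):
            letters[order[pos]] += letter
    return letters


def compare_groups(values: dict[str, np.ndarray] | pd.DataFrame,
                   design: str = "one_factor",
                   alpha: float = 0.05) -> GroupComparison:
    """Fixed-effects ANOVA with Duncan letter grouping.

    ``values`` is either {group label: replicate array} (one factor) or a
    long-format frame with columns value, factor1[, factor2] for the
    two-factor design (letters are then computed over the factor1 x
    factor2 cell means).  Two groups are additionally compared by a
    pooled-variance t-test.
    """
    if design not in ("one_factor", "two_factor"):
        raise ExpressionError(f"unknown design {design!r}")
    if isinstance(values, pd.DataFrame):
        if design == "two_factor":
            df = values.copy()
            needed = {"value", "factor1", "factor2"}
            if not needed <= set(df.columns):
                raise ExpressionError(f"two-factor frame needs columns {needed}")
            model = smf.ols("value ~ C(factor1) * C(factor2)", data=df).fit()
            anova = sm.stats.anova_lm(model, typ=2)
            cells = {
                f"{f1}:{f2}": g["value"].to_numpy()
                for (f1, f2), g in df.groupby(["factor1", "factor2"])
            }
            letters = duncan_letters(cells, alpha=alpha)
            means = {k: float(np.mean(v)) for k, v in cells.items()}
            return GroupComparison(anova=anova, letters=letters, means=means)
        values = {str(k): g["value"].to_numpy()
                  for k, g in values.groupby("factor1")}

    groups = {str(k): np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2:
        raise ExpressionError("need at least 2 groups")
    if any(g.size < 2 for g in groups.values()):
        raise ExpressionError("need at least 2 replicates per group")
    if all(np.ptp(g) == 0 for g in groups.values()):
        raise ExpressionError("degenerate zero within-group variance")
    long = pd.DataFrame({
        "value": np.concatenate(list(groups.values())),
        "factor1": np.concatenate(
            [[k] * len(v) for k, v in groups.items()]
        ),
    })
    model = smf.ols("value ~ C(factor1)", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    letters = duncan_letters(groups, alpha=alpha)
    means = {k: float(v.mean()) for k, v in groups.items()}
    p_value = None
    if len(groups) == 2:
        a, b = groups.values()
        p_value = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return GroupComparison(anova=anova, letters=letters, means=means,
                           p_value=p_value)
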