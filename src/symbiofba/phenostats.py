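"""Performance metrics, two-sample tests, FDR control, metabolite screening.

Small, exactly specified procedures used around the metabolic analyses:

* insect performance metrics — larval relative growth rate
  ``RGR = ln(w_day7 / w_day2) / 5`` (mg·mg⁻¹·day⁻¹) and intrinsic rate of
  increase ``r_m = 0.745 · ln(M_d) / d`` (day⁻¹) from total progeny ``M_d``
  and days-to-first-reproduction ``d``;
* two-sample t tests computable either from raw samples or from printed
  summaries (mean ± SE, n) — the summary form reproduces the pooled t
  exactly when group sizes are equal;
* native Benjamini–Hochberg step-up adjustment;
* the two-stage metabolite screen: a per-feature t-test prefilter, then a
  mixed model (symbiont status fixed, host genotype random) on the
  candidates, with BH adjustment of the stage-2 p values.  Mixed-model
  fitting is delegated to statsmodels' REML implementation; the screening
  orchestration, candidate selection and FDR step are native.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

TestMethod = Literal["pooled-t", "welch-t", "mann-whitney"]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table form of one group: mean ± SE with replicate count."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError(f"standard error must be >= 0, got {self.se}")
        if self.n < 2:
            raise ValidationError(f"need n >= 2 replicates, got {self.n}")

    @classmethod
    def from_samples(cls, x: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(x, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"need >= 2 samples, got {arr.size}")
        return cls(
            mean=float(arr.mean()),
            se=float(arr.std(ddof=1) / math.sqrt(arr.size)),
            n=int(arr.size),
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: TestMethod


def pooled_t_summary(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Two-sample t test from summary statistics.

    ``t = (m₁ − m₂) / √(se₁² + se₂²)`` with ``df = n₁ + n₂ − 2``; identical
    to the textbook pooled-variance t whenever n₁ = n₂.  Two-sided p.
    """
    denom = math.hypot(g1.se, g2.se)
    diff = g1.mean - g2.mean
    if denom == 0.0:
        if diff == 0.0:
            t = 0.0
        else:
            raise ValidationError(
                "both standard errors are zero with unequal means: the t "
                "statistic is infinite"
            )
    else:
        t = diff / denom
    df = g1.n + g2.n - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=t, df=float(df), p=float(p), method="pooled-t")


def welch_t_summary(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Welch's t from summaries, with Welch–Satterthwaite df."""
    v1, v2 = g1.se**2, g2.se**2
    denom = math.sqrt(v1 + v2)
    if denom == 0.0:
        return pooled_t_summary(g1, g2)
    t = (g1.mean - g2.mean) / denom
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=t, df=float(df), p=float(p), method="welch-t")


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p values, order-preserving.

    ``p_adj(i) = min_{j >= i} ( p(j) · m / j )`` over the ascending order,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return [float(v) for v in out]


def relative_growth_rate(w_day2: float, w_day7: float) -> float:
    """Larval RGR = ln(w₇ / w₂) / 5, in mg·mg⁻¹·day⁻¹ over the 5-day assay."""
    if w_day2 <= 0 or w_day7 <= 0:
        raise ValidationError(f"weights must be positive, got ({w_day2}, {w_day7})")
    return math.log(w_day7 / w_day2) / 5.0


def intrinsic_rate(Md: float, d: float) -> float:
    """Intrinsic rate of increase r_m = 0.745 · ln(M_d) / d (day⁻¹).

    ``M_d`` is total progeny over twice the pre-reproductive period ``d``.
    """
    if Md < 1:
        raise ValidationError(f"progeny count must be >= 1, got {Md}")
    if d <= 0:
        raise ValidationError(f"days to first reproduction must be > 0, got {d}")
    return 0.745 * math.log(Md) / d


# ---------------------------------------------------------------------------
# advisory distribution checks


@dataclass(frozen=True)
class AssumptionFlags:
    """Advisory normality/variance-homogeneity flags; never switch tests
    silently — the caller chooses the method explicitly."""

    shapiro_p: tuple[float, float]
    bartlett_p: float

    @property
    def normality_ok(self) -> bool:
        return min(self.shapiro_p) > 0.05

    @property
    def homoscedastic(self) -> bool:
        return self.bartlett_p > 0.05


def check_assumptions(x1: Sequence[float], x2: Sequence[float]) -> AssumptionFlags:
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return AssumptionFlags(
        shapiro_p=(float(sps.shapiro(x1).pvalue), float(sps.shapiro(x2).pvalue)),
        bartlett_p=float(sps.bartlett(x1, x2).pvalue),
    )


def two_sample_test(
    x1: Sequence[float],
    x2: Sequence[float],
    method: TestMethod = "pooled-t",
) -> TestResult:
    """Two-sample test on raw samples with an explicitly chosen method."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("each group needs >= 2 samples")
    if method == "pooled-t":
        res = sps.ttest_ind(x1, x2, equal_var=True)
        df = x1.size + x2.size - 2
    elif method == "welch-t":
        res = sps.ttest_ind(x1, x2, equal_var=False)
        df = float(res.df)
    elif method == "mann-whitney":
        res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method="asymptotic")
        return TestResult(
            statistic=float(res.statistic), df=float("nan"),
            p=float(res.pvalue), method=method,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        statistic=float(res.statistic), df=float(df), p=float(res.pvalue), method=method
    )


# ---------------------------------------------------------------------------
# two-stage metabolite screen


def metabolite_screen(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    alpha_stage1: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen features (rows) for a symbiont-status effect.

    ``matrix``: features × samples abundance table (log scale recommended).
    ``design``: one row per sample with columns ``sample``, ``status``
    (two levels) and ``genotype``.

    Stage 1 runs an uncorrected two-sample t test per feature and flags
    candidates at ``alpha_stage1``.  Stage 2 refits each candidate with a
    linear mixed model (status fixed, genotype random intercept, REML via
    statsmodels) and BH-adjusts the stage-2 p values.  With a single
    genotype the mixed stage is impossible; the screen falls back to the
    t-test p values with a logged warning.

    Returns one row per feature: ``t_stat, p_t, candidate, mixed_stat,
    p_mixed, p_adj, significant, note``.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    missing = [c for c in ("status", "genotype") if c not in design.columns]
    if missing:
        raise ValidationError(f"design table lacks columns {missing}")
    samples = [c for c in matrix.columns if c in design.index]
    if len(samples) != matrix.shape[1]:
        unmatched = set(matrix.columns) - set(samples)
        raise ValidationError(f"samples missing from design: {sorted(unmatched)}")
    status = design.loc[samples, "status"]
    levels = sorted(status.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 status levels, got {levels}")
    genotype = design.loc[samples, "genotype"]
    n_genotypes = genotype.nunique()
    mixed_possible = n_genotypes >= 2
    if not mixed_possible:
        warnings.warn(
            "only one genotype present: falling back to t-test-only screening",
            stacklevel=2,
        )

    g1_cols = [s for s in samples if status[s] == levels[0]]
    g2_cols = [s for s in samples if status[s] == levels[1]]

    records = []
    for feature, row in matrix.iterrows():
        x1 = row[g1_cols].to_numpy(dtype=float)
        x2 = row[g2_cols].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x1, x2])) == 0.0:
            records.append(
                {
                    "feature": feature, "t_stat": float("nan"), "p_t": float("nan"),
                    "candidate": False, "mixed_stat": float("nan"),
                    "p_mixed": float("nan"), "note": "constant feature, skipped",
                }
            )
            continue
        res = sps.ttest_ind(x1, x2, equal_var=True)
        records.append(
            {
                "feature": feature, "t_stat": float(res.statistic),
                "p_t": float(res.pvalue), "candidate": bool(res.pvalue < alpha_stage1),
                "mixed_stat": float("nan"), "p_mixed": float("nan"), "note": "",
            }
        )

    for rec in records:
        if not rec["candidate"]:
            continue
        if not mixed_possible:
            rec["mixed_stat"] = rec["t_stat"]
            rec["p_mixed"] = rec["p_t"]
            rec["note"] = "t-only fallback (single genotype)"
            continue
        stat, p = _mixed_status_test(
            matrix.loc[rec["feature"], samples].to_numpy(dtype=float),
            status.to_numpy(), genotype.to_numpy(),
        )
        rec["mixed_stat"], rec["p_mixed"] = stat, p

    table = pd.DataFrame.from_records(records).set_index("feature")
    table["p_adj"] = float("nan")
    cand = table.index[table["candidate"] & table["p_mixed"].notna()]
    if len(cand):
        table.loc[cand, "p_adj"] = bh_adjust(table.loc[cand, "p_mixed"].tolist())
    table["significant"] = table["p_adj"] < alpha
    return table


def _mixed_status_test(y: np.ndarray, status: np.ndarray, genotype: np.ndarray) -> tuple[float, float]:
    """Wald test of the fixed status effect in a random-intercept model.

    Delegates REML fitting to statsmodels MixedLM; convergence warnings on
    near-zero variance components are routine for screened features and are
    suppressed.  Because status varies at the genotype level, the Wald
    statistic is referred to a t distribution with (number of genotypes − 2)
    degrees of freedom — with a handful of genotypes the asymptotic normal
    reference would be badly anti-conservative.
    """
    import statsmodels.api as sm

    frame = pd.DataFrame(
        {"y": y, "status": pd.Categorical(status), "genotype": genotype}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula("y ~ status", groups="genotype", data=frame)
        fit = model.fit(reml=True)
    name = [n for n in fit.fe_params.index if n.startswith("status")][0]
    stat = float(fit.fe_params[name] / fit.bse[name])
    df = max(len(np.unique(genotype)) - 2, 1)
    p = float(2.0 * sps.t.sf(abs(stat), df))
    return stat, p
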