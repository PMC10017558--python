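"""Repeated-measures comparisons of PCAT_MA across acquisition conditions.

Each vessel is measured under every condition of a within factor (tube
voltage, or reconstruction regime), so the natural analyses are a one-way
within-subjects (repeated-measures) ANOVA for the tube-voltage effect and
two-sided paired-sample t tests post hoc, at alpha = 0.05. Both statistics
are computed from their closed-form sum-of-squares / difference-score
definitions so that small cases can be checked by hand:

    F = MS_treatment / MS_error,  df = (k - 1, (n - 1)(k - 1))
    t = mean(d) / (sd(d) / sqrt(n)),  df = n - 1

Condition summaries are reported as mean +/- standard error. Post hoc p
values are reported raw by default (Bonferroni available behind a flag),
and no sphericity correction is applied unless requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import round_half_up
from .measurement import PCATMeasurement

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class RMDesign:
    """Complete subjects-by-levels response matrix for a within factor."""

    subjects: list[str]
    levels: list
    responses: np.ndarray  # (n_subjects, n_levels)
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        n, k = self.responses.shape
        if len(self.subjects) != n or len(self.levels) != k:
            raise StatsError("responses shape must be (n_subjects, n_levels)")
        if n < 2 or k < 2:
            raise StatsError("need at least 2 subjects and 2 levels")
        if np.isnan(self.responses).any():
            raise StatsError("design must be complete (no missing cells)")

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, subject: str, within: str, response: str,
        alpha: float = DEFAULT_ALPHA,
    ) -> "RMDesign":
        """Build a complete design from a long table, dropping incomplete subjects."""
        wide = df.pivot_table(index=subject, columns=within, values=response, aggfunc="mean")
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            logger.info("dropped %d incomplete subject(s) from the %s design", dropped, within)
        if len(complete) < 2:
            raise StatsError(
                f"fewer than 2 complete subjects for within-factor {within!r} "
                f"(missing cells: {sorted(set(wide.columns))})"
            )
        return cls(
            subjects=[str(s) for s in complete.index],
            levels=list(complete.columns),
            responses=complete.to_numpy(),
            alpha=alpha,
        )


@dataclass
class RMAnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    ss_treatment: float
    ss_subjects: float
    ss_error: float
    degenerate: bool = False
    gg_epsilon: float | None = None


def rm_anova(design: RMDesign, gg_correction: bool = False) -> RMAnovaResult:
    """One-way within-subjects ANOVA from the standard SS decomposition.

    With ``gg_correction`` the Greenhouse-Geisser epsilon shrinks both
    degrees of freedom before the p value is taken (off by default).
    A zero error variance (exactly collinear subjects) is flagged as
    degenerate; its p is reported at the machine boundary.
    """
    x = design.responses
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    level_means = x.mean(axis=0)
    ss_subjects = k * float(((subj_means - grand) ** 2).sum())
    ss_treatment = n * float(((level_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_treatment
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_treat = ss_treatment / df1
    ms_error = ss_error / df2

    eps = None
    if ms_error <= max(abs(ms_treat), 1.0) * np.finfo(float).eps * 1e3:
        if ss_treatment == 0.0:
            return RMAnovaResult(0.0, (df1, df2), 1.0, 0.0, ss_subjects, ss_error,
                                 degenerate=ms_error <= 0)
        return RMAnovaResult(
            np.inf, (df1, df2), 0.0, ss_treatment, ss_subjects, ss_error, degenerate=True
        )
    F = ms_treat / ms_error
    if gg_correction:
        eps = _gg_epsilon(x)
        p = float(sps.f.sf(F, eps * df1, eps * df2))
    else:
        p = float(sps.f.sf(F, df1, df2))
    return RMAnovaResult(float(F), (df1, df2), p, ss_treatment, ss_subjects, ss_error,
                         gg_epsilon=eps)


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the level covariance matrix."""
    k = x.shape[1]
    S = np.cov(x.T, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


def paired_t(x, y, alpha: float = DEFAULT_ALPHA) -> PairedTResult:
    """Two-sided paired-sample t test from the difference scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired_t needs two equal-length 1D samples")
    n = x.size
    if n < 2:
        raise StatsError("paired_t needs at least 2 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(0.0, df, 1.0, 0.0, degenerate=True)
        return PairedTResult(np.inf if md > 0 else -np.inf, df, 0.0, md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTResult(float(t), df, p, md)


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Reporting-rule percentage, rounded half away from zero (21/36 -> 58.3)."""
    if denominator <= 0:
        raise StatsError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Study-level report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    anova_by_recon: dict[str, RMAnovaResult]
    ttest_ir_vs_fbp_by_kvp: dict[int, PairedTResult]
    condition_summary: pd.DataFrame  # kvp, recon, n, mean_hu, se_hu
    alpha: float = DEFAULT_ALPHA
    bonferroni: bool = False

    def tests_frame(self) -> pd.DataFrame:
        """All test statistics as one tidy table (for CSV export)."""
        rows = []
        for recon, res in sorted(self.anova_by_recon.items()):
            rows.append({
                "test": "rm_anova_kvp", "condition": recon,
                "statistic": res.F, "df1": res.df[0], "df2": res.df[1],
                "p": res.p, "degenerate": res.degenerate,
            })
        for kvp, res in sorted(self.ttest_ir_vs_fbp_by_kvp.items()):
            rows.append({
                "test": "paired_t_ir_vs_fbp", "condition": str(kvp),
                "statistic": res.t, "df1": res.df, "df2": np.nan,
                "p": res.p, "degenerate": res.degenerate,
            })
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = []
        for recon, res in sorted(self.anova_by_recon.items()):
            flag = " (degenerate: zero error variance)" if res.degenerate else ""
            lines.append(
                f"Tube-voltage effect ({recon}): F({res.df[0]}, {res.df[1]}) = "
                f"{res.F:.3f}, p = {res.p:.3g}{flag}"
            )
        m = len(self.ttest_ir_vs_fbp_by_kvp)
        for kvp, res in sorted(self.ttest_ir_vs_fbp_by_kvp.items()):
            p = min(res.p * m, 1.0) if self.bonferroni else res.p
            flag = " (degenerate: zero difference variance)" if res.degenerate else ""
            lines.append(
                f"IR vs FBP at {kvp} kVp: t({res.df}) = {res.t:.3f}, "
                f"p = {p:.3g}, mean diff = {res.mean_diff:+.2f} HU{flag}"
            )
        lines.append("")
        lines.append("Condition means (mean +/- SE, HU):")
        for _, r in self.condition_summary.iterrows():
            lines.append(
                f"  {int(r['kvp'])} kVp {r['recon']}: {r['mean_hu']:.2f} +/- "
                f"{r['se_hu']:.2f} (n = {int(r['n'])})"
            )
        return "\n".join(lines)


def run_study_stats(
    measurements: list[PCATMeasurement],
    alpha: float = DEFAULT_ALPHA,
    bonferroni: bool = False,
    gg_correction: bool = False,
) -> StudyReport:
    """The study's comparison battery on a set of PCAT measurements.

    Per reconstruction regime, a repeated-measures ANOVA across tube
    voltages (vessels as subjects); per tube voltage, a paired t test
    between IR and FBP; and per condition, mean +/- SE.
    """
    df = pd.DataFrame(
        {
            "vessel_id": [m.vessel_id for m in measurements],
            "kvp": [m.kvp for m in measurements],
            "recon": [m.recon for m in measurements],
            "pcat_ma_hu": [m.pcat_ma_hu for m in measurements],
        }
    )
    kvps = sorted(df["kvp"].unique())
    recons = sorted(df["recon"].unique())
    if len(kvps) < 2 or len(recons) < 2:
        missing = []
        if len(kvps) < 2:
            missing.append("a second tube voltage")
        if len(recons) < 2:
            missing.append("a second reconstruction regime")
        raise StatsError("insufficient design: missing " + " and ".join(missing))

    anova_by_recon = {}
    for recon in recons:
        design = RMDesign.from_long(
            df[df["recon"] == recon], "vessel_id", "kvp", "pcat_ma_hu", alpha=alpha
        )
        anova_by_recon[recon] = rm_anova(design, gg_correction=gg_correction)

    ttests = {}
    for kvp in kvps:
        sub = df[df["kvp"] == kvp]
        wide = sub.pivot_table(index="vessel_id", columns="recon", values="pcat_ma_hu").dropna()
        if {"IR", "FBP"}.issubset(wide.columns) and len(wide) >= 2:
            ttests[int(kvp)] = paired_t(wide["IR"].to_numpy(), wide["FBP"].to_numpy(), alpha)

    summary = (
        df.groupby(["kvp", "recon"])["pcat_ma_hu"]
        .agg(n="count", mean_hu="mean", se_hu=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
        .sort_values(["kvp", "recon"], ignore_index=True)
    )
    return StudyReport(
        anova_by_recon=anova_by_recon,
        ttest_ir_vs_fbp_by_kvp=ttests,
        condition_summary=summary,
        alpha=alpha,
        bonferroni=bonferroni,
    )
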