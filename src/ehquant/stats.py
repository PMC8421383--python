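"""Two-group comparison workflow and the validation comparison suite.

Each comparison first checks normality of both samples (Shapiro-Wilk at
alpha 0.05); if both pass, a two-sided Welch t-test is used, otherwise
a two-sided Mann-Whitney U test.  Welch's unequal-variance form is the
default because group SDs in this domain can differ several-fold.  All
p-values are reported raw (no multiple-testing correction) and the
branch taken is always recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
ALPHA_NORMALITY = 0.05


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of one two-group comparison, with all intermediates."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    method_used: str  # 't_test' (Welch) or 'mann_whitney'
    statistic: float
    p_value: float
    alpha: float
    significant: bool

    def summary(self) -> str:
        lines = [
            f"{self.label_a} (n={self.n_a}, mean={self.mean_a:.3f}, SD={self.sd_a:.3f})"
            f" vs {self.label_b} (n={self.n_b}, mean={self.mean_b:.3f}, SD={self.sd_b:.3f})",
            f"  normality p: {self.normality_p_a:.3g} / {self.normality_p_b:.3g}"
            f" -> {self.method_used}",
            f"  statistic = {self.statistic:.4g}, p = {self.p_value:.3g}"
            f" ({'significant' if self.significant else 'not significant'}"
            f" at alpha = {self.alpha})",
        ]
        return "\n".join(lines)


def _normality_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; a zero-variance sample is treated as
    decisively non-normal (the test statistic is undefined there)."""
    if np.ptp(x) == 0.0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def compare_groups(
    a,
    b,
    alpha: float = ALPHA,
    alpha_normality: float = ALPHA_NORMALITY,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparisonResult:
    """Normality-gated two-group comparison (Welch t or Mann-Whitney U)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("insufficient sample: each group needs n >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    pa, pb = _normality_p(a), _normality_p(b)
    if pa > alpha_normality and pb > alpha_normality:
        res = sps.ttest_ind(a, b, equal_var=False)
        method = "t_test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        method = "mann_whitney"
    p = float(res.pvalue)
    return GroupComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        normality_p_a=pa,
        normality_p_b=pb,
        method_used=method,
        statistic=float(res.statistic),
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# validation comparison plan

DEFAULT_COMPARISONS: tuple[dict, ...] = (
    dict(name="cochlea_affected_vs_control", site="cochlea", a=("affected", None), b=("control", None)),
    dict(name="vestibule_affected_vs_control", site="vestibule", a=("affected", None), b=("control", None)),
    dict(name="cochlea_histo_vs_mri", site="cochlea", a=("affected", "histo_area"), b=("affected", "mri_negative_pixel")),
    dict(name="vestibule_histo_vs_mri", site="vestibule", a=("affected", "histo_area"), b=("affected", "mri_negative_pixel")),
    dict(name="saccule_vs_utricle", site=("saccule", "utricle"), a=("affected", None), b=("affected", None)),
) + tuple(
    dict(
        name=f"canal_{canal}_{region}_affected_vs_unaffected",
        site=f"canal_{canal}_{region}",
        a=("affected", None),
        b=("unaffected", None),
    )
    for canal in ("anterior", "lateral", "posterior")
    for region in ("ampullary", "nonampullary")
)


def _select(df: pd.DataFrame, site: str, side: str, method: str | None) -> np.ndarray:
    sel = (df["site"] == site) & (df["side"] == side)
    if method is not None and "method" in df.columns:
        sel &= df["method"] == method
    return df.loc[sel, "ratio"].to_numpy()


def run_validation_suite(
    measurements: pd.DataFrame,
    comparisons: tuple[dict, ...] = DEFAULT_COMPARISONS,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run the configured group comparisons over a tidy measurement table
    (columns: site, side, method, ratio).

    Raises if a configured comparison has a missing or undersized group,
    naming the comparison.  Returns one row per comparison.
    """
    rows = []
    for comp in comparisons:
        site = comp["site"]
        site_a, site_b = site if isinstance(site, tuple) else (site, site)
        side_a, method_a = comp["a"]
        side_b, method_b = comp["b"]
        a = _select(measurements, site_a, side_a, method_a)
        b = _select(measurements, site_b, side_b, method_b)
        if a.size < 3 or b.size < 3:
            raise ValueError(
                f"comparison {comp['name']!r}: missing or insufficient group "
                f"(n_a={a.size}, n_b={b.size})"
            )
        r = compare_groups(
            a,
            b,
            alpha=alpha,
            label_a=f"{site_a}/{side_a}" + (f"/{method_a}" if method_a else ""),
            label_b=f"{site_b}/{side_b}" + (f"/{method_b}" if method_b else ""),
        )
        rows.append(
            dict(
                comparison=comp["name"],
                n_a=r.n_a,
                n_b=r.n_b,
                mean_a=r.mean_a,
                mean_b=r.mean_b,
                sd_a=r.sd_a,
                sd_b=r.sd_b,
                method_used=r.method_used,
                statistic=r.statistic,
                p_value=r.p_value,
                significant=r.significant,
            )
        )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of a validation report table."""
    lines = []
    for _, r in report.iterrows():
        flag = "*" if r["significant"] else " "
        lines.append(
            f"{flag} {r['comparison']:45s} {r['method_used']:12s} "
            f"mean {r['mean_a']:.3f} vs {r['mean_b']:.3f}  p={r['p_value']:.3g}"
        )
    return "\n".join(lines)
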