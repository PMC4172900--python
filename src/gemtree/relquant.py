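"""Relative quantification and expression-level statistics.

Fold changes from paired qRT-PCR cycle thresholds by the comparative
2^-ddCt method (target gene normalised to a housekeeping gene in tumor and
matched normal tissue), one-sample t-tests of log fold change against zero,
Pearson correlations between log expression levels, and gene-vs-phenotype
association tests (two-sample t / one-way ANOVA on log values).

Test statistics are computed from the textbook formulas with p-values from
scipy's t and F distributions; degenerate (zero-variance) inputs yield a
flagged result with NaN p rather than an exception, so a many-gene pipeline
does not abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "FoldChangeSummary",
    "CorrelationResult",
    "AssociationResult",
    "relative_expression",
    "fold_change_test",
    "correlate",
    "phenotype_association",
    "fold_change_table",
    "correlation_table",
    "fold_changes_from_ct",
]


@dataclass(frozen=True)
class CtRecord:
    """Paired cycle thresholds for one patient and one target gene.

    ct_ref_* are the housekeeping (reference) gene's thresholds in the same
    samples. Values far outside the usual 0-45 cycle range are suspicious but
    not rejected; non-finite values are errors.
    """

    patient_id: str
    gene: str
    ct_target_tumor: float
    ct_ref_tumor: float
    ct_target_normal: float
    ct_ref_normal: float

    def __post_init__(self) -> None:
        for name in ("ct_target_tumor", "ct_ref_tumor", "ct_target_normal", "ct_ref_normal"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} is not finite ({v!r})")


@dataclass(frozen=True)
class FoldChangeSummary:
    gene: str
    n: int
    median_fc: float
    q1_fc: float
    q3_fc: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    n: int
    r: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class AssociationResult:
    test: str  # "t" or "anova"
    statistic: float
    p_value: float
    df: tuple
    degenerate: bool = False


def relative_expression(record: CtRecord) -> float:
    """2^-ddCt with ddCt = (Ct_target - Ct_ref)_tumor - (Ct_target - Ct_ref)_normal.

    Shifting all four Ct values by a constant leaves the result unchanged.
    """
    ddct = (record.ct_target_tumor - record.ct_ref_tumor) - (
        record.ct_target_normal - record.ct_ref_normal
    )
    return float(2.0 ** (-ddct))


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics (numpy default)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(q1), float(med), float(q3)


def fold_change_test(fold_changes, gene: str = "", log_base: float = math.e) -> FoldChangeSummary:
    """One-sample two-sided t-test of mean log fold change against 0.

    The t statistic and p-value do not depend on the log base; the median and
    quartiles are reported on the original fold-change scale. All logs with
    zero sample variance give a degenerate flag (p undefined).
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.size < 2:
        raise ValueError("need at least 2 fold changes")
    if np.any(fc <= 0) or not np.all(np.isfinite(fc)):
        raise ValueError("fold changes must be positive and finite")
    logs = np.log(fc) / math.log(log_base)
    n = fc.size
    q1, med, q3 = _quartiles(fc)
    sd = logs.std(ddof=1)
    if sd == 0.0:
        return FoldChangeSummary(gene, n, med, q1, q3, float("nan"), float("nan"), True)
    t = logs.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return FoldChangeSummary(gene, n, med, q1, q3, float(t), float(p), False)


def correlate(x, y, gene_a: str = "", gene_b: str = "", log: bool = False) -> CorrelationResult:
    """Pearson correlation with a two-sided p from the t transform.

    With ``log=True`` the inputs are log-transformed first (the convention for
    fold-change data); otherwise they are used as given.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if log:
        if np.any(xv <= 0) or np.any(yv <= 0):
            raise ValueError("log=True requires positive values")
        xv, yv = np.log(xv), np.log(yv)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return CorrelationResult(gene_a, gene_b, n, float("nan"), float("nan"), True)
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(gene_a, gene_b, n, r, float(p), False)


def phenotype_association(log_values, groups) -> AssociationResult:
    """Two-sample pooled-variance t-test (2 groups) or one-way ANOVA (>2).

    ``log_values`` are already on the log scale; ``groups`` are categorical
    labels. Every group needs at least 2 observations.
    """
    v = np.asarray(log_values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for lev in levels:
        s = v[g == lev]
        if s.size < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
        samples.append(s)

    if len(levels) == 2:
        a, b = samples
        na, nb = a.size, b.size
        df = na + nb - 2
        pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if pooled == 0.0:
            if a.mean() == b.mean():
                return AssociationResult("t", 0.0, 1.0, (df,), False)
            return AssociationResult("t", float("nan"), float("nan"), (df,), True)
        t = (a.mean() - b.mean()) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(abs(t), df=df)
        return AssociationResult("t", float(t), float(p), (df,), False)

    n = v.size
    k = len(levels)
    grand = v.mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    df1, df2 = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AssociationResult("anova", 0.0, 1.0, (df1, df2), False)
        return AssociationResult("anova", float("nan"), float("nan"), (df1, df2), True)
    f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    return AssociationResult("anova", float(f), float(p), (df1, df2), False)


# ---------------------------------------------------------------------------
# Table-level conveniences (CohortTable / Ct CSV in, tidy frames out)
# ---------------------------------------------------------------------------


def fold_change_table(cohort: pd.DataFrame, genes) -> pd.DataFrame:
    """FoldChangeSummary rows for each ``<gene>_fc`` column of a cohort table."""
    rows = []
    for gene in genes:
        s = fold_change_test(cohort[f"{gene}_fc"].to_numpy(dtype=float), gene=gene)
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


def correlation_table(cohort: pd.DataFrame, genes) -> pd.DataFrame:
    """Pairwise log-scale Pearson correlations between gene fold changes."""
    rows = []
    genes = list(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            res = correlate(
                cohort[f"{a}_fc"].to_numpy(dtype=float),
                cohort[f"{b}_fc"].to_numpy(dtype=float),
                gene_a=a,
                gene_b=b,
                log=True,
            )
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def fold_changes_from_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`relative_expression` to a long-format Ct table.

    Expects columns patient_id, gene, ct_target_tumor, ct_ref_tumor,
    ct_target_normal, ct_ref_normal; returns a wide table with one
    ``<gene>_fc`` column per gene.
    """
    required = [
        "patient_id",
        "gene",
        "ct_target_tumor",
        "ct_ref_tumor",
        "ct_target_normal",
        "ct_ref_normal",
    ]
    missing = [c for c in required if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    fc = ct_table.apply(
        lambda row: relative_expression(
            CtRecord(
                str(row["patient_id"]),
                str(row["gene"]),
                float(row["ct_target_tumor"]),
                float(row["ct_ref_tumor"]),
                float(row["ct_target_normal"]),
                float(row["ct_ref_normal"]),
            )
        ),
        axis=1,
    )
    long = ct_table[["patient_id", "gene"]].copy()
    long["fc"] = fc
    wide = long.pivot(index="patient_id", columns="gene", values="fc")
    wide.columns = [f"{g}_fc" for g in wide.columns]
    return wide.reset_index()
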