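"""Seed-development expression profile groups and 2^-ddCt qPCR analysis.

Three-stage FPKM vectors (20, 40 and 60 days after flowering) are assigned
to one of five profile classes: ``not_expressed`` (all stages below an FPKM
floor), group ``I`` (early peak at DAF20), ``II`` (peak at DAF40), ``III``
(trough at DAF40) or ``IV`` (expressed without a fold-change pivot, i.e.
broadly high across stages).  The peak/trough calls use a configurable fold
threshold (default 2).

qPCR relative expression follows the 2^-ddCt method: per-replicate
dCt = Ct(target) - Ct(internal control gene); ddCt is the mean dCt of the
treatment minus the mean dCt of the reference condition; fold = 2^-ddCt.
The standard error is taken over per-replicate folds and significance from a
two-sided Student's t test on the dCt values (Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("DAF20", "DAF40", "DAF60")

PROFILE_LABELS = ("not_expressed", "I", "II", "III", "IV")


def classify_profile(
    fpkm: tuple[float, float, float],
    floor: float = 1.0,
    fold: float = 2.0,
) -> str:
    """Assign a three-stage FPKM vector to one profile group.

    Rules, checked in order on (DAF20, DAF40, DAF60):

    - ``not_expressed``: all three below ``floor``;
    - ``I``: DAF20 at least ``fold`` times the larger of DAF40/DAF60;
    - ``II``: DAF40 at least ``fold`` times the larger of DAF20/DAF60;
    - ``III``: DAF40 at most 1/``fold`` of the smaller of DAF20/DAF60;
    - ``IV``: everything else (expressed, no qualifying peak or trough).

    The label is invariant to a uniform rescaling of all three values while
    they stay above the floor.
    """
    d20, d40, d60 = fpkm
    if min(d20, d40, d60) < 0:
        raise ValueError("FPKM values must be non-negative")
    if max(d20, d40, d60) < floor:
        return "not_expressed"
    if d20 >= fold * max(d40, d60):
        return "I"
    if d40 >= fold * max(d20, d60):
        return "II"
    if d40 * fold <= min(d20, d60):
        return "III"
    return "IV"


def classify_profile_matrix(
    fpkm: pd.DataFrame, floor: float = 1.0, fold: float = 2.0
) -> pd.Series:
    """Classify every row of a gene x stage FPKM matrix.

    The frame must carry the three stage columns ``DAF20/DAF40/DAF60``.
    """
    missing = [s for s in STAGES if s not in fpkm.columns]
    if missing:
        raise ValueError(f"missing stage columns: {missing}")
    return pd.Series(
        {
            gene: classify_profile(
                (row["DAF20"], row["DAF40"], row["DAF60"]), floor, fold
            )
            for gene, row in fpkm.iterrows()
        },
        name="profile_group",
    )


@dataclass
class RelativeExpression:
    """2^-ddCt fold change with replicate SE and t-test p-value."""

    gene_id: str
    time_point: object
    fold: float
    se: float
    p_value: float
    ddct: float
    n_replicates: int


def relative_expression_ddct(
    treatment_ct,
    treatment_control_gene_ct,
    reference_ct,
    reference_control_gene_ct,
    gene_id: str = "",
    time_point=None,
    welch: bool = False,
) -> RelativeExpression:
    """Relative expression of a target gene by the 2^-ddCt method.

    Parameters are per-replicate Ct arrays: the target gene and the internal
    control gene, in the treatment and in the reference condition.  dCt is
    computed per replicate, ddCt as the treatment-minus-reference difference
    of mean dCt, and the fold change as ``2**-ddCt``.  The SE is the standard
    error of per-replicate treatment folds (each normalized to the reference
    mean dCt), and the p-value comes from a two-sided t test on the dCt
    values (Student's by default, Welch when requested).

    Invariant to adding a constant to every Ct value; at least two replicates
    per condition are needed for an SE and p-value.
    """
    t_ct = np.asarray(treatment_ct, dtype=float)
    t_ref = np.asarray(treatment_control_gene_ct, dtype=float)
    r_ct = np.asarray(reference_ct, dtype=float)
    r_ref = np.asarray(reference_control_gene_ct, dtype=float)
    if t_ct.shape != t_ref.shape or r_ct.shape != r_ref.shape:
        raise ValueError("target and control-gene Ct replicate counts differ")
    if t_ct.size < 2 or r_ct.size < 2:
        raise ValueError("at least two replicates per condition required")
    dct_t = t_ct - t_ref
    dct_r = r_ct - r_ref
    ddct = dct_t.mean() - dct_r.mean()
    fold = float(2.0 ** -ddct)
    rep_folds = 2.0 ** -(dct_t - dct_r.mean())
    se = float(rep_folds.std(ddof=1) / np.sqrt(rep_folds.size))
    t_res = stats.ttest_ind(dct_t, dct_r, equal_var=not welch)
    return RelativeExpression(
        gene_id=gene_id,
        time_point=time_point,
        fold=fold,
        se=se,
        p_value=float(t_res.pvalue),
        ddct=float(ddct),
        n_replicates=int(t_ct.size),
    )


def qpcr_table_analysis(
    ct: pd.DataFrame,
    reference: str = "control",
    welch: bool = False,
) -> pd.DataFrame:
    """Run the 2^-ddCt analysis over a long-format Ct table.

    Expected columns: ``gene``, ``condition``, ``time``, ``replicate``,
    ``ct`` and ``control_ct`` (the internal-control gene measured in the same
    well/replicate).  Every non-reference condition is contrasted against the
    reference at the same time point.  Returns one row per
    (gene, condition, time) with fold, SE, ddCt and p-value.
    """
    required = {"gene", "condition", "time", "replicate", "ct", "control_ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if reference not in set(ct["condition"]):
        raise ValueError(f"reference condition {reference!r} absent")
    rows = []
    for (gene, time), sub in ct.groupby(["gene", "time"], sort=True):
        ref = sub[sub["condition"] == reference].sort_values("replicate")
        if ref.empty:
            continue
        for cond, grp in sub[sub["condition"] != reference].groupby("condition"):
            grp = grp.sort_values("replicate")
            rel = relative_expression_ddct(
                grp["ct"].to_numpy(),
                grp["control_ct"].to_numpy(),
                ref["ct"].to_numpy(),
                ref["control_ct"].to_numpy(),
                gene_id=gene,
                time_point=time,
                welch=welch,
            )
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "time": time,
                    "fold": rel.fold,
                    "se": rel.se,
                    "ddct": rel.ddct,
                    "p_value": rel.p_value,
                    "n_replicates": rel.n_replicates,
                }
            )
    return pd.DataFrame(rows)


def de_time_course_summary(
    relative: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Count significantly up/down regulated genes per time point.

    ``relative`` is the output of :func:`qpcr_table_analysis` (columns
    ``time``, ``fold``, ``p_value``).  A gene is up at a time point when
    fold > 1 and p < alpha, down when fold < 1 and p < alpha.  Raw p-values
    are used by default; ``adjust`` applies Benjamini-Hochberg within each
    time point.
    """
    rows = []
    for time, sub in relative.groupby("time", sort=True):
        p = sub["p_value"].to_numpy()
        if adjust and p.size:
            p = _benjamini_hochberg(p)
        sig = p < alpha
        fold = sub["fold"].to_numpy()
        rows.append(
            {
                "time": time,
                "n_up": int(np.sum(sig & (fold > 1))),
                "n_down": int(np.sum(sig & (fold < 1))),
                "n_tested": int(len(sub)),
            }
        )
    return pd.DataFrame(rows).set_index("time")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj
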