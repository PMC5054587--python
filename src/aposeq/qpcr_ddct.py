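"""Relative qPCR quantification by the delta-delta-Ct method.

Technical replicates are averaged first; per biological replicate the
target gene's Ct is referenced against the housekeeping gene (delta Ct),
and the log2 fold change between groups is the difference of delta Ct
values (delta-delta Ct), reported as log2(test/control) so that the test
group being the reference genotype matches the package-wide
log2(reference/comparison) convention.  A gene is called differential when
the average fold change exceeds 1.5-fold and a t-test on the per-replicate
delta Ct values reaches p < 0.05 (unpaired by default; a paired variant is
provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CtRecord:
    sample_id: str          # group label (genotype), e.g. R35 or m115
    gene_id: str
    bio_rep: int
    tech_rep: int
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive ({self.gene_id}, {self.sample_id})")


@dataclass
class QpcrResult:
    gene_id: str
    avg_log2fc: float
    sd: float
    t_p: float
    significant: bool
    rep_log2fc: np.ndarray
    dct_test: np.ndarray
    dct_control: np.ndarray


def load_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table with columns sample, gene, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path)
    need = {"sample", "gene", "bio_rep", "tech_rep", "ct"}
    if not need.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(need)}")
    return df


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": r.sample_id, "gene": r.gene_id, "bio_rep": r.bio_rep,
             "tech_rep": r.tech_rep, "ct": r.ct}
            for r in records
        ]
    )


def _delta_ct(df: pd.DataFrame, gene: str, ref_gene: str, group: str) -> pd.Series:
    """Per-biological-replicate delta Ct (target - reference), tech reps averaged."""
    sub = df[df["sample"] == group]
    tgt = sub[sub["gene"] == gene].groupby("bio_rep")["ct"].mean()
    ref = sub[sub["gene"] == ref_gene].groupby("bio_rep")["ct"].mean()
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene} missing for group {group}")
    if tgt.empty:
        raise ValueError(f"target gene {gene} missing for group {group}")
    dct = (tgt - ref).dropna()
    if dct.empty:
        raise ValueError(f"no matching biological replicates for {gene} in {group}")
    return dct


def ddct_logfc(
    ct_table: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    test_group: str,
    control_group: str,
    paired: bool = False,
    config=None,
) -> QpcrResult:
    """Delta-delta-Ct log2 fold change of ``test_group`` over ``control_group``.

    Requires at least two biological replicates per group.  Per-replicate
    fold changes pair replicates by their sorted ids; avg and sd are taken
    over those pairs.  The t-test compares per-replicate delta Ct values
    between groups (paired when ``paired``).
    """
    dct_test = _delta_ct(ct_table, target_gene, ref_gene, test_group)
    dct_ctrl = _delta_ct(ct_table, target_gene, ref_gene, control_group)
    if len(dct_test) < 2 or len(dct_ctrl) < 2:
        raise ValueError("at least two biological replicates per group required")
    n = min(len(dct_test), len(dct_ctrl))
    rep_fc = dct_ctrl.sort_index().to_numpy()[:n] - dct_test.sort_index().to_numpy()[:n]
    avg = float(rep_fc.mean())
    sd = float(rep_fc.std(ddof=1))
    a, b = dct_test.to_numpy(), dct_ctrl.to_numpy()
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate noise-free case: identical within-group values
        t_p = 1.0 if a.mean() == b.mean() else 0.0
    elif paired:
        t_p = float(stats.ttest_rel(a[:n], b[:n]).pvalue)
    else:
        t_p = float(stats.ttest_ind(a, b).pvalue)
    if not np.isfinite(t_p):
        t_p = 1.0
    result = QpcrResult(
        gene_id=target_gene,
        avg_log2fc=avg,
        sd=sd,
        t_p=t_p,
        significant=False,
        rep_log2fc=rep_fc,
        dct_test=dct_test.to_numpy(),
        dct_control=dct_ctrl.to_numpy(),
    )
    if config is not None:
        result.significant = call_significant(result, config)
    return result


def call_significant(result: QpcrResult, config) -> bool:
    """Flag iff fold change exceeds ``qpcr_fc_min`` and the t-test p < ``qpcr_alpha``.

    The fold-change rule is strict (> 1.5-fold, i.e. |avg log2fc| >
    log2 1.5); so is the p-value rule (< 0.05).
    """
    if len(result.rep_log2fc) < 2:
        raise ValueError("significance call requires >= 2 replicate fold changes")
    return bool(
        2 ** abs(result.avg_log2fc) > config.qpcr_fc_min and result.t_p < config.qpcr_alpha
    )
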