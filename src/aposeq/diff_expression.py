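"""Count normalization and two-group differential calling.

Re-implements the trimmed mean of M-values (TMM) between-sample scaling
factor, the conditional negative-binomial exact test for two-group count
comparisons, and Benjamini-Hochberg adjustment.  Differential flags follow
the study rule: adjusted p <= 0.01 and at least a two-fold change for mRNA;
fold change alone (pseudocount 1) for the unreplicated small-RNA libraries.

The package-wide fold-change sign convention is log2(reference group /
comparison group): a gene lower in the mutant of a parent:mutant comparison
has a positive log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormFactors:
    """TMM scaling factors (geometric mean 1) with raw library sizes."""

    sample_ids: list[str]
    factors: np.ndarray
    lib_sizes: np.ndarray

    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors


@dataclass
class DeResult:
    feature_id: str
    log2fc: float
    p: float
    p_adj: float
    is_differential: bool


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference sample (log2 scale)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) inverse variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 0.0
    f = (m[keep2] / w[keep2]).sum() / (1.0 / w[keep2]).sum()
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for a features x samples frame.

    Genes with zero count in either member of a sample/reference pair are
    excluded pairwise; log-ratios are double-trimmed (30 % each tail on M,
    5 % each tail on average abundance A) and inverse-variance weighted.
    Factors are rescaled so their geometric mean is 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, n in zip(counts.columns, lib) if n == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    if ref_sample is None:
        # sample whose 75th-percentile relative expression is closest to the mean
        uq = np.array([np.quantile(mat[:, k] / lib[k], 0.75) for k in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    logf = np.array(
        [
            _tmm_pair(mat[:, k], mat[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
            if k != ref_idx
            else 0.0
            for k in range(mat.shape[1])
        ]
    )
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(counts.columns), factors, lib)


def estimate_dispersion_moments(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> float:
    """Common NB dispersion by method of moments (var = mu + phi mu^2).

    A ratio-of-sums estimator pools the per-gene moments across features and
    groups: phi = sum_g (var_g - mu_g) / sum_g mu_g^2, which stays nearly
    unbiased even with two replicates per group where per-gene estimates are
    individually very noisy.  Counts must already be on a common library
    scale; returns 0.1 for unreplicated designs.
    """
    num = 0.0
    den = 0.0
    for grp in (np.asarray(counts_a, float), np.asarray(counts_b, float)):
        if grp.shape[1] < 2:
            continue
        mu = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        ok = mu > 0
        num += float((var[ok] - mu[ok]).sum())
        den += float((mu[ok] ** 2).sum())
    if den == 0:
        return 0.1
    return float(max(0.0, num / den))


def _exact_p_one(sa: int, sb: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided conditional exact p for group sums (sa, sb).

    Under a shared mean and common dispersion, the group-A sum given the
    total follows either a binomial split (dispersion 0, Poisson limit) or
    the NB-conditional distribution; the p-value sums the probabilities of
    all outcomes no more likely than the observed one.
    """
    t = sa + sb
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if dispersion <= 0:
        logp = stats.binom.logpmf(s, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        r_a, r_b = n_a / dispersion, n_b / dispersion
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        logp = stats.nbinom.logpmf(s, r_a, p_a) + stats.nbinom.logpmf(s[::-1], r_b, p_b)
    prob = np.exp(logp - logp.max())
    prob = prob / prob.sum()
    obs = prob[sa]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-7)].sum()))


def equalize_lib_sizes(counts: pd.DataFrame, norm: NormFactors | None = None) -> pd.DataFrame:
    """Rescale counts to a common effective library size (geometric mean), rounded."""
    lib = counts.to_numpy(dtype=float).sum(axis=0)
    eff = lib * (norm.factors if norm is not None else 1.0)
    common = np.exp(np.mean(np.log(eff)))
    scaled = counts.to_numpy(dtype=float) * (common / eff)
    return pd.DataFrame(np.rint(scaled).astype(np.int64), index=counts.index, columns=counts.columns)


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, dispersion: float | None = None
) -> np.ndarray:
    """Per-feature exact p-values for two groups of equalized count columns.

    ``dispersion`` may be a fixed value; when None it is estimated by
    method of moments across features (requires replicates; defaults to 0.1
    for unreplicated designs).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a))
    counts_b = np.atleast_2d(np.asarray(counts_b))
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("negative counts")
    if dispersion is None:
        dispersion = estimate_dispersion_moments(counts_a, counts_b)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    sa = counts_a.sum(axis=1).astype(int)
    sb = counts_b.sum(axis=1).astype(int)
    return np.array([_exact_p_one(a, b, n_a, n_b, dispersion) for a, b in zip(sa, sb)])


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order restored)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def run_de(
    counts: pd.DataFrame,
    group_ref: list[str],
    group_cmp: list[str],
    config,
    mode: str = "mrna",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Normalize, test, adjust, and flag differential features for two groups.

    mRNA mode: TMM normalization, NB exact test, BH adjustment, flag iff
    p_adj <= ``de_alpha`` and |log2fc| >= log2(``fc_min``).  sRNA mode (no
    replication): flag on normalized fold change alone with pseudocount
    ``srna_pseudocount``; p columns are NaN.
    """
    sub = counts[group_ref + group_cmp]
    norm = tmm_factors(sub)
    eff = norm.effective_lib_sizes()
    common = np.exp(np.mean(np.log(eff)))
    cpm = sub.to_numpy(float) * (common / eff)
    mean_ref = cpm[:, : len(group_ref)].mean(axis=1)
    mean_cmp = cpm[:, len(group_ref) :].mean(axis=1)
    if mode == "srna":
        pc = config.srna_pseudocount
        log2fc = np.log2((mean_ref + pc) / (mean_cmp + pc))
        flag = np.abs(log2fc) > np.log2(config.fc_min)
        p = p_adj = np.full(len(sub), np.nan)
    elif mode == "mrna":
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2(mean_ref / mean_cmp)
        eq = equalize_lib_sizes(sub, norm)
        p = nb_exact_test(
            eq[group_ref].to_numpy(), eq[group_cmp].to_numpy(), dispersion
        )
        p_adj = adjust_bh(p)
        flag = (p_adj <= config.de_alpha) & (np.abs(log2fc) >= np.log2(config.fc_min))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {
            "feature_id": sub.index,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "is_differential": np.asarray(flag, dtype=bool),
        }
    ).set_index("feature_id")


def call_differential(results: pd.DataFrame, config, mode: str = "mrna") -> pd.DataFrame:
    """(Re-)flag a results frame carrying log2fc (+ p_adj in mRNA mode)."""
    out = results.copy()
    if mode == "mrna":
        out["is_differential"] = (out["p_adj"] <= config.de_alpha) & (
            out["log2fc"].abs() >= np.log2(config.fc_min)
        )
    elif mode == "srna":
        out["is_differential"] = out["log2fc"].abs() > np.log2(config.fc_min)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
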