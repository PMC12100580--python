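"""Summaries of branch and branch-site codon-model selection tests.

Codon-model fitting happens upstream (external likelihood software); this
module consumes its tabulated log-likelihoods and dN/dS (omega) estimates.
For each gene with one foreground species, the branch alternative (b_free:
free foreground omega) is compared by likelihood-ratio test against two
nulls — b_neut (foreground omega fixed at 1... relative rate equal to
background) and M0 (one omega tree-wide) — and the branch-site alternative
(bsA) against bsA1 and M1. Each model pair differs by one parameter, so
D = 2*(lnL_alt - lnL_null) is referred to chi-square with 1 df and
p-values are BH-corrected per comparison family across genes.

A gene is a selection-shift candidate when the alternative beats the
configured null set at the FDR threshold; candidates are classified
"faster" or "slower" than the background by comparing foreground and
background omega. Genes whose foreground omega exceeds Q3 + 1.5*IQR of all
tested genes are flagged as omega outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de_convergence import bh_fdr

BRANCH_SCHEMA = {"gene": str, "lnl_bfree": float, "lnl_bneut": float,
                 "lnl_m0": float, "omega_fore": float, "omega_back": float}
BRANCH_SITE_SCHEMA = {"gene": str, "lnl_bsA": float, "lnl_bsA1": float,
                      "lnl_m1": float, "sites": str}


def lrt(lnl_alt: float, lnl_null: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic D = 2*(lnL_alt - lnL_null) and its chi2 p.

    Negative D (numerical optimiser noise in the upstream fits) is clamped
    to 0 with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (np.isfinite(lnl_alt) and np.isfinite(lnl_null)):
        raise ValueError("log-likelihoods must be finite")
    d = 2.0 * (lnl_alt - lnl_null)
    if d < 0:
        warnings.warn(
            f"negative LRT statistic {d:.4g} clamped to 0 (alt fit below null)",
            RuntimeWarning, stacklevel=2,
        )
        d = 0.0
    return d, float(stats.chi2.sf(d, df=df))


@dataclass(frozen=True)
class OutlierResult:
    q1: float
    q3: float
    iqr: float
    threshold: float
    flagged: tuple[str, ...] = field(default_factory=tuple)  # descending omega


def omega_outliers(omegas: dict[str, float]) -> OutlierResult:
    """Tukey fence on foreground omega: flag genes with omega > Q3 + 1.5*IQR.

    Quartiles by linear interpolation between order statistics (Q3 at rank
    position (n-1)*0.75) — the outlier count depends on this convention, so
    it is fixed here.
    """
    if len(omegas) < 4:
        raise ValueError("need at least 4 omega values for quartiles")
    vals = np.array(list(omegas.values()), dtype=float)
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation default
    iqr = q3 - q1
    thr = q3 + 1.5 * iqr
    flagged = sorted(
        (g for g, w in omegas.items() if w > thr),
        key=lambda g: (-omegas[g], g),
    )
    return OutlierResult(q1=float(q1), q3=float(q3), iqr=float(iqr),
                         threshold=float(thr), flagged=tuple(flagged))


def _null_mask(padj_a: pd.Series, padj_b: pd.Series, alpha: float, rule: str) -> pd.Series:
    if rule == "both":
        return (padj_a < alpha) & (padj_b < alpha)
    if rule == "any":
        return (padj_a < alpha) | (padj_b < alpha)
    if rule == "bneut-only":
        return padj_a < alpha
    raise ValueError(f"unknown null rule {rule!r}")


def branch_test_summary(records: pd.DataFrame, alpha_fdr: float = 0.05,
                        null_rule: str = "both") -> pd.DataFrame:
    """Per-gene branch-test verdicts for one foreground species.

    Two LRTs per gene (b_free vs b_neut, b_free vs M0), BH FDR across genes
    per comparison. A gene is a "shift" when the configured combination of
    nulls is rejected; shift genes are classified faster/slower by omega
    (ties -> "unclassified"). Omega outliers are flagged with the Tukey
    fence computed over the shift genes (the set the rule targets);
    fewer than 4 shift genes means no flags.
    """
    d1, p1, d2, p2 = [], [], [], []
    for rec in records.itertuples(index=False):
        a, pa = lrt(rec.lnl_bfree, rec.lnl_bneut)
        b, pb = lrt(rec.lnl_bfree, rec.lnl_m0)
        d1.append(a); p1.append(pa); d2.append(b); p2.append(pb)
    out = pd.DataFrame({
        "gene": records["gene"].astype(str).to_numpy(),
        "D_vs_bneut": d1, "padj_vs_bneut": bh_fdr(p1),
        "D_vs_m0": d2, "padj_vs_m0": bh_fdr(p2),
        "omega_fore": records["omega_fore"].to_numpy(dtype=float),
        "omega_back": records["omega_back"].to_numpy(dtype=float),
    })
    shift = _null_mask(out["padj_vs_bneut"], out["padj_vs_m0"], alpha_fdr, null_rule)
    rate = np.where(out["omega_fore"] > out["omega_back"], "faster",
                    np.where(out["omega_fore"] < out["omega_back"], "slower",
                             "unclassified"))
    out["verdict"] = np.where(shift, "shift", "ns")
    out["rate_class"] = np.where(shift, rate, "NA")
    # the Tukey fence applies to the genes where the free-ratio model won
    shift_omegas = dict(zip(out.loc[shift, "gene"], out.loc[shift, "omega_fore"]))
    if len(shift_omegas) >= 4:
        outl = omega_outliers(shift_omegas)
        out["outlier"] = out["gene"].isin(outl.flagged)
    else:
        out["outlier"] = False
    return out


def branch_site_summary(records: pd.DataFrame, alpha_fdr: float = 0.05,
                        null_rule: str = "both") -> pd.DataFrame:
    """Per-gene branch-site verdicts; selected sites carried through as-is.

    Sites are 1-based codon positions into the cluster alignment, stored as
    a comma-separated string (empty/NA for none).
    """
    d1, p1, d2, p2 = [], [], [], []
    for rec in records.itertuples(index=False):
        a, pa = lrt(rec.lnl_bsA, rec.lnl_bsA1)
        b, pb = lrt(rec.lnl_bsA, rec.lnl_m1)
        d1.append(a); p1.append(pa); d2.append(b); p2.append(pb)
    sites = records["sites"] if "sites" in records.columns else pd.Series(
        [""] * len(records))
    out = pd.DataFrame({
        "gene": records["gene"].astype(str).to_numpy(),
        "D_vs_bsA1": d1, "padj_vs_bsA1": bh_fdr(p1),
        "D_vs_m1": d2, "padj_vs_m1": bh_fdr(p2),
        "sites": sites.fillna("").astype(str).to_numpy(),
    })
    shift = _null_mask(out["padj_vs_bsA1"], out["padj_vs_m1"], alpha_fdr, null_rule)
    out["verdict"] = np.where(shift, "shift", "ns")
    return out


def intersect_candidates(set_a, set_b) -> list[str]:
    """Genes shifted in both foreground species, lexicographically ordered."""
    return sorted(set(set_a) & set(set_b))
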