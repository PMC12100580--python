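"""Convergence of differential expression between two parasite/non-parasite pairs.

Two congeneric comparisons (an obligate parasite against its saprophagous
congener in each of two genera) each yield a per-gene table of log2 fold
changes and adjusted p-values, with positive fold change meaning higher
expression in the parasite. Genes significant in both comparisons are
classified by sign agreement:

* concordant_up / concordant_down — significant in both, same sign;
* antagonistic — significant in both, opposite signs;
* exclusive_A / exclusive_B — significant in exactly one comparison.

If expression evolved independently in the two lineages, the chance of a
gene being differentially expressed in both comparisons is the product of
the marginal probabilities, so the expected overlap in a universe of N
tested genes is nA*nB/N per direction. The observed count is compared to
that expectation with a one-cell goodness-of-fit statistic
(O-E)^2/E ~ chi2 with 1 df; a 2x2 contingency chi-square is available as
an alternative formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = (
    "concordant_up", "concordant_down", "antagonistic",
    "exclusive_A", "exclusive_B", "neither",
)

DEG_SCHEMA = {"gene": str, "log2fc": float, "pvalue": float, "padj": float}


class TieError(ValueError):
    """A significant gene has log2fc exactly 0; its direction is undefined."""


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unchanged."""
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_de_simple(counts: pd.DataFrame, groups: dict[str, str], alpha: float = 0.05) -> pd.DataFrame:
    """Minimal two-group differential-expression caller for synthetic counts.

    A deliberately simple negative-binomial Wald test used only to make the
    synthetic pipeline self-contained — not a reimplementation of a
    production DE method. Per gene: library-size-normalised group means, a
    method-of-moments dispersion pooled across groups (variance = mu +
    alpha*mu^2), a Wald z-test on the difference of log means via the delta
    method, and BH-adjusted p-values. All-zero genes are left untested.

    Parameters
    ----------
    counts : DataFrame, genes x samples, nonnegative integers.
    groups : sample -> condition map; exactly two conditions, >=2 samples each.
    """
    conds = sorted(set(groups.values()))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    cols = {c: [s for s in counts.columns if groups.get(s) == c] for c in conds}
    for c, ss in cols.items():
        if len(ss) < 2:
            raise ValueError(f"condition {c!r} has {len(ss)} samples; need >=2")
    g1, g2 = conds
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    # total-count normalisation to the mean library size
    libs = mat.sum(axis=0)
    norm = mat / libs * libs.mean()
    a = norm[:, [counts.columns.get_loc(s) for s in cols[g1]]]
    b = norm[:, [counts.columns.get_loc(s) for s in cols[g2]]]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # pooled MoM dispersion from within-group moments
        mu = (m1 + m2) / 2
        vw = (v1 + v2) / 2
        disp = np.clip((vw - mu) / mu**2, 0.0, None)
        disp = np.where(np.isfinite(disp), disp, 0.0)
        pc = 0.5
        lfc = np.log2((m1 + pc) / (m2 + pc))
        var_m1 = (m1 + disp * m1**2) / a.shape[1]
        var_m2 = (m2 + disp * m2**2) / b.shape[1]
        se = np.sqrt(var_m1 / (m1 + pc) ** 2 + var_m2 / (m2 + pc) ** 2)
        z = (np.log(m1 + pc) - np.log(m2 + pc)) / se
    tested = (m1 + m2) > 0
    # Student-t reference with pooled-sample df guards against the Wald
    # statistic's small-sample anticonservativeness
    df_t = a.shape[1] + b.shape[1] - 2
    pval = np.where(tested & (se > 0), 2 * stats.t.sf(np.abs(z), df=df_t), np.nan)
    pval = np.where(tested & (se == 0), 1.0, pval)
    out = pd.DataFrame({
        "gene": counts.index.astype(str),
        "log2fc": lfc,
        "pvalue": pval,
        "padj": bh_fdr(pval),
        "tested": tested,
    })
    out.loc[~out["tested"], ["log2fc", "pvalue", "padj"]] = np.nan
    return out


def _sig(df: pd.DataFrame, alpha: float) -> pd.Series:
    return df["padj"].notna() & (df["padj"] < alpha)


def classify_shared_degs(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition the shared gene universe by joint significance and sign.

    Returns a per-gene table (gene, category, log2fc_A, log2fc_B) over the
    union of gene ids, and summary counts including ``intersection`` (the
    number of genes significant in both comparisons).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a = table_a.set_index("gene")
    b = table_b.set_index("gene")
    genes = a.index.union(b.index)
    a = a.reindex(genes)
    b = b.reindex(genes)
    sa, sb = _sig(a, alpha), _sig(b, alpha)
    both = sa & sb
    zero_tie = both & ((a["log2fc"] == 0) | (b["log2fc"] == 0))
    if zero_tie.any():
        raise TieError(
            f"significant gene(s) with log2fc exactly 0: {list(genes[zero_tie])[:5]}"
        )
    same = np.sign(a["log2fc"]) == np.sign(b["log2fc"])
    cat = pd.Series("neither", index=genes, name="category")
    cat[both & same & (a["log2fc"] > 0)] = "concordant_up"
    cat[both & same & (a["log2fc"] < 0)] = "concordant_down"
    cat[both & ~same] = "antagonistic"
    cat[sa & ~sb] = "exclusive_A"
    cat[~sa & sb] = "exclusive_B"
    per_gene = pd.DataFrame({
        "gene": genes, "category": cat.to_numpy(),
        "log2fc_A": a["log2fc"].to_numpy(), "log2fc_B": b["log2fc"].to_numpy(),
    })
    counts = {c: int((cat == c).sum()) for c in CATEGORIES}
    counts["intersection"] = int(both.sum())
    return per_gene, counts


def expected_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Expected shared count under independence: nA*nB/N (hypergeometric mean)."""
    if n_universe <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes must lie within [0, N]")
    return n_a * n_b / n_universe


@dataclass(frozen=True)
class ConvergenceTestResult:
    direction: str
    observed: int
    expected: float
    chi2: float
    pvalue: float


def convergence_test(
    observed: int, expected: float, direction: str = ""
) -> ConvergenceTestResult:
    """One-cell goodness-of-fit test of an overlap count against independence."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    chi2 = (observed - expected) ** 2 / expected
    return ConvergenceTestResult(
        direction=direction, observed=int(observed), expected=float(expected),
        chi2=float(chi2), pvalue=float(stats.chi2.sf(chi2, df=1)),
    )


def convergence_test_contingency(
    observed: int, n_a: int, n_b: int, n_universe: int, direction: str = ""
) -> ConvergenceTestResult:
    """Alternative 2x2 contingency chi-square (no continuity correction)."""
    table = np.array([
        [observed, n_a - observed],
        [n_b - observed, n_universe - n_a - n_b + observed],
    ])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ConvergenceTestResult(
        direction=direction, observed=int(observed),
        expected=expected_overlap(n_a, n_b, n_universe),
        chi2=float(chi2), pvalue=float(p),
    )


def run_convergence_analysis(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    universe: int | None = None,
    form: str = "goodness_of_fit",
) -> dict:
    """Classify shared DEGs and test each direction against independence.

    The universe N defaults to genes with a non-missing adjusted p-value in
    BOTH tables; ``universe`` overrides it. Directions whose expectation is
    zero are reported as untestable (chi2/p NA).
    """
    per_gene, counts = classify_shared_degs(table_a, table_b, alpha)
    a = table_a.set_index("gene")
    b = table_b.set_index("gene")
    genes = a.index.intersection(b.index)
    tested_both = a.loc[genes, "padj"].notna() & b.loc[genes, "padj"].notna()
    n_univ = universe if universe is not None else int(tested_both.sum())
    if n_univ <= 0:
        raise ValueError("empty test universe")

    def margins(df, alpha):
        sig = _sig(df, alpha)
        return int((sig & (df["log2fc"] > 0)).sum()), int((sig & (df["log2fc"] < 0)).sum())

    up_a, down_a = margins(a, alpha)
    up_b, down_b = margins(b, alpha)
    plan = {
        "concordant_up": (counts["concordant_up"], up_a * up_b / n_univ, up_a, up_b),
        "concordant_down": (counts["concordant_down"], down_a * down_b / n_univ, down_a, down_b),
        # both antagonistic sign patterns pooled
        "antagonistic": (
            counts["antagonistic"],
            (up_a * down_b + down_a * up_b) / n_univ,
            up_a * down_b + down_a * up_b,  # pooled margin product, used for E only
            None,
        ),
    }
    tests = []
    for direction, (obs, exp, ma, mb) in plan.items():
        if exp <= 0:
            tests.append(ConvergenceTestResult(direction, obs, exp, float("nan"), float("nan")))
        elif form == "contingency" and direction != "antagonistic":
            tests.append(convergence_test_contingency(obs, ma, mb, n_univ, direction))
        else:
            tests.append(convergence_test(obs, exp, direction))
    return {
        "per_gene": per_gene,
        "counts": counts,
        "universe": n_univ,
        "margins": {"up_A": up_a, "down_A": down_a, "up_B": up_b, "down_B": down_b},
        "tests": tests,
    }


def tests_to_frame(tests) -> pd.DataFrame:
    return pd.DataFrame([
        {"direction": t.direction, "observed": t.observed, "expected": t.expected,
         "chi2": t.chi2, "pvalue": t.pvalue}
        for t in tests
    ])
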