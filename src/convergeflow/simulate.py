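"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed integer seed and returns,
alongside the data tables, a truth table sufficient to score recovery at
the downstream stage (planted category per gene, planted preference per
species, planted selection shifts and omega outliers, the planted enriched
term, planted cluster fates).

Default parameter values follow the study conditions of the blowfly
system: seven Calliphoridae species on a 7-taxon tree, two congeneric
parasite/saprophage comparisons, Table-1-scale preference indices and
no-oviposition rates, the published shared-DEG category counts, 12
preference-linked genes among ~4832 genes expressed in every species, and
617/266 branch-test selection shifts with 11/5 omega outliers.

The packaged default tree is a synthetic stand-in topology with plausible
branch lengths, not the published phylogeny.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as cio
from .behaviour import logit_pi

# synthetic stand-in 7-taxon tree (not the published phylogeny)
DEFAULT_TREE_NEWICK = (
    "(((Ch_bezziana:0.040,Ch_megacephala:0.040):0.030,Ch_albiceps:0.070):0.080,"
    "((Co_hominivorax:0.050,Co_macellaria:0.050):0.060,"
    "(L_cuprina:0.060,L_eximia:0.060):0.050):0.040);"
)

# species-level true fresh-substrate choice probabilities and
# no-oviposition rates used as generator defaults (Table-1-scale)
SPECIES_THETA = {
    "Co_hominivorax": 1.0,
    "Co_macellaria": 0.059,
    "Ch_megacephala": 0.0,
    "Ch_albiceps": 0.424,
    "L_cuprina": 0.634,
    "L_eximia": 0.412,
}
SPECIES_P_SKIP = {
    "Co_hominivorax": 0.5,
    "Co_macellaria": 0.2,
    "Ch_megacephala": 0.6,
    "Ch_albiceps": 0.2,
    "L_cuprina": 0.2,
    "L_eximia": 0.55,
}
SPECIES_N_TRIALS = {
    "Co_hominivorax": 8,
    "Co_macellaria": 20,
    "Ch_megacephala": 20,
    "Ch_albiceps": 20,
    "L_cuprina": 20,
    "L_eximia": 20,
}

# preference substitution for the unassayed second obligate parasite
PI_SUBSTITUTION = {"Ch_bezziana": "Co_hominivorax"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _negbin(rng: np.random.Generator, mean, dispersion, size=None):
    """Negative binomial with variance mean + dispersion*mean^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# oviposition trials


def simulate_oviposition(
    thetas: dict[str, float] | None = None,
    p_skip: dict[str, float] | None = None,
    n_trials: dict[str, int] | None = None,
    egg_mean: float = 120.0,
    egg_dispersion: float = 0.3,
    seed=0,
):
    """Two-choice egg-count trials with no-oviposition replicates.

    Per trial: with probability p_skip the replicate lays nothing; else the
    total clutch is negative-binomial around ``egg_mean`` and split
    binomially with the species' true fresh-choice probability theta.
    Returns (trials DataFrame, truth DataFrame).
    """
    rng = _rng(seed)
    thetas = dict(SPECIES_THETA if thetas is None else thetas)
    p_skip = dict(SPECIES_P_SKIP if p_skip is None else p_skip)
    n_trials = dict(SPECIES_N_TRIALS if n_trials is None else n_trials)
    rows, truth = [], []
    for sp in sorted(thetas):
        th, ps, nt = thetas[sp], p_skip.get(sp, 0.0), n_trials.get(sp, 20)
        truth.append({"species": sp, "theta": th, "p_skip": ps, "n_trials": nt})
        for rep in range(1, nt + 1):
            if rng.random() < ps:
                fresh = rotten = 0
            else:
                total = int(_negbin(rng, egg_mean, egg_dispersion))
                fresh = int(rng.binomial(total, th)) if total > 0 else 0
                rotten = total - fresh
            rows.append({"species": sp, "replicate": f"r{rep}",
                         "eggs_fresh": fresh, "eggs_rotten": rotten})
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# differential-expression counts for two congeneric comparisons

DEFAULT_DE_CATEGORIES = {
    "concordant_up": 97, "concordant_down": 71, "antagonistic": 46,
    "exclusive_A": 300, "exclusive_B": 100,
}


def simulate_de_counts(
    n_genes: int = 5000,
    categories: dict[str, int] | None = None,
    lfc: float = 3.0,
    dispersion: float = 0.05,
    n_reps: int = 3,
    base_mean_log_range: tuple[float, float] = (4.0, 8.0),
    seed=0,
):
    """Negative-binomial counts for two parasite-vs-saprophage comparisons.

    Planted genes receive +/-``lfc`` log2 fold change in the designated
    comparison(s) with signs per category (antagonistic genes split evenly
    between the two opposite-sign patterns, exclusives between up and
    down); the remainder are null in both. Returns
    (counts_A, counts_B, groups_A, groups_B, truth).
    """
    rng = _rng(seed)
    categories = dict(DEFAULT_DE_CATEGORIES if categories is None else categories)
    if sum(categories.values()) > n_genes:
        raise ValueError("planted category counts exceed n_genes")
    genes = [f"OG{i:05d}" for i in range(n_genes)]
    base = 2.0 ** rng.uniform(*base_mean_log_range, size=n_genes)

    # per-gene planted log2 shift in each comparison
    shift_a = np.zeros(n_genes)
    shift_b = np.zeros(n_genes)
    cat = np.array(["null"] * n_genes, dtype=object)
    idx = 0

    def take(k):
        nonlocal idx
        sl = slice(idx, idx + k)
        idx += k
        return sl

    for name, count in categories.items():
        sl = take(count)
        cat[sl] = name
        half = count // 2
        r = np.arange(count)
        if name == "concordant_up":
            shift_a[sl], shift_b[sl] = lfc, lfc
        elif name == "concordant_down":
            shift_a[sl], shift_b[sl] = -lfc, -lfc
        elif name == "antagonistic":
            sign = np.where(r < half, 1.0, -1.0)
            shift_a[sl] = sign * lfc
            shift_b[sl] = -sign * lfc
        elif name == "exclusive_A":
            shift_a[sl] = np.where(r < half, 1.0, -1.0) * lfc
        elif name == "exclusive_B":
            shift_b[sl] = np.where(r < half, 1.0, -1.0) * lfc
        else:
            raise ValueError(f"unknown category {name!r}")

    def comparison(shift, parasite, sapro):
        cols = {}
        for rep in range(1, n_reps + 1):
            cols[f"{parasite}_r{rep}"] = _negbin(rng, base * 2.0 ** (shift / 2), dispersion)
        for rep in range(1, n_reps + 1):
            cols[f"{sapro}_r{rep}"] = _negbin(rng, base * 2.0 ** (-shift / 2), dispersion)
        counts = pd.DataFrame(cols, index=genes)
        groups = {c: ("parasite" if c.startswith(parasite) else "saprophage")
                  for c in cols}
        return counts, groups

    counts_a, groups_a = comparison(shift_a, "Co_hominivorax", "Co_macellaria")
    counts_b, groups_b = comparison(shift_b, "Ch_bezziana", "Ch_megacephala")
    truth = pd.DataFrame({"gene": genes, "category": cat,
                          "lfc_A": shift_a, "lfc_B": shift_b})
    return counts_a, counts_b, groups_a, groups_b, truth


# ---------------------------------------------------------------------------
# expression medians evolving on the tree, with preference-linked genes


def simulate_expression_on_tree(
    tree: dendropy.Tree | None = None,
    logit_pis: dict[str, float] | None = None,
    n_genes: int = 5000,
    n_unexpressed: int = 168,
    n_linked: int = 12,
    slope: float = -30.0,
    bm_sigma: float = 1.6,
    n_reps: int = 3,
    jitter_sd: float = 0.05,
    n_ref: dict[str, int] | None = None,
    seed=0,
):
    """Brownian-motion expression with planted preference-correlated genes.

    Species-level TPM10K medians are intercept + slope*logitPI (linked
    genes only) + a Brownian deviation accumulated preorder along the tree
    with per-branch variance bm_sigma^2 * length. Replicate TPMs are
    log-normal jitter around the species value, floored at a small
    positive value so "expressed" genes stay expressed; ``n_unexpressed``
    genes are zeroed in every sample of one random species so the
    expressed-in-all-species filter has a known answer. The written matrix
    is on the TPM scale (TPM10K divided by n_ref/1e4), so applying the
    TPM10K conversion downstream recovers the planted structure.

    Returns (tpm DataFrame, sample_species map, n_ref map, truth DataFrame).
    """
    rng = _rng(seed)
    if tree is None:
        tree = cio.read_newick(DEFAULT_TREE_NEWICK)
    if logit_pis is None:
        logit_pis = default_logit_pis()
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if set(species) - set(logit_pis):
        raise ValueError("logit PI missing for some tree tips")
    if n_ref is None:
        refs = rng.integers(9000, 14001, size=len(species))
        n_ref = dict(zip(species, (int(r) for r in refs)))

    genes = [f"OG{i:05d}" for i in range(n_genes)]
    linked = np.zeros(n_genes, dtype=bool)
    linked[:n_linked] = True
    unexpr_idx = np.arange(n_genes - n_unexpressed, n_genes)
    unexpr_species = rng.choice(species, size=n_unexpressed)

    # Brownian deviations: preorder accumulation of Gaussian increments
    bm = {}
    for node in tree.preorder_node_iter():
        parent = bm.get(node.parent_node, np.zeros(n_genes))
        length = node.edge.length or 0.0
        bm[node] = parent + rng.normal(0.0, bm_sigma * np.sqrt(length), size=n_genes)
    tip_dev = {leaf.taxon.label: bm[leaf] for leaf in tree.leaf_node_iter()}

    intercept = rng.uniform(30.0, 100.0, size=n_genes)
    sample_species: dict[str, str] = {}
    cols: dict[str, np.ndarray] = {}
    medians = {}
    for sp in species:
        val = intercept + np.where(linked, slope * logit_pis[sp], 0.0) + tip_dev[sp]
        val = np.clip(val, 0.01, None)
        medians[sp] = val
        scale = n_ref[sp] / 1e4
        for rep in range(1, n_reps + 1):
            name = f"{sp}_r{rep}"
            sample_species[name] = sp
            tpm = val * np.exp(rng.normal(0.0, jitter_sd, size=n_genes)) / scale
            cols[name] = tpm
    tpm_df = pd.DataFrame(cols, index=genes)
    # zero out the planted not-expressed-everywhere genes in one species each
    for gi, sp in zip(unexpr_idx, unexpr_species):
        for rep in range(1, n_reps + 1):
            tpm_df.iloc[gi, tpm_df.columns.get_loc(f"{sp}_r{rep}")] = 0.0
    truth = pd.DataFrame({
        "gene": genes,
        "linked": linked,
        "true_slope": np.where(linked, slope, 0.0),
        "expressed_in_all": ~np.isin(np.arange(n_genes), unexpr_idx),
    })
    return tpm_df, sample_species, n_ref, truth


def default_logit_pis() -> dict[str, float]:
    """Logit-transformed default preference indices for the 7 species.

    The unassayed obligate parasite inherits the assayed one's value via
    the explicit substitution rule.
    """
    pis = {sp: logit_pi(th) for sp, th in SPECIES_THETA.items()}
    for target, donor in PI_SUBSTITUTION.items():
        pis[target] = pis[donor]
    return pis


# ---------------------------------------------------------------------------
# branch and branch-site selection tables


def _bounded_omega(rng, size):
    """Gamma-shaped but bounded base omega on [0.02, 0.30].

    Bounded support keeps the Tukey fence (~0.35 at these parameters)
    strictly between the base maximum and the planted outlier range, so
    planted outliers are exactly the flagged set.
    """
    return 0.02 + 0.28 * rng.beta(2.0, 2.0, size=size)


def simulate_selection_tables(
    n_genes: int = 6038,
    n_shift: tuple[int, int] = (617, 266),
    n_faster: tuple[int, int] = (489, 218),
    n_shared: int = 61,
    n_outliers: tuple[int, int] = (11, 5),
    n_bs_shift: tuple[int, int] = (548, 245),
    n_bs_shared: int = 35,
    effect: float = 30.0,
    outlier_range: tuple[float, float] = (0.43, 0.70),
    foregrounds: tuple[str, str] = ("Co_hominivorax", "Ch_bezziana"),
    seed=0,
):
    """Branch and branch-site likelihood tables for two foreground species.

    Null genes draw both LRT statistics from chi-square(1) (converted to
    log-likelihood pairs); shifted genes add ``effect`` to both statistics.
    The two foregrounds share ``n_shared`` shifted genes. Foreground omega
    comes from a bounded gamma-shaped base, with ``n_outliers`` planted in
    ``outlier_range`` (inside the faster class); background omega is
    scaled below/above foreground for faster/slower genes.

    Returns dicts keyed by foreground: branch tables, branch-site tables,
    and a truth table.
    """
    rng = _rng(seed)
    if max(n_shift[0] + n_shift[1] - n_shared,
           n_bs_shift[0] + n_bs_shift[1] - n_bs_shared) > n_genes:
        raise ValueError("planted shift sets exceed n_genes")
    genes = np.array([f"OG{i:05d}" for i in range(n_genes)])

    def pick_shift_sets(k1, k2, shared):
        both = np.arange(shared)
        only1 = np.arange(shared, k1)
        only2 = np.arange(k1, k1 + k2 - shared)
        return np.concatenate([both, only1]), np.concatenate([both, only2])

    shift_sets = pick_shift_sets(n_shift[0], n_shift[1], n_shared)
    bs_sets = pick_shift_sets(n_bs_shift[0], n_bs_shift[1], n_bs_shared)

    branch, branch_site, truth_rows = {}, {}, []
    for f_idx, fore in enumerate(foregrounds):
        shift_idx = shift_sets[f_idx]
        is_shift = np.zeros(n_genes, dtype=bool)
        is_shift[shift_idx] = True
        # faster/slower split within the shifted set
        faster = np.zeros(n_genes, dtype=bool)
        faster[shift_idx[: n_faster[f_idx]]] = True
        omega_fore = _bounded_omega(rng, n_genes)
        out_idx = shift_idx[: n_outliers[f_idx]]  # inside the faster class
        omega_fore[out_idx] = rng.uniform(*outlier_range, size=n_outliers[f_idx])
        omega_back = np.where(
            is_shift & faster, omega_fore * rng.uniform(0.3, 0.8, n_genes),
            np.where(is_shift, omega_fore * rng.uniform(1.3, 2.5, n_genes),
                     omega_fore),
        )
        d1 = rng.chisquare(1, size=n_genes) + np.where(is_shift, effect, 0.0)
        d2 = rng.chisquare(1, size=n_genes) + np.where(is_shift, effect, 0.0)
        lnl_bfree = -1000.0 - rng.uniform(0, 50, n_genes)
        branch[fore] = pd.DataFrame({
            "gene": genes,
            "lnl_bfree": lnl_bfree,
            "lnl_bneut": lnl_bfree - d1 / 2.0,
            "lnl_m0": lnl_bfree - d2 / 2.0,
            "omega_fore": omega_fore,
            "omega_back": omega_back,
        })

        bs_idx = bs_sets[f_idx]
        is_bs = np.zeros(n_genes, dtype=bool)
        is_bs[bs_idx] = True
        e1 = rng.chisquare(1, size=n_genes) + np.where(is_bs, effect, 0.0)
        e2 = rng.chisquare(1, size=n_genes) + np.where(is_bs, effect, 0.0)
        lnl_bsa = -1000.0 - rng.uniform(0, 50, n_genes)
        sites = np.array([""] * n_genes, dtype=object)
        for gi in bs_idx:
            k = rng.integers(1, 6)
            pos = np.sort(rng.choice(np.arange(1, 201), size=k, replace=False))
            sites[gi] = ",".join(map(str, pos))
        branch_site[fore] = pd.DataFrame({
            "gene": genes,
            "lnl_bsA": lnl_bsa,
            "lnl_bsA1": lnl_bsa - e1 / 2.0,
            "lnl_m1": lnl_bsa - e2 / 2.0,
            "sites": sites,
        })
        tr = pd.DataFrame({
            "gene": genes, "foreground": fore,
            "shift": is_shift, "faster": is_shift & faster,
            "outlier": np.isin(np.arange(n_genes), out_idx),
            "bs_shift": is_bs, "omega_fore": omega_fore,
        })
        truth_rows.append(tr)
    return branch, branch_site, pd.concat(truth_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# gene -> GO-term annotations with one planted enriched term


def simulate_annotations(
    universe: list[str],
    study_a: list[str],
    study_b: list[str],
    n_terms: int = 150,
    mean_term_size: float = 25.0,
    planted_coverage: float = 0.8,
    seed=0,
):
    """Random gene-term incidences plus one term enriched in both study sets.

    The planted term annotates ``planted_coverage`` of each study set and a
    matching small number of background genes. Returns (annotation
    DataFrame, planted term id).
    """
    rng = _rng(seed)
    universe = list(universe)
    rows = []
    for t in range(n_terms):
        term = f"GO:{t:07d}"
        size = max(2, int(_negbin(rng, mean_term_size, 0.3)))
        for g in rng.choice(universe, size=min(size, len(universe)), replace=False):
            rows.append({"gene": g, "term": term})
    planted = f"GO:{n_terms:07d}"
    covered = set()
    for study in (study_a, study_b):
        k = max(2, int(round(planted_coverage * len(study))))
        covered.update(rng.choice(np.array(study), size=k, replace=False))
    background = [g for g in universe if g not in covered]
    extra = rng.choice(np.array(background), size=min(5, len(background)), replace=False)
    for g in sorted(covered) + list(extra):
        rows.append({"gene": g, "term": planted})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True), planted


# ---------------------------------------------------------------------------
# alignment clusters with known filtering fates

DEFAULT_CLUSTER_FATES = {"passed": 40, "dropped_length": 35, "dropped_short_seqs": 25}


def simulate_alignment_clusters(
    fates: dict[str, int] | None = None,
    min_len: int = 300,
    seed=0,
):
    """Alignment clusters whose fate under the default filter is known.

    Three constructions: ``passed`` (gapless, length >= min_len),
    ``dropped_length`` (gapless but shorter than min_len) and
    ``dropped_short_seqs`` (long alignment in which all but one sequence
    degaps below min_len). Returns (clusters, truth DataFrame).
    """
    from .msa import AlignmentCluster

    rng = _rng(seed)
    fates = dict(DEFAULT_CLUSTER_FATES if fates is None else fates)
    alphabet = np.array(list("ACGT"))

    def bases(k):
        return "".join(rng.choice(alphabet, size=k))

    clusters, rows = [], []
    order = [f for f, k in sorted(fates.items()) for _ in range(k)]
    rng.shuffle(order)
    for i, fate in enumerate(order):
        cid = f"cluster{i:03d}"
        n_seq = int(rng.integers(3, 6))
        if fate == "passed":
            length = int(rng.integers(min_len + 50, min_len + 200))
            seqs = {f"{cid}_s{j}": bases(length) for j in range(n_seq)}
        elif fate == "dropped_length":
            length = int(rng.integers(min_len // 2, min_len))
            seqs = {f"{cid}_s{j}": bases(length) for j in range(n_seq)}
        elif fate == "dropped_short_seqs":
            length = int(rng.integers(min_len + 100, min_len + 250))
            seqs = {f"{cid}_s0": bases(length)}
            for j in range(1, n_seq):
                # bases at both termini, heavy interior gapping -> degaps short
                n_keep = int(rng.integers(min_len // 3, min_len - 10))
                keep = {0, length - 1}
                keep.update(rng.choice(np.arange(1, length - 1),
                                       size=n_keep - 2, replace=False))
                seqs[f"{cid}_s{j}"] = "".join(
                    bases(1) if c in keep else "-" for c in range(length)
                )
        else:
            raise ValueError(f"unknown planted fate {fate!r}")
        clusters.append(AlignmentCluster.from_mapping(cid, seqs))
        rows.append({"cluster": cid, "true_fate": fate})
    return clusters, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# write-everything entry point used by the CLI and the pipeline smoke run


def simulate_all(out_dir: str | Path, seed: int = 0, config: dict | None = None) -> None:
    """Generate every pipeline input under ``out_dir`` with a truth/ folder."""
    cfg = dict(config or {})
    out = Path(out_dir)
    truth_dir = out / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=6)

    trials, tr_truth = simulate_oviposition(seed=int(seeds[0]))
    cio.write_table(trials, out / "oviposition_trials.tsv")
    cio.write_table(tr_truth, truth_dir / "oviposition_truth.tsv")

    ca, cb, ga, gb, de_truth = simulate_de_counts(
        n_genes=int(cfg.get("de_n_genes", 5000)),
        lfc=float(cfg.get("de_lfc", 3.0)),
        dispersion=float(cfg.get("de_dispersion", 0.05)),
        seed=int(seeds[1]),
    )
    cio.write_table(ca.rename_axis("gene").reset_index(), out / "counts_A.tsv")
    cio.write_table(cb.rename_axis("gene").reset_index(), out / "counts_B.tsv")
    for name, groups in (("A", ga), ("B", gb)):
        gdf = pd.DataFrame(sorted(groups.items()), columns=["sample", "condition"])
        cio.write_table(gdf, out / f"samples_{name}.tsv")
    cio.write_table(de_truth, truth_dir / "de_truth.tsv")

    tpm, sample_species, n_ref, expr_truth = simulate_expression_on_tree(
        n_genes=int(cfg.get("expr_n_genes", 5000)),
        n_linked=int(cfg.get("expr_n_linked", 12)),
        slope=float(cfg.get("expr_slope", -30.0)),
        bm_sigma=float(cfg.get("expr_bm_sigma", 1.6)),
        seed=int(seeds[2]),
    )
    cio.write_table(tpm.rename_axis("gene").reset_index(), out / "expression_tpm.tsv")
    cio.write_table(pd.DataFrame(sorted(sample_species.items()),
                                 columns=["sample", "species"]),
                    out / "expression_samples.tsv")
    cio.write_table(pd.DataFrame(sorted(n_ref.items()), columns=["species", "n_ref"]),
                    out / "reference_sizes.tsv")
    cio.write_table(expr_truth, truth_dir / "expression_truth.tsv")
    (out / "species_tree.nwk").write_text(DEFAULT_TREE_NEWICK + "\n", encoding="utf-8")
    pi_rows = [{"species": sp, "pi_mean": th} for sp, th in sorted(SPECIES_THETA.items())]
    cio.write_table(pd.DataFrame(pi_rows), out / "preference_index.tsv")

    branch, branch_site, sel_truth = simulate_selection_tables(
        n_genes=int(cfg.get("sel_n_genes", 6038)),
        effect=float(cfg.get("sel_effect", 30.0)),
        seed=int(seeds[3]),
    )
    for fore, df in branch.items():
        cio.write_table(df, out / f"branch_{fore}.tsv")
    for fore, df in branch_site.items():
        cio.write_table(df, out / f"branch_site_{fore}.tsv")
    cio.write_table(sel_truth, truth_dir / "selection_truth.tsv")

    genes = list(de_truth["gene"])
    study_a = list(de_truth.loc[de_truth["category"] != "null", "gene"][:60])
    study_b = list(de_truth.loc[de_truth["category"] != "null", "gene"][40:100])
    ann, planted_term = simulate_annotations(genes, study_a, study_b, seed=int(seeds[4]))
    cio.write_table(ann, out / "annotations.tsv")
    cio.write_gene_list(study_a, out / "study_A.txt")
    cio.write_gene_list(study_b, out / "study_B.txt")
    cio.write_gene_list(genes, out / "universe.txt")
    (truth_dir / "planted_term.txt").write_text(planted_term + "\n", encoding="utf-8")

    clusters, fate_truth = simulate_alignment_clusters(seed=int(seeds[5]))
    from .msa import write_cluster_dir

    write_cluster_dir(clusters, out / "clusters")
    cio.write_table(fate_truth, truth_dir / "cluster_fates.tsv")
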