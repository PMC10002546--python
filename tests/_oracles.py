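"""Independent reference implementations used as test oracles.

These are deliberately naive: explicit loops, Counter-based set logic and
direct formula transcriptions, kept separate from the package code paths
they check.
"""

import itertools
from collections import Counter

import numpy as np
from scipy.stats import rankdata


def bh_stepup_reference(p):
    """Benjamini–Hochberg step-up by the textbook formula:
    q_i = min over j with p_(j) ≥ p_(i) of m·p_(j)/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for back, idx in enumerate(order[::-1]):
        j = m - back  # 1-based rank of p_(j)
        running = min(running, m * p[idx] / j)
        q[idx] = min(running, 1.0)
    return q


def ranksum_exact_reference(x, y):
    """Two-sided rank-sum p by exhaustive enumeration over label
    assignments: P(|S − E[S]| ≥ |s_obs − E[S]|)."""
    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n = len(pooled)
    n1 = len(x)
    mu = n1 * (n + 1) / 2.0
    s_obs = sum(ranks[:n1])
    dev = abs(s_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        s = sum(ranks[i] for i in comb)
        total += 1
        if abs(s - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def pearson_closed_form(x, y):
    """Pearson r by the direct sum formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def qc_three_pass_reference(dense, symbols, min_genes, min_cells, max_mito, prefix="MT-"):
    """Brute-force QC: returns (kept_gene_idx, kept_cell_idx).

    Pass 1 drops cells with detected genes < min_genes; pass 2 drops cells
    with mito fraction > max_mito; pass 3 drops genes detected in fewer
    than min_cells surviving cells.
    """
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    mito = [s.lower().startswith(prefix.lower()) for s in symbols]
    kept_cells = []
    for c in range(n_cells):
        detected = sum(1 for g in range(n_genes) if dense[g, c] > 0)
        if detected < min_genes:
            continue
        total = dense[:, c].sum()
        mito_total = sum(dense[g, c] for g in range(n_genes) if mito[g])
        frac = mito_total / total if total > 0 else 0.0
        if frac > max_mito:
            continue
        kept_cells.append(c)
    kept_genes = []
    for g in range(n_genes):
        n_detected = sum(1 for c in kept_cells if dense[g, c] > 0)
        if n_detected >= min_cells:
            kept_genes.append(g)
    return kept_genes, kept_cells


def harmonize_reference(tables, reference):
    """Brute-force strict 1-1 intersection of pairwise ortholog tables.

    ``tables``: list of (species_a, species_b, pairs).  Returns
    {ref_gene: {species: gene}} over genes surviving every table.
    """
    per_species = {}
    for a, b, pairs in tables:
        if a == reference:
            other, oriented = b, list(dict.fromkeys(pairs))
        else:
            other, oriented = a, list(dict.fromkeys((y, x) for x, y in pairs))
        ca = Counter(r for r, _ in oriented)
        cb = Counter(o for _, o in oriented)
        per_species[other] = {
            r: o for r, o in oriented if ca[r] == 1 and cb[o] == 1
        }
    common = None
    for kept in per_species.values():
        common = set(kept) if common is None else common & set(kept)
    return {
        r: {species: kept[r] for species, kept in per_species.items()}
        for r in (common or set())
    }
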