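"""Gene-set machinery: hypergeometric overlap enrichment with FDR, and
cell-type enrichment against specificity-index-probability (pSI)
thresholded marker sets.

The pSI of gene g for cell type c is a permutation-calibrated upper-tail
probability of the gene's specificity statistic — the margin by which its
mean expression in c exceeds its maximum over the remaining cell types —
so small pSI marks genes expressed specifically in one cell type. Marker
sets at stricter pSI thresholds are nested inside looser ones, giving the
classic nested-hexagon display, and the candidate list is tested against
every (cell type x threshold) marker set by the hypergeometric upper tail
with joint Benjamini-Hochberg FDR across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import InvalidArgumentError, bh_fdr

PSI_THRESHOLDS = (0.05, 0.01, 0.001, 1e-4)


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a background universe."""

    sets: dict[str, list[str]]
    universe: list[str]
    source: str = "unknown"

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if not uni:
            raise InvalidArgumentError("empty universe")
        self.universe = sorted(uni)
        self.sets = {name: sorted(set(genes) & uni)
                     for name, genes in self.sets.items()}


def hypergeom_enrich(query: list[str], collection: GeneSetCollection,
                     fdr_alpha: float = 0.10) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test of a query list against each
    set in the collection, BH-FDR corrected across sets.

    Query genes outside the universe are dropped (count reported in
    ``frame.attrs['n_query_outside_universe']``); rows are sorted by p
    with a deterministic tie-break on set name.
    """
    uni = set(collection.universe)
    q_in = sorted(set(query) & uni)
    n_out = len(set(query)) - len(q_in)
    M, N = len(uni), len(q_in)
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        K = len(genes)
        overlap = sorted(set(genes) & set(q_in))
        k = len(overlap)
        p = float(sps.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"set_name": name, "overlap_count": k, "set_size": K,
                     "query_size": N, "universe_size": M, "p": p,
                     "overlapping_genes": ",".join(overlap)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out.p.to_numpy()).q
        out["significant"] = out.q < fdr_alpha
        out = out.sort_values(["p", "set_name"],
                              kind="mergesort").reset_index(drop=True)
    out.attrs["n_query_outside_universe"] = n_out
    return out


@dataclass
class PsiTable:
    """Specificity-index probabilities per (gene, cell type)."""

    values: pd.DataFrame                 # genes x cell types, in (0, 1]
    thresholds: tuple = PSI_THRESHOLDS

    def markers(self, cell_type: str, threshold: float) -> list[str]:
        col = self.values[cell_type]
        return sorted(col.index[col < threshold])


def compute_psi(cell_expression: pd.DataFrame, n_permutations: int = 200,
                seed: int = 0,
                thresholds: tuple = PSI_THRESHOLDS) -> PsiTable:
    """Permutation-calibrated specificity index probability.

    `cell_expression` is a genes x cell-types matrix of mean expression
    (log scale). The specificity statistic for (g, c) is
    ``x[g, c] - max_{c' != c} x[g, c']``; its null distribution is built by
    shuffling each gene's row independently (cell types exchangeable under
    the null) and pooling across genes and permutations. pSI is the
    fraction of null statistics at least as large. Constant rows get
    pSI = 1 (no specificity information).
    """
    X = cell_expression.to_numpy(float)
    n_genes, n_ct = X.shape
    if n_ct < 2:
        raise InvalidArgumentError("need >= 2 cell types")
    if n_genes < 50:
        raise InvalidArgumentError("need >= 50 genes")
    rng = np.random.default_rng(seed)

    def spec_stat(M):
        order = np.argsort(M, axis=1)
        top = M[np.arange(len(M)), order[:, -1]]
        second = M[np.arange(len(M)), order[:, -2]]
        # margin vs the best *other* cell type: top column gets top-second,
        # all others get value-top (negative)
        out = M - top[:, None]
        out[np.arange(len(M)), order[:, -1]] = top - second
        return out

    obs = spec_stat(X)
    null = np.empty((n_permutations, n_genes, n_ct), dtype=float)
    for b in range(n_permutations):
        perm = np.argsort(rng.random((n_genes, n_ct)), axis=1)
        null[b] = spec_stat(np.take_along_axis(X, perm, axis=1))
    pool = np.sort(null.ravel())
    # pSI = P(null >= observed), add-one corrected to stay in (0, 1]
    n_pool = pool.size
    ge = n_pool - np.searchsorted(pool, obs.ravel(), side="left")
    psi = ((ge + 1) / (n_pool + 1)).reshape(obs.shape)
    constant = np.ptp(X, axis=1) == 0
    psi[constant] = 1.0
    values = pd.DataFrame(psi, index=cell_expression.index,
                          columns=cell_expression.columns)
    return PsiTable(values=values, thresholds=tuple(thresholds))


def csea_enrich(query: list[str], psi: PsiTable, universe: list[str],
                thresholds: tuple | None = None, fdr_alpha: float = 0.10,
                joint_fdr: bool = True) -> pd.DataFrame:
    """Cell-type enrichment of a gene list at nested pSI thresholds.

    For each (cell type, threshold), the marker set is ``pSI < threshold``
    and the query is tested by the hypergeometric upper tail; FDR is taken
    jointly across the whole grid by default (per-threshold with
    ``joint_fdr=False``). Empty marker sets give NA cells.
    """
    thresholds = tuple(thresholds or psi.thresholds)
    extra = set(thresholds) - set(psi.thresholds)
    if extra:
        raise InvalidArgumentError(f"thresholds not in PsiTable: {extra}")
    uni = sorted(set(universe))
    q_in = sorted(set(query) & set(uni))
    M, N = len(uni), len(q_in)
    rows = []
    for ct in psi.values.columns:
        for thr in thresholds:
            markers = [g for g in psi.markers(ct, thr) if g in set(uni)]
            K = len(markers)
            if K == 0:
                rows.append({"cell_type": ct, "psi_threshold": thr,
                             "overlap_count": 0, "set_size": 0,
                             "query_size": N, "universe_size": M,
                             "p": np.nan})
                continue
            k = len(set(markers) & set(q_in))
            rows.append({"cell_type": ct, "psi_threshold": thr,
                         "overlap_count": k, "set_size": K,
                         "query_size": N, "universe_size": M,
                         "p": float(sps.hypergeom.sf(k - 1, M, K, N))})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    if joint_fdr:
        ok = out.p.notna()
        if ok.any():
            out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy()).q
    else:
        for thr in thresholds:
            sel = (out.psi_threshold == thr) & out.p.notna()
            if sel.any():
                out.loc[sel, "q"] = bh_fdr(out.loc[sel, "p"].to_numpy()).q
    out["significant"] = out.q < fdr_alpha
    return out


def csea_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Nested-hexagon style summary: one row per cell type with the
    per-threshold significance pattern and the best q."""
    rows = []
    for ct, g in grid.groupby("cell_type", sort=True):
        g = g.sort_values("psi_threshold", ascending=False)
        rows.append({
            "cell_type": ct,
            "pattern": "".join("*" if s else ("." if pd.notna(q) else "x")
                               for s, q in zip(g.significant, g.q)),
            "best_q": g.q.min(),
            "any_significant": bool(g.significant.any()),
        })
    return pd.DataFrame(rows)
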