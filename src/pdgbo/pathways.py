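"""Pathway enrichment and its correlation with drug response.

Single-sample gene-set enrichment (ssGSEA): genes of one sample are ranked
by expression; the enrichment score is the sum of the running difference
between the weighted in-set rank CDF and the unweighted out-of-set CDF,

    ES = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{k<=i, k in S} w_k / sum_{k in S} w_k,   w_k = nr_k**alpha,
    P_out(i) = |{k<=i, k not in S}| / (N - |S|),

with nr_k the normalized rank (1 for the top gene) and alpha = 0.25 by
default.  Enrichment scores are standardized across samples (inter-sample
z), correlated with per-drug response scores (Pearson), and the pathway
rows of the resulting correlation matrix are hierarchically clustered
(1 - Pearson distance, average linkage, k = 3) into C1 (response negatively
correlated with enrichment), C2 (positively correlated) and C3 (mixed).
Per-drug OLS regression on annotated target pathways rounds out the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import linregress, pearsonr, rankdata

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "ssgsea_matrix",
    "zscore_enrichment",
    "cluster_pathways",
    "correlate_drug_pathway",
    "regress_drug_on_target_pathways",
]

LOW_N = 5  # correlations/regressions with fewer samples are flagged


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways from a GMT file)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file (name<TAB>description<TAB>gene...): dedup, reject empties."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need >= 3 tab-separated fields)"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            genes = list(seen)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc, source=path)


def write_gmt(collection: GeneSetCollection | dict[str, list[str]], path: str) -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    desc = (
        collection.descriptions if isinstance(collection, GeneSetCollection) else {}
    )
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, desc.get(name, "na"), *genes]) + "\n")


def ssgsea_score(
    expression: pd.Series, gene_set: list[str] | set[str], alpha: float = 0.25
) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Genes are ordered by decreasing expression (ties broken by average
    rank for the weights, and by gene name for the walk order, which keeps
    the score reproducible).  Requires >= 2 set genes present in the
    profile and a non-empty complement.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    expr = expression.astype(float)
    genes = expr.index
    in_set = genes.isin(set(gene_set))
    n = len(genes)
    n_in = int(in_set.sum())
    if n_in < 2:
        raise ValueError("fewer than 2 gene-set genes overlap the expression profile")
    if n_in == n:
        raise ValueError("gene-set complement is empty")
    # average ranks on ties; normalized so the top gene has rank ~1
    ranks = rankdata(expr.to_numpy(), method="average")  # 1 = lowest
    norm_rank = ranks / n
    weights = norm_rank**alpha
    # walk in descending expression; tie-break on gene name for determinism
    order = np.lexsort((np.asarray(genes), -expr.to_numpy()))
    w = weights[order]
    s = in_set[order]
    w_in = np.where(s, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~s) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expression: pd.DataFrame,
    collection: GeneSetCollection | dict[str, list[str]],
    alpha: float = 0.25,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """ES matrix (pathway x sample) over a genes-x-samples expression frame.

    Pathways with insufficient overlap are skipped with a warning.
    """
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    rows = {}
    for name, genes in sets.items():
        overlap = expression.index.isin(set(genes)).sum()
        if overlap < min_overlap or overlap == len(expression.index):
            warnings.warn(f"skipping pathway {name!r}: unusable overlap ({overlap})")
            continue
        rows[name] = [
            ssgsea_score(expression[s], genes, alpha=alpha) for s in expression.columns
        ]
    return pd.DataFrame(rows, index=expression.columns).T


def zscore_enrichment(es: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Inter-sample standardization of each pathway row (sample sd, n-1).

    Constant rows become all-zero and are returned in the flag list.
    """
    if es.shape[1] < 2:
        raise ValueError("need >= 2 samples to standardize enrichment")
    vals = es.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    flagged = [str(p) for p, f in zip(es.index, flat) if f]
    return pd.DataFrame(z, index=es.index, columns=es.columns), flagged


def correlate_drug_pathway(
    enrichment: pd.DataFrame, response: pd.DataFrame
) -> tuple[pd.DataFrame, int, list[str]]:
    """Pearson r between each pathway's enrichment and each drug's response.

    Both inputs are indexed entity x sample; correlation runs across the
    shared samples.  Returns (r matrix pathway x drug, n shared samples,
    flags).  Fewer than 3 shared samples is an error; n < 5 is flagged
    low-n but allowed (a four-patient cohort is typical).
    """
    shared = [s for s in enrichment.columns if s in response.columns]
    n = len(shared)
    if n < 3:
        raise ValueError(f"only {n} shared samples; need >= 3")
    flags = ["low_n"] if n < LOW_N else []
    e = enrichment[shared].to_numpy(dtype=float)
    r_resp = response[shared].to_numpy(dtype=float)
    if not (np.isfinite(e).all() and np.isfinite(r_resp).all()):
        raise ValueError("non-finite values in enrichment or response")
    rmat = np.empty((e.shape[0], r_resp.shape[0]))
    for i in range(e.shape[0]):
        for j in range(r_resp.shape[0]):
            rmat[i, j] = pearsonr(e[i], r_resp[j]).statistic
    return (
        pd.DataFrame(rmat, index=enrichment.index, columns=response.index),
        n,
        flags,
    )


def cluster_pathways(
    r_matrix: pd.DataFrame, k: int = 3, metric: str = "euclidean"
) -> tuple[list[str], pd.Series]:
    """Cluster pathway rows of the pathway-drug r matrix into C1/C2/C3.

    Average-linkage hierarchical clustering of the rows, tree cut at k.
    The default metric is Euclidean: the clusters of interest are defined
    by the *level* of the correlations (uniformly negative vs uniformly
    positive vs near-zero/mixed), which a correlation ("1 - Pearson")
    distance would remove by centering each row; that metric remains
    available for shape-based grouping.  Cluster labels are assigned by
    mean correlation with drug response: most negative -> C1, most
    positive -> C2, remaining (mixed) -> C3.
    Returns (dendrogram leaf order, pathway -> label series).
    """
    if len(r_matrix) < 3:
        raise ValueError("need >= 3 pathways to cluster")
    x = r_matrix.to_numpy(dtype=float)
    d = pdist(x, metric=metric)
    d = np.nan_to_num(d, nan=1.0)  # constant rows under correlation metric
    link = hierarchy.linkage(d, method="average")
    order = [str(r_matrix.index[i]) for i in hierarchy.leaves_list(link)]
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels_present = sorted(set(raw), key=lambda g: x[raw == g].mean())
    if len(labels_present) == 1:
        name_map = {labels_present[0]: "C3"}
    elif len(labels_present) == 2:
        name_map = {labels_present[0]: "C1", labels_present[-1]: "C2"}
    else:
        # most negative mean r -> C1, most positive -> C2, the rest -> C3
        name_map = {g: "C3" for g in labels_present}
        name_map[labels_present[0]] = "C1"
        name_map[labels_present[-1]] = "C2"
    labels = pd.Series(
        [name_map[g] for g in raw], index=r_matrix.index, name="cluster"
    )
    return order, labels


def regress_drug_on_target_pathways(
    enrichment: pd.DataFrame,
    response: pd.DataFrame,
    drug_pathway_map: dict[str, list[str]] | dict[str, str],
) -> pd.DataFrame:
    """OLS of each drug's response on its annotated target pathway enrichment.

    Reports slope, intercept, Pearson r and the two-sided p-value from the
    t-distribution with n-2 df.  Drugs or pathways missing from the data
    are skipped with a warning, never an error.  n < 5 rows are flagged.
    """
    shared = [s for s in enrichment.columns if s in response.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    records = []
    for drug, pathways in drug_pathway_map.items():
        if isinstance(pathways, str):
            pathways = [pathways]
        if drug not in response.index:
            warnings.warn(f"drug {drug!r} not in response matrix: skipped")
            continue
        for pathway in pathways:
            if pathway not in enrichment.index:
                warnings.warn(f"pathway {pathway!r} not in enrichment matrix: skipped")
                continue
            x = enrichment.loc[pathway, shared].to_numpy(dtype=float)
            y = response.loc[drug, shared].to_numpy(dtype=float)
            fit = linregress(x, y)
            records.append(
                {
                    "drug_id": drug,
                    "pathway": pathway,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r": fit.rvalue,
                    "p": fit.pvalue,
                    "n": len(shared),
                    "flags": "low_n" if len(shared) < LOW_N else "",
                }
            )
    return pd.DataFrame(
        records,
        columns=["drug_id", "pathway", "slope", "intercept", "r", "p", "n", "flags"],
    )
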