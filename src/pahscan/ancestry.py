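"""Ancestry inference and relatedness handling.

Marker SNPs (common, complete, LD-pruned) feed three steps:

* PCA of a labelled reference panel; study samples are *projected* onto the
  reference loadings (never refitted), and each population's scores are
  modelled as a multivariate Gaussian on the leading principal components;
* per-sample population assignment by maximum Gaussian likelihood, with an
  ambiguity margin: when the top two log-likelihoods are closer than the
  margin (default 4.6 nats, i.e. a likelihood ratio of 100), the sample is
  labelled "other" (admixed or unrepresented ancestry);
* pairwise kinship by the KING-robust within-cohort estimator, family
  networks as connected components of the thresholded kinship graph
  (default threshold 0.0442, the conventional 3rd-degree cutoff), and a
  maximum unrelated sample set (exact maximum independent set on small
  components, minimum-degree greedy above the exact-search cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

__all__ = [
    "MarkerParams",
    "MarkerPanel",
    "PopulationModel",
    "ReferencePCA",
    "select_marker_snps",
    "fit_reference_pca",
    "assign_population",
    "estimate_kinship",
    "max_unrelated_set",
    "KINSHIP_THRESHOLD_3RD_DEGREE",
]

KINSHIP_THRESHOLD_3RD_DEGREE = 0.0442
DEFAULT_AMBIGUITY_MARGIN = 4.6  # log-likelihood difference ~ LR 100


@dataclass(frozen=True)
class MarkerParams:
    min_maf: float = 0.30
    window: int = 50        # variants per pruning window
    shift: int = 5
    vif_threshold: float = 2.0


@dataclass
class MarkerPanel:
    keys: list                      # (chrom, pos, ref, alt) per retained SNP
    indices: np.ndarray             # columns retained from the candidate matrix
    params: MarkerParams


@dataclass
class PopulationModel:
    label: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError(f"covariance for {self.label!r} is not symmetric")
        np.linalg.cholesky(self.cov)  # raises if not positive definite

    def loglik(self, scores: np.ndarray) -> np.ndarray:
        return multivariate_normal.logpdf(scores, mean=self.mean, cov=self.cov)


@dataclass
class ReferencePCA:
    loadings: np.ndarray            # n_snps x n_pcs
    snp_means: np.ndarray           # per-SNP mean dosage in the reference
    snp_scales: np.ndarray          # per-SNP sd used for standardisation
    models: dict = field(default_factory=dict)
    n_pcs: int = 5

    def project(self, genotypes: np.ndarray) -> np.ndarray:
        g = np.atleast_2d(np.asarray(genotypes, dtype=float))
        if np.isnan(g).any():
            raise ValueError("missing genotypes on the marker panel")
        z = (g - self.snp_means) / self.snp_scales
        return z @ self.loadings


def _vif(candidate: np.ndarray, kept: np.ndarray) -> float:
    """Variance inflation factor of a SNP against already-kept window SNPs."""
    if kept.size == 0 or kept.shape[1] == 0:
        return 1.0
    y = candidate - candidate.mean()
    x = kept - kept.mean(axis=0)
    denom = float(y @ y)
    if denom == 0:
        return np.inf
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    r2 = 1.0 - float(resid @ resid) / denom
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def select_marker_snps(genotypes, keys, params: MarkerParams = MarkerParams()) -> MarkerPanel:
    """Select the ancestry marker panel from candidate SNP genotypes.

    ``genotypes``: complete n_samples x n_snps dosage matrix (no missing
    entries allowed).  MAF >= ``min_maf`` first; then sliding-window VIF
    pruning (windows of ``window`` variants shifting by ``shift``): a SNP is
    dropped when its VIF against the SNPs already retained in the current
    window exceeds ``vif_threshold``.  Deterministic given input order.
    """
    g = np.asarray(genotypes, dtype=float)
    if np.isnan(g).any():
        raise ValueError("candidate marker SNPs must have no missing genotypes")
    af = g.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    candidates = np.where(maf >= params.min_maf)[0]
    if candidates.size == 0:
        raise ValueError("no SNP passes the MAF criterion; empty marker panel")

    removed = np.zeros(g.shape[1], dtype=bool)
    ncand = candidates.size
    start = 0
    while True:
        window_idx = candidates[start:start + params.window]
        kept_in_window: list[int] = []
        for j in window_idx:
            if removed[j]:
                continue
            kept = g[:, kept_in_window] if kept_in_window else np.empty((g.shape[0], 0))
            if _vif(g[:, j], kept) > params.vif_threshold:
                removed[j] = True
            else:
                kept_in_window.append(j)
        if start + params.window >= ncand:
            break
        start += params.shift
    retained = [j for j in candidates if not removed[j]]
    if not retained:
        raise ValueError("VIF pruning removed every candidate SNP; empty marker panel")
    return MarkerPanel(
        keys=[keys[j] for j in retained],
        indices=np.array(retained),
        params=params,
    )


def fit_reference_pca(genotypes, labels, n_pcs: int = 5, ridge: float = 0.0) -> ReferencePCA:
    """PCA of the reference panel plus per-population Gaussian models.

    Genotypes are standardised per SNP (mean-centred, unit variance) before
    the SVD; at least two populations, each with more samples than
    ``n_pcs``, are required.  ``ridge`` adds a diagonal to each population
    covariance (regularisation escape hatch for degenerate clusters).
    """
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels)
    pops = [str(p) for p in pd.unique(labels)]
    if len(pops) < 2:
        raise ValueError("reference panel must contain at least two populations")
    for p in pops:
        if (labels == p).sum() <= n_pcs:
            raise ValueError(f"population {p!r} has too few reference samples")
    means = g.mean(axis=0)
    scales = g.std(axis=0, ddof=0)
    if (scales == 0).any():
        raise ValueError("monomorphic SNP in reference panel; reselect markers")
    z = (g - means) / scales
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_pcs].T
    scores = z @ loadings
    models = {}
    for p in pops:
        s = scores[labels == p]
        cov = np.cov(s, rowvar=False) + ridge * np.eye(n_pcs)
        try:
            models[p] = PopulationModel(p, s.mean(axis=0), cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular covariance for population {p!r}; pass ridge > 0"
            ) from exc
    return ReferencePCA(loadings=loadings, snp_means=means, snp_scales=scales,
                        models=models, n_pcs=n_pcs)


def assign_population(
    genotypes,
    pca: ReferencePCA,
    ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN,
):
    """Assign samples to populations by maximum Gaussian likelihood.

    Projection uses the reference loadings (no refit).  Samples whose top
    two log-likelihoods differ by less than ``ambiguity_margin`` are
    labelled "other".  Returns (labels, scores, loglik DataFrame).
    """
    scores = pca.project(genotypes)
    pops = list(pca.models)
    ll = np.column_stack([pca.models[p].loglik(scores) for p in pops])
    ll = np.atleast_2d(ll)
    order = np.argsort(-ll, axis=1)
    top = order[:, 0]
    margin = ll[np.arange(len(ll)), top] - ll[np.arange(len(ll)), order[:, 1]]
    labels = np.where(margin < ambiguity_margin, "other",
                      np.array(pops, dtype=object)[top])
    return list(labels), scores, pd.DataFrame(ll, columns=pops)


def estimate_kinship(genotypes, sample_ids=None) -> pd.DataFrame:
    """All-pairs KING-robust kinship and mean IBS distance.

    phi_ij = (N_het,het - 2 N_opp-hom) / (N_het(i) + N_het(j)) over the
    marker panel; a duplicated sample (or self-pair) gives ~0.5,
    parent-offspring ~0.25, unrelated ~0.  Returns a long-format DataFrame
    (i < j) with columns sample_i, sample_j, kinship, ibs_distance.
    """
    g = np.asarray(genotypes)
    n, m = g.shape
    if n < 2:
        raise ValueError("kinship needs at least two samples")
    af = g.mean(axis=0) / 2.0
    if ((af == 0) | (af == 1)).all():
        raise ValueError("marker panel is monomorphic in this sample set")
    het = (g == 1).astype(np.float32)
    hom0 = (g == 0).astype(np.float32)
    hom2 = (g == 2).astype(np.float32)
    n_hethet = het @ het.T
    opp = hom0 @ hom2.T
    n_opp = opp + opp.T
    n_het = het.sum(axis=1)
    denom = n_het[:, None] + n_het[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    # fraction of genotype-discordant sites as a coarse IBS distance
    concord = n_hethet + hom0 @ hom0.T + hom2 @ hom2.T
    ibs_dist = 1.0 - concord / m
    ids = np.array(list(sample_ids) if sample_ids is not None else range(n), dtype=object)
    iu, ju = np.triu_indices(n, k=1)
    return pd.DataFrame({
        "sample_i": ids[iu], "sample_j": ids[ju],
        "kinship": phi[iu, ju].astype(float),
        "ibs_distance": ibs_dist[iu, ju].astype(float),
    })


def _exact_mis(graph: nx.Graph) -> set:
    """Exact maximum independent set = maximum clique of the complement."""
    comp = nx.complement(graph)
    clique, _ = nx.max_weight_clique(comp, weight=None)
    return set(clique)


def _greedy_mis(graph: nx.Graph) -> set:
    """Minimum-degree greedy independent set (deterministic tie-break)."""
    g = graph.copy()
    chosen = set()
    while g.number_of_nodes():
        node = min(g.nodes, key=lambda v: (g.degree(v), str(v)))
        chosen.add(node)
        g.remove_nodes_from(list(g.neighbors(node)) + [node])
    return chosen


def max_unrelated_set(
    kinship: pd.DataFrame,
    threshold: float = KINSHIP_THRESHOLD_3RD_DEGREE,
    samples=None,
    exact_limit: int = 15,
):
    """Family networks and a maximum unrelated subset.

    An edge joins any pair with kinship >= threshold; family networks are
    the connected components with >= 2 members.  Components up to
    ``exact_limit`` nodes are solved exactly (branch-and-bound maximum
    independent set); larger ones by the minimum-degree greedy heuristic.
    Returns (sorted unrelated sample list, list of family-network sets).
    """
    graph = nx.Graph()
    if samples is not None:
        graph.add_nodes_from(samples)
    for rec in kinship.itertuples(index=False):
        graph.add_node(rec.sample_i)
        graph.add_node(rec.sample_j)
        if rec.kinship >= threshold:
            graph.add_edge(rec.sample_i, rec.sample_j)
    unrelated: set = set()
    networks = []
    for comp_nodes in nx.connected_components(graph):
        sub = graph.subgraph(comp_nodes)
        if sub.number_of_edges() == 0:
            unrelated |= set(comp_nodes)
            continue
        networks.append(set(comp_nodes))
        if len(comp_nodes) <= exact_limit:
            unrelated |= _exact_mis(sub)
        else:
            unrelated |= _greedy_mis(sub)
    return sorted(unrelated, key=str), networks
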