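"""SV signature extraction by NMF with cluster-stability rank selection.

The samples x classes count matrix M is factorized as M^T ~ S.E with S
(classes x k) the signatures and E (k x samples) the exposures, both
non-negative. Because NMF solutions depend on initialization and on
sampling noise, the number of signatures k is chosen by a stability scan:

1. for each candidate k, run ``n_iter`` factorizations, each on an
   independent Poisson-resampled copy of the count matrix with a fresh
   random non-negative initialization (Frobenius objective, multiplicative
   updates);
2. pool the ``k * n_iter`` signature vectors and partition them into k
   clusters by cosine-distance k-medoids;
3. stability(k) = mean silhouette width over the pooled vectors (cosine
   distance; a singleton cluster, or one whose members are identical,
   scores 1) — high when the same k signatures reappear across restarts;
4. consensus signatures are the L1-normalized cluster means and exposures
   the non-negative least-squares fit of the original (un-resampled)
   matrix onto them.

The selected rank maximizes stability minus the mean relative
reconstruction error (ties to the smaller k). Stability alone cannot
discriminate: every rank at or below the true one tends to be almost
perfectly stable, because a too-small factorization keeps finding the
same merged signatures across restarts. Subtracting the reconstruction
error rewards ranks that both reproduce across restarts and explain the
counts; past the true rank, stability collapses while the error barely
improves, so the combined score peaks at the true rank. The full per-k
table is always reported so the choice can be overridden.
Exposure/group association uses a two-sided Mann-Whitney rank-sum test
per signature with Benjamini-Hochberg correction across signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

from .classification import FeatureMatrix
from .datamodel import SVTabError

__all__ = ["SignatureResult", "nmf_stability_scan", "exposure_association"]


@dataclass
class RankResult:
    """Factorization summary for one candidate rank."""

    k: int
    signatures: pd.DataFrame  # classes x k, columns sum to 1
    exposures: pd.DataFrame  # k x samples, non-negative
    stability: float  # mean silhouette width in [-1, 1]
    reconstruction_error: float  # mean relative Frobenius error over restarts


@dataclass
class SignatureResult:
    """Per-rank results of a stability scan plus the selected rank.

    The selected rank maximizes ``stability - reconstruction_error``
    (ties to the smaller k); inspect :meth:`metrics_table` to override.
    """

    ranks: dict  # k -> RankResult
    selected_rank: int

    @property
    def best(self) -> RankResult:
        return self.ranks[self.selected_rank]

    def metrics_table(self) -> pd.DataFrame:
        rows = [
            (k, r.stability, r.reconstruction_error)
            for k, r in sorted(self.ranks.items())
        ]
        return pd.DataFrame(rows, columns=["k", "stability", "reconstruction_error"])


def _cosine_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1)
    norms[norms == 0] = 1.0
    unit = vectors / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    return 1.0 - sim


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator, n_init: int = 5) -> np.ndarray:
    """Seeded PAM-style k-medoids on a precomputed distance matrix."""
    m = dist.shape[0]
    best_labels, best_cost = None, np.inf
    for _ in range(n_init):
        medoids = list(rng.choice(m, size=k, replace=False))
        for _ in range(100):
            labels = np.argmin(dist[:, medoids], axis=1)
            new_medoids = []
            for c in range(k):
                members = np.where(labels == c)[0]
                if len(members) == 0:
                    # re-seed an empty cluster with the point farthest
                    # from its current medoid
                    far = int(np.argmax(dist[np.arange(m), [medoids[l] for l in labels]]))
                    new_medoids.append(far)
                    continue
                sub = dist[np.ix_(members, members)]
                new_medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
            if new_medoids == medoids:
                break
            medoids = new_medoids
        labels = np.argmin(dist[:, medoids], axis=1)
        cost = dist[np.arange(m), [medoids[l] for l in labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels.copy()
    return best_labels


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette with the convention that degenerate cases score 1.

    A point in a singleton cluster, or one where both the intra- and the
    nearest inter-cluster mean distance vanish (identical vectors), gets
    width 1: the clustering is perfectly stable there, not undefined.
    """
    m = len(labels)
    ks = np.unique(labels)
    if len(ks) == 1:
        return 1.0
    widths = np.empty(m)
    for i in range(m):
        own = labels[i]
        members = np.where(labels == own)[0]
        if len(members) == 1:
            widths[i] = 1.0
            continue
        a = dist[i, members[members != i]].mean()
        b = min(
            dist[i, np.where(labels == other)[0]].mean()
            for other in ks
            if other != own
        )
        denom = max(a, b)
        widths[i] = 1.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


def nmf_stability_scan(
    matrix: FeatureMatrix,
    k_range,
    n_iter: int = 10,
    seed: int = 0,
    max_nmf_iter: int = 500,
) -> SignatureResult:
    """Scan candidate signature counts and pick the most stable one.

    ``matrix`` is the samples x classes count matrix; ``k_range`` an
    iterable of candidate ranks; ``n_iter`` the number of Poisson-resampled
    restarts per rank (>= 2). All randomness (resampling, NMF
    initialization, k-medoids restarts) derives from ``seed``.
    """
    X = matrix.values.to_numpy(dtype=float)  # samples x classes
    if (X < 0).any():
        raise SVTabError("feature matrix must be non-negative")
    ks = sorted(int(k) for k in k_range)
    n_samples, n_classes = X.shape
    if not ks:
        raise SVTabError("empty k_range")
    if ks[0] < 1 or ks[-1] > min(n_samples, n_classes):
        raise SVTabError(
            f"k_range {ks} outside matrix dimensions {n_samples} x {n_classes}"
        )
    if n_iter < 2:
        raise SVTabError("n_iter must be >= 2")

    V = X.T  # classes x samples
    rng = np.random.default_rng(seed)
    results: dict[int, RankResult] = {}
    for k in ks:
        pooled = []
        rel_errors = []
        for _ in range(n_iter):
            resampled = rng.poisson(V).astype(float)
            model = NMF(
                n_components=k,
                init="random",
                solver="mu",
                beta_loss="frobenius",
                max_iter=max_nmf_iter,
                random_state=int(rng.integers(2**31 - 1)),
                tol=1e-5,
            )
            with warnings.catch_warnings():
                # multiplicative updates plateau slowly; the factorization is
                # already adequate at max_nmf_iter
                warnings.simplefilter("ignore", ConvergenceWarning)
                S = model.fit_transform(resampled)  # classes x k
            E = model.components_  # k x samples
            norm = np.linalg.norm(resampled)
            rel_errors.append(
                np.linalg.norm(resampled - S @ E) / norm if norm > 0 else 0.0
            )
            col_sums = S.sum(axis=0)
            col_sums[col_sums == 0] = 1.0
            pooled.append(S / col_sums)
        pooled = np.hstack(pooled).T  # (k*n_iter) x classes
        dist = _cosine_distance_matrix(pooled)
        labels = _kmedoids(dist, k, rng)
        stability = _mean_silhouette(dist, labels)

        consensus = np.zeros((n_classes, k))
        for c in range(k):
            members = pooled[labels == c]
            mean = members.mean(axis=0) if len(members) else np.zeros(n_classes)
            total = mean.sum()
            consensus[:, c] = mean / total if total > 0 else mean
        # deterministic column order: by dominant class, then by its weight
        order = sorted(
            range(k),
            key=lambda c: (int(consensus[:, c].argmax()), -consensus[:, c].max()),
        )
        consensus = consensus[:, order]
        exposures = np.column_stack([nnls(consensus, V[:, j])[0] for j in range(n_samples)])

        sig_names = [f"S{k}_{i + 1}" for i in range(k)]
        results[k] = RankResult(
            k=k,
            signatures=pd.DataFrame(consensus, index=matrix.class_order, columns=sig_names),
            exposures=pd.DataFrame(exposures, index=sig_names, columns=matrix.sample_order),
            stability=stability,
            reconstruction_error=float(np.mean(rel_errors)),
        )

    selected = max(
        ks,
        key=lambda k: (results[k].stability - results[k].reconstruction_error, -k),
    )
    return SignatureResult(ranks=results, selected_rank=selected)


def exposure_association(
    result: SignatureResult | RankResult,
    groups: dict,
) -> pd.DataFrame:
    """Test each signature's exposures between two sample groups.

    ``groups`` maps sample -> 'carrier' or 'non-carrier' (samples missing
    from the mapping are ignored). Returns a table (signature, statistic,
    p, q) where p is the two-sided Mann-Whitney p-value and q its
    Benjamini-Hochberg adjustment across signatures.
    """
    rank = result.best if isinstance(result, SignatureResult) else result
    exposures = rank.exposures
    carriers = [s for s in exposures.columns if groups.get(s) == "carrier"]
    others = [s for s in exposures.columns if groups.get(s) == "non-carrier"]
    if not carriers or not others:
        raise SVTabError("both groups must contain at least one sample")
    rows = []
    for sig in exposures.index:
        x = exposures.loc[sig, carriers].to_numpy(dtype=float)
        y = exposures.loc[sig, others].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = float(len(x) * len(y) / 2), 1.0
        else:
            stat, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append((sig, float(stat), float(p)))
    table = pd.DataFrame(rows, columns=["signature", "statistic", "p"])
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
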