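"""Quantitative analyses of trained networks and recorded activity.

Covers receptive-field reconstruction (ON minus OFF feedforward weights),
hierarchical clustering and correlation matrices of population responses,
lateral-weight statistics (transpose symmetry, weight concentration,
correlated-pair weight share, receptive-field similarity of strongly
connected pairs), spontaneous-activity pattern extraction and matching,
the stimulus-mixture morphing experiment with its regression decomposition,
and firing-rate summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .stimuli import PATCH_SIZE, N_PIXELS, N_CHANNELS, split_on_off


@dataclass
class ResponseMatrix:
    """Cells x presentations response matrix with clustering metadata.

    ``counts`` holds total spikes per E cell per presentation (or mean
    subthreshold potential when ``potentials`` is promoted to the response).
    ``sort_order`` is the presentation permutation produced by
    :func:`cluster_and_sort` (identity until then).
    """

    counts: np.ndarray
    stimulus_ids: np.ndarray
    stim_duration: int = 300
    potentials: np.ndarray | None = None
    sort_order: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_presentations(self) -> int:
        return self.counts.shape[1]


def _corr_columns(M: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of columns; zero-variance columns get 0."""
    M = np.asarray(M, dtype=float)
    centered = M - M.mean(axis=0)
    sd = centered.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(centered)
    Z[:, ok] = centered[:, ok] / sd[ok] / np.sqrt(M.shape[0])
    C = Z.T @ Z
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def reconstruct_rf(W_ff: np.ndarray) -> np.ndarray:
    """Per-cell receptive-field maps: ON weights minus OFF weights.

    ``W_ff`` is (n_cells x 578); the result is (n_cells x 17 x 17).
    """
    W_ff = np.asarray(W_ff, dtype=float)
    if W_ff.ndim != 2 or W_ff.shape[1] != N_CHANNELS:
        raise ValueError(f"W_ff must have {N_CHANNELS} columns")
    on = W_ff[:, :N_PIXELS].reshape(-1, PATCH_SIZE, PATCH_SIZE)
    off = W_ff[:, N_PIXELS:].reshape(-1, PATCH_SIZE, PATCH_SIZE)
    return on - off


def cluster_and_sort(responses: ResponseMatrix,
                     linkage_method: str = "average"):
    """Sort presentations by similarity via hierarchical clustering.

    Distance is 1 - Pearson correlation between response columns, with
    average linkage; the new order is the dendrogram leaf order.  Columns
    with zero variance are assigned correlation 0 by convention and sort
    last.  Returns (sorted ResponseMatrix, correlation matrix of the sorted
    columns).
    """
    M = responses.counts
    if M.shape[1] < 2:
        raise ValueError("need at least 2 presentations to cluster")
    sd = M.std(axis=0)
    ok = np.flatnonzero(sd > 0)
    flat = np.flatnonzero(sd == 0)
    if len(ok) >= 2:
        C_ok = _corr_columns(M[:, ok])
        dist = squareform(np.clip(1.0 - C_ok, 0.0, 2.0), checks=False)
        Z = hierarchy.linkage(dist, method=linkage_method)
        leaf = hierarchy.leaves_list(Z)
        order = np.concatenate([ok[leaf], flat])
    else:
        order = np.concatenate([ok, flat])
    sorted_rm = ResponseMatrix(counts=M[:, order],
                               stimulus_ids=responses.stimulus_ids[order],
                               stim_duration=responses.stim_duration,
                               potentials=None if responses.potentials is None
                               else responses.potentials[:, order],
                               sort_order=order)
    return sorted_rm, _corr_columns(sorted_rm.counts)


def count_response_clusters(responses: ResponseMatrix, max_k: int = 8,
                            min_silhouette: float = 0.25,
                            linkage_method: str = "average") -> int:
    """Estimate the number of discrete response patterns.

    Active (non-zero-variance) presentations are clustered hierarchically on
    correlation distance; candidate partitions with k = 2..max_k clusters are
    scored by mean silhouette width, and the best k is returned.  If no
    partition reaches ``min_silhouette`` — i.e. the active responses form one
    homogeneous block — the count is 1.
    """
    M = responses.counts
    sd = M.std(axis=0)
    ok = np.flatnonzero(sd > 0)
    if len(ok) < 3:
        return 1 if len(ok) else 0
    C = _corr_columns(M[:, ok])
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False),
                          method=linkage_method)
    best_k, best_s = 1, -1.0
    for k in range(2, min(max_k, len(ok) - 1) + 1):
        labels = hierarchy.fcluster(Z, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = _mean_silhouette(D, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k if best_s >= min_silhouette else 1


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = labels == own
        n_same = same.sum()
        a = D[i, same].sum() / (n_same - 1) if n_same > 1 else 0.0
        b = np.inf
        for c in uniq:
            if c == own:
                continue
            b = min(b, D[i, labels == c].mean())
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def weight_symmetry(W_lat_EE: np.ndarray) -> float:
    """Pearson correlation of off-diagonal lateral weights with the transpose.

    Measures how bidirectional the learned connectivity is; returns NaN when
    the off-diagonal entries have no variance (undefined correlation).
    """
    W = np.asarray(W_lat_EE, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W_lat_EE must be square")
    mask = ~np.eye(W.shape[0], dtype=bool)
    a, b = W[mask], W.T[mask]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def weight_concentration(W: np.ndarray, top_fraction: float) -> float:
    """Share of total weight in the strongest ``top_fraction`` of connections.

    Off-diagonal entries only for square (lateral) matrices; all entries for
    rectangular ones.  Returns NaN when the total weight is zero.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    W = np.asarray(W, dtype=float)
    if W.ndim == 2 and W.shape[0] == W.shape[1]:
        vals = W[~np.eye(W.shape[0], dtype=bool)]
    else:
        vals = W.ravel()
    if np.any(vals < 0):
        raise ValueError("weights must be non-negative")
    total = vals.sum()
    if total == 0:
        return float("nan")
    k = int(np.ceil(top_fraction * vals.size))
    top = np.sort(vals)[::-1][:k]
    return float(top.sum() / total)


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def correlated_pair_weight_share(responses: ResponseMatrix,
                                 W_lat_EE: np.ndarray,
                                 top_pair_fraction: float = 0.05) -> float:
    """Lateral-weight share of the most response-correlated cell pairs.

    Unordered E-cell pairs are ranked by the Pearson correlation of their
    response vectors across presentations; the summed (both directions)
    lateral weight within the top ``top_pair_fraction`` of pairs is divided
    by the total lateral weight.  NaN if the total weight is zero.
    """
    if not (0 < top_pair_fraction <= 1):
        raise ValueError("top_pair_fraction must be in (0, 1]")
    W = np.asarray(W_lat_EE, dtype=float)
    n = W.shape[0]
    C = _corr_columns(responses.counts.T)       # cells x cells correlation
    ii, jj = _pair_indices(n)
    corr = C[ii, jj]
    k = int(np.ceil(top_pair_fraction * corr.size))
    top = np.argsort(corr)[::-1][:k]
    pair_w = W[ii[top], jj[top]] + W[jj[top], ii[top]]
    mask = ~np.eye(n, dtype=bool)
    total = W[mask].sum()
    if total == 0:
        return float("nan")
    return float(pair_w.sum() / total)


def rf_pair_similarity(W_ff: np.ndarray, W_lat_EE: np.ndarray,
                       top_weight_fraction: float = 0.1) -> float:
    """Median RF correlation among the most strongly connected cell pairs.

    Pairs are ranked by summed bidirectional lateral weight; for the top
    ``top_weight_fraction`` of pairs, the Pearson correlation between the two
    cells' reconstructed receptive-field maps is computed and the median
    returned.
    """
    rf = reconstruct_rf(W_ff).reshape(W_ff.shape[0], -1)
    W = np.asarray(W_lat_EE, dtype=float)
    n = W.shape[0]
    ii, jj = _pair_indices(n)
    pair_w = W[ii, jj] + W[jj, ii]
    k = int(np.ceil(top_weight_fraction * pair_w.size))
    if k < 1:
        raise ValueError("no qualifying pairs")
    top = np.argsort(pair_w)[::-1][:k]
    cors = np.empty(k)
    for m, t in enumerate(top):
        a, b = rf[ii[t]], rf[jj[t]]
        sa, sb = a.std(), b.std()
        cors[m] = 0.0 if sa == 0 or sb == 0 else float(np.corrcoef(a, b)[0, 1])
    return float(np.median(cors))


def spontaneous_patterns(raster, bin_ms: int = 50,
                         top_fraction: float = 0.3,
                         n_cells: int | None = None) -> np.ndarray:
    """Most-active population patterns of a spontaneous-activity raster.

    E-cell spikes are binned in ``bin_ms`` windows; the ``top_fraction`` of
    bins with the highest total population spike count are selected (ties
    broken in favour of earlier bins) and returned as a cells x bins count
    matrix, ranked by activity.
    """
    if raster.duration < bin_ms:
        raise ValueError("raster shorter than one bin")
    nE = raster.n_E if n_cells is None else n_cells
    n_bins = raster.duration // bin_ms
    sel = raster.neurons < nE
    t = raster.times[sel]
    ids = raster.neurons[sel]
    bins = np.minimum(t // bin_ms, n_bins - 1).astype(np.int64)
    M = np.zeros((nE, n_bins))
    np.add.at(M, (ids, bins), 1.0)
    totals = M.sum(axis=0)
    n_top = int(np.ceil(top_fraction * n_bins))
    # stable sort on -totals keeps earlier bins first among ties
    order = np.argsort(-totals, kind="stable")[:n_top]
    return M[:, order]


def pattern_match_score(patterns_a: np.ndarray,
                        patterns_b: np.ndarray) -> tuple[float, float]:
    """Compare two pattern sets (e.g. spontaneous vs evoked).

    For each column of ``patterns_a``, its best correlation with any column
    of ``patterns_b`` is found.  Returns (mean best-match correlation, mean
    overall cross-correlation); matched structure shows in the first number
    exceeding the second.
    """
    A = np.asarray(patterns_a, dtype=float)
    B = np.asarray(patterns_b, dtype=float)
    n = A.shape[1]
    X = _corr_columns(np.hstack([A, B]))
    cross = X[:n, n:]
    return float(cross.max(axis=1).mean()), float(cross.mean())


def mixture_series(s1: np.ndarray, s2: np.ndarray, n: int = 30) -> list:
    """Linear morph between two patches, from pure s2 to pure s1.

    Element k (1-based) is ((k-1) s1 + (n-k) s2) / (n-1): the first element
    is exactly s2, the last exactly s1.  Blending happens at the normalized-
    patch stage, before the ON/OFF split, so endpoint purity is exact.
    Returns the list of ON/OFF vectors.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("stimuli must have the same shape")
    out = []
    for k in range(n):
        a = k / (n - 1)
        out.append(split_on_off((1.0 - a) * s2 + a * s1))
    return out


def intensity_ramp(s: np.ndarray, n: int = 30,
                   descending: bool = False) -> list:
    """Intensity ramp of a single patch over the same n steps as a mixture."""
    s = np.asarray(s, dtype=float)
    out = []
    for k in range(n):
        a = k / (n - 1)
        if descending:
            a = 1.0 - a
        out.append(split_on_off(a * s))
    return out


def regress_mixture(r_n: np.ndarray, r_1: np.ndarray,
                    r_2: np.ndarray) -> tuple[float, float]:
    """Decompose a mixture response onto the two pure-stimulus responses.

    All three vectors are normalized to unit norm, then r_n is regressed
    (least squares, no intercept) on r_1 and r_2; returns (beta1, beta2).
    A zero-norm r_n yields (0, 0).
    """
    r_n = np.asarray(r_n, dtype=float)
    r_1 = np.asarray(r_1, dtype=float)
    r_2 = np.asarray(r_2, dtype=float)
    n1, n2 = np.linalg.norm(r_1), np.linalg.norm(r_2)
    if n1 == 0 and n2 == 0:
        raise ValueError("r_1 and r_2 must not both be zero")
    nn = np.linalg.norm(r_n)
    if nn == 0:
        import warnings
        warnings.warn("zero-norm mixture response; coefficients set to 0")
        return 0.0, 0.0
    X = np.column_stack([r_1 / n1 if n1 else r_1, r_2 / n2 if n2 else r_2])
    beta, *_ = np.linalg.lstsq(X, r_n / nn, rcond=None)
    return float(beta[0]), float(beta[1])


def mixture_regression_series(responses: np.ndarray) -> tuple[np.ndarray,
                                                              np.ndarray]:
    """(beta1, beta2) series for a cells x n mixture-response matrix.

    The pure-stimulus responses are the first (pure s2) and last (pure s1)
    columns; beta1 weights the response to s1, beta2 the response to s2.
    """
    R = np.asarray(responses, dtype=float)
    r_2, r_1 = R[:, 0], R[:, -1]
    n = R.shape[1]
    b1 = np.empty(n)
    b2 = np.empty(n)
    for k in range(n):
        b1[k], b2[k] = regress_mixture(R[:, k], r_1, r_2)
    return b1, b2


def transition_sharpness(beta_series: np.ndarray) -> float:
    """Largest single-step change in a regression-coefficient series.

    Quantifies how abrupt the switch between response modes is along the
    mixture axis: 1/(n-1) for a linear ramp, 1 for a step function.
    """
    b = np.asarray(beta_series, dtype=float)
    if b.size < 2:
        raise ValueError("series must have length >= 2")
    return float(np.abs(np.diff(b)).max())


def rate_stats(responses: ResponseMatrix,
               stim_duration: float | None = None) -> tuple[float, float,
                                                            float]:
    """(median rate, max rate, median per-stimulus max rate), all in Hz.

    Counts are converted to rates over the stimulus window.  The median is
    over all (cell, presentation) entries; the max is the single largest
    rate; the third statistic is the median over presentations of each
    presentation's most active cell.
    """
    dur = responses.stim_duration if stim_duration is None else stim_duration
    if dur <= 0:
        raise ValueError("stim_duration must be positive")
    rates = responses.counts / (dur * 1e-3)
    return (float(np.median(rates)), float(rates.max()),
            float(np.median(rates.max(axis=0))))


def report(stats: dict, path=None) -> str:
    """Flat key-value report of analysis statistics (TSV; optionally saved)."""
    lines = [f"{k}\t{v}" for k, v in stats.items()]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text
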