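"""Filter-based feature selection: max-normalization, correlation pruning
and minimal-redundancy-maximal-relevance (mRMR) reduction.

The selection stage mirrors a classical radiomics filter pipeline:

1. every feature column is normalized by its maximum absolute entry
   (columns then live in [-1, 1] with max |value| = 1);
2. collinear features (|Pearson| > 0.85 by default) are pruned greedily,
   keeping the member of each pair more correlated with the class target;
3. mutual information (plug-in estimate on equal-frequency discretized
   columns, in bits) drives a backward mRMR deselection down to k = 20
   features using the difference scheme
   score(f) = I(f; target) - mean_g I(f; g);
4. the surviving features are reported in descending order of the absolute
   Pearson correlation with the 0/1 target.

The whole stage is deterministic: the same table always yields the same
selection, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable


@dataclass
class SelectionResult:
    """Outcome of the pruning + mRMR pipeline."""

    selected: list[str]                      # ordered by descending |relevance|
    relevance: pd.Series                     # Pearson corr with target, selected
    mi_relevance: pd.Series                  # MI with target (bits), selected
    dropped_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    #: (kept, dropped, |corr|) log of the correlation pruning

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "relevance": {k: float(v) for k, v in self.relevance.items()},
            "mi_relevance": {k: float(v) for k, v in self.mi_relevance.items()},
            "dropped_pairs": [[a, b, float(c)] for a, b, c in self.dropped_pairs],
        }


def normalize_table(table: FeatureTable) -> FeatureTable:
    """Divide each column by its maximum absolute entry (idempotent).

    All-zero columns are left untouched and listed in the manifest under
    ``zero_columns``.
    """
    out = table.copy()
    maxabs = out.data.abs().max(axis=0)
    zero_cols = list(maxabs.index[maxabs == 0])
    scale = maxabs.replace(0, 1.0)
    out.data = out.data / scale
    out.manifest["zero_columns"] = zero_cols
    out.manifest["max_normalized"] = True
    return out


def pearson_relevance(column: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation between one feature column and the 0/1 target.

    A constant column (or constant target) maps to 0 rather than NaN.
    """
    x = np.asarray(column, float)
    y = np.asarray(target, float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def relevance_series(table: FeatureTable) -> pd.Series:
    return pd.Series(
        {c: pearson_relevance(table.data[c].to_numpy(), table.labels)
         for c in table.data.columns}
    )


def discretize_equal_frequency(column: np.ndarray, bins: int = 4) -> np.ndarray:
    """Integer labels 1..bins by equal-frequency (rank) binning.

    With fewer distinct values than bins, each distinct value becomes its own
    label (a constant column collapses to a single label).  Otherwise rank
    order decides the bin; ties are broken by value order then index (stable
    sort), which keeps bin occupancies within one of n/bins.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(column)
    uniq, inv = np.unique(x, return_inverse=True)
    if uniq.size < bins:
        return inv + 1
    n = x.size
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * bins // n + 1
    return labels


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete label vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())


def _discretized_matrix(table: FeatureTable, bins: int) -> np.ndarray:
    return np.column_stack([
        discretize_equal_frequency(table.data[c].to_numpy(), bins)
        for c in table.data.columns
    ])


def _pairwise_mi(disc: np.ndarray, block: int = 256) -> np.ndarray:
    """Symmetric plug-in MI matrix (bits); diagonal = per-column entropy.

    Vectorized: columns are one-hot encoded so the joint histogram of every
    pair is a single tensor contraction; equals
    :func:`mutual_information` applied pairwise.
    """
    n, m = disc.shape
    nb = int(disc.max())
    onehot = np.zeros((n, m, nb))
    rows = np.repeat(np.arange(n), m)
    onehot[rows, np.tile(np.arange(m), n), (disc - 1).ravel()] = 1.0
    marg = onehot.sum(axis=0) / n                       # (m, nb)
    out = np.empty((m, m))
    for start in range(0, m, block):
        stop = min(start + block, m)
        # joint[a, b, i, j] = #(x_a == i, x_b == j) / n
        joint = np.einsum("nai,nbj->abij", onehot[:, start:stop], onehot) / n
        indep = marg[start:stop, None, :, None] * marg[None, :, None, :]
        ratio = np.divide(joint, indep, out=np.ones_like(joint),
                          where=joint > 0)
        out[start:stop] = (joint * np.log2(ratio, where=joint > 0,
                                           out=np.zeros_like(joint))
                           ).sum(axis=(2, 3))
    return out


def mi_map(table: FeatureTable, bins: int = 4) -> pd.DataFrame:
    """Pairwise mutual-information map over discretized feature columns."""
    disc = _discretized_matrix(table, bins)
    mat = _pairwise_mi(disc)
    return pd.DataFrame(mat, index=table.data.columns, columns=table.data.columns)


def prune_correlated(table: FeatureTable, threshold: float = 0.85,
                     relevance: pd.Series | None = None
                     ) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Greedy removal of one member of every |Pearson| > threshold pair.

    Pairs are visited in descending |corr| order; from each still-alive pair
    the member with lower |relevance| is dropped (ties: the later column).
    Afterwards no surviving pair exceeds the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if relevance is None:
        relevance = relevance_series(table)
    cols = list(table.data.columns)
    X = table.data.to_numpy(float)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    corr = np.abs(Z.T @ Z) / X.shape[0]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    iu = np.triu_indices(len(cols), k=1)
    over = corr[iu] > threshold
    pairs = sorted(
        zip(iu[0][over], iu[1][over], corr[iu][over]),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    alive = np.ones(len(cols), dtype=bool)
    log: list[tuple[str, str, float]] = []
    rel = np.abs(relevance.reindex(cols).to_numpy(float))
    for a, b, c in pairs:
        if not (alive[a] and alive[b]):
            continue
        drop = b if rel[b] <= rel[a] else a
        keep = a if drop == b else b
        alive[drop] = False
        log.append((cols[keep], cols[drop], float(c)))
    kept = [c for c, ok in zip(cols, alive) if ok]
    out = table.copy()
    out.data = out.data[kept]
    out.manifest["pruned"] = [c for c, ok in zip(cols, alive) if not ok]
    return out, log


def mrmr_rank(table: FeatureTable, k: int = 20, bins: int = 4,
              redundancy_weight: float = 1.0, scheme: str = "backward",
              prune_threshold: float | None = None) -> SelectionResult:
    """mRMR reduction of a (pruned, normalized) table to k features.

    Backward deselection (default): repeatedly remove the feature minimizing
    score(f) = I(f; target) - w * mean_{g remaining} I(f; g) until k remain
    (difference scheme).  A forward variant is available for comparison.
    The returned list is ordered by descending |Pearson relevance| as reported.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    work = table
    dropped: list[tuple[str, str, float]] = []
    if prune_threshold is not None:
        work, dropped = prune_correlated(work, prune_threshold)
    cols = list(work.data.columns)
    m = len(cols)
    if k >= m:
        import warnings

        if k > m:
            warnings.warn(f"k={k} exceeds available features ({m}); keeping all")
        chosen = np.ones(m, dtype=bool)
    else:
        disc = _discretized_matrix(work, bins)
        rel_mi = np.array([mutual_information(disc[:, a], work.labels)
                           for a in range(m)])
        mi = _pairwise_mi(disc)
        np.fill_diagonal(mi, 0.0)
        if scheme == "backward":
            # remove the feature whose removal leaves the best remaining set
            # under the difference criterion
            # phi(S) = mean_f I(f;t) - w * mean_{f<g in S} I(f;g)
            chosen = np.ones(m, dtype=bool)
            red_sum = mi.sum(axis=1)          # per-feature MI sum over alive
            red_total = red_sum.sum() / 2.0   # sum over alive pairs
            rel_sum = rel_mi.sum()
            n_alive = m
            while n_alive > k:
                idx = np.flatnonzero(chosen)
                n1 = n_alive - 1
                pair_n = n1 * (n1 - 1) / 2.0
                rel_part = (rel_sum - rel_mi[idx]) / n1
                red_part = ((red_total - red_sum[idx]) / pair_n
                            if pair_n > 0 else 0.0)
                phi = rel_part - redundancy_weight * red_part
                worst = idx[_argmax_last(phi)]
                chosen[worst] = False
                rel_sum -= rel_mi[worst]
                red_total -= red_sum[worst]
                red_sum -= mi[:, worst]
                n_alive -= 1
        elif scheme == "forward":
            chosen = np.zeros(m, dtype=bool)
            first = int(np.argmax(rel_mi))
            chosen[first] = True
            while chosen.sum() < k:
                cand = np.flatnonzero(~chosen)
                sel = np.flatnonzero(chosen)
                score = rel_mi[cand] - redundancy_weight * mi[np.ix_(cand, sel)
                                                              ].mean(axis=1)
                chosen[cand[int(np.argmax(score))]] = True
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    sel_cols = [c for c, ok in zip(cols, chosen) if ok]
    rel = pd.Series({c: pearson_relevance(work.data[c].to_numpy(), work.labels)
                     for c in sel_cols})
    disc_sel = np.column_stack([
        discretize_equal_frequency(work.data[c].to_numpy(), bins)
        for c in sel_cols
    ])
    mi_rel = pd.Series({c: mutual_information(disc_sel[:, a], work.labels)
                        for a, c in enumerate(sel_cols)})
    order = sorted(range(len(sel_cols)), key=lambda a: (-abs(rel.iloc[a]), a))
    ordered = [sel_cols[a] for a in order]
    return SelectionResult(selected=ordered, relevance=rel[ordered],
                           mi_relevance=mi_rel[ordered], dropped_pairs=dropped)


def _argmax_last(score: np.ndarray) -> int:
    """Index of the maximum; ties resolved to the later position."""
    rev = score[::-1]
    return len(score) - 1 - int(np.argmax(rev))


def select_features(table: FeatureTable, k: int = 20, threshold: float = 0.85,
                    bins: int = 4) -> tuple[FeatureTable, SelectionResult]:
    """Full selection stage: normalize -> prune -> mRMR(k); returns the
    reduced table (columns in reported order) and the selection report."""
    norm = normalize_table(table)
    rel = relevance_series(norm)
    pruned, log = prune_correlated(norm, threshold, rel)
    result = mrmr_rank(pruned, k=k, bins=bins)
    result.dropped_pairs = log
    reduced = norm.copy()
    reduced.data = norm.data[result.selected]
    reduced.manifest["selected"] = result.selected
    return reduced, result
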