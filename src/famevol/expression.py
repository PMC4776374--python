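"""Tissue-atlas analysis: gene-wise normalisation, hierarchical clustering
on Pearson correlation with average linkage, tissue-preference calls,
duplicate expression divergence and qPCR relative expression (2^-ddCt).

The agglomeration is written out here rather than delegated so the merge
rule is total and deterministic (UPGMA update on 1 - r, ties to the
lexicographically smallest pair; constant rows sit at distance 1 from
everything); the test suite cross-checks it against scipy's average
linkage on matrices without ties.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def genewise_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score with the population (divide-by-n) SD.

    Constant rows map to all zeros, so clustering stays total.
    """
    if m.shape[1] < 1:
        raise ValueError("need at least one tissue")
    values = m.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def correlation_distance(m: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between rows; rows with zero variance get distance 1
    to every other row (0 to themselves)."""
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1)
    ok = sd > 0
    d = np.ones((len(m), len(m)))
    if ok.any():
        r = np.corrcoef(values[ok])
        d[np.ix_(ok, ok)] = 1 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.index, columns=m.index)


@dataclass
class Merge:
    left: frozenset[str]
    right: frozenset[str]
    height: float


def hierarchical_cluster(m: pd.DataFrame) -> tuple[list[Merge], list[str]]:
    """Average-linkage agglomeration on the correlation distance.

    Returns the full merge history and the dendrogram leaf order.  At each
    step the minimum-distance cluster pair merges (ties: lexicographically
    smallest pair of founding labels); cluster-cluster distance is the
    unweighted mean of member pairwise distances (UPGMA update).
    """
    if len(m) < 2:
        raise ValueError("need at least two genes")
    d0 = correlation_distance(m)
    labels = list(m.index.astype(str))
    clusters: dict[int, frozenset[str]] = {i: frozenset({l}) for i, l in enumerate(labels)}
    sizes = {i: 1 for i in clusters}
    reps = {i: labels[i] for i in clusters}
    order: dict[int, list[str]] = {i: [labels[i]] for i in clusters}
    d = {(_i, _j): float(d0.iloc[_i, _j]) for _i in clusters for _j in clusters if _i < _j}
    merges: list[Merge] = []
    next_id = len(labels)
    while len(clusters) > 1:
        (i, j), h = min(
            d.items(), key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]]))))
        )
        li, lj = (i, j) if reps[i] <= reps[j] else (j, i)
        merges.append(Merge(clusters[li], clusters[lj], h))
        new = next_id
        next_id += 1
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = sizes[i] + sizes[j]
        reps[new] = min(reps[i], reps[j])
        order[new] = order[li] + order[lj]
        for k in list(clusters):
            if k in (i, j, new):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(new, k), max(new, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        for k in (i, j):
            del clusters[k], sizes[k], reps[k], order[k]
        d.pop((i, j), None)
    leaf_order = order[next_id - 1]
    return merges, leaf_order


def dendrogram_newick(merges: list[Merge], leaf_order: list[str]) -> str:
    """Render the merge history as a newick string with merge heights."""
    node: dict[frozenset[str], str] = {frozenset({l}): l for l in leaf_order}
    height: dict[frozenset[str], float] = {frozenset({l}): 0.0 for l in leaf_order}
    for mg in merges:
        key = mg.left | mg.right
        bl_l = max(mg.height - height[mg.left], 0.0) / 2
        bl_r = max(mg.height - height[mg.right], 0.0) / 2
        node[key] = f"({node[mg.left]}:{bl_l:.6g},{node[mg.right]}:{bl_r:.6g})"
        height[key] = mg.height
    return node[merges[-1].left | merges[-1].right] + ";" if merges else ";"


def tissue_preference(
    m: pd.DataFrame, fold: float = 2.0, floor: float = 1.0
) -> dict[str, list[str]]:
    """Call a gene preferential in tissue t when value(t) >= fold * row
    median and value(t) >= floor; multi-tissue calls allowed."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    calls: dict[str, list[str]] = {}
    med = m.median(axis=1)
    for gid in m.index:
        row = m.loc[gid]
        hit = [t for t in m.columns if row[t] >= fold * med[gid] and row[t] >= floor]
        calls[str(gid)] = hit
    return calls


def duplicate_expression_divergence(
    pairs: list[tuple[str, str]],
    m: pd.DataFrame,
    r_threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-pair similar/divergent call: similar iff Pearson r >= threshold.

    Pairs with a missing gene (or a constant row, where r is undefined) are
    recorded as unevaluated.
    """
    rows = []
    for a, b in pairs:
        if a not in m.index or b not in m.index:
            logger.warning("pair (%s, %s) missing from matrix; skipped", a, b)
            rows.append({"gene_a": a, "gene_b": b, "r": np.nan, "call": "unevaluated"})
            continue
        x, y = m.loc[a].to_numpy(float), m.loc[b].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            rows.append({"gene_a": a, "gene_b": b, "r": np.nan, "call": "unevaluated"})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {"gene_a": a, "gene_b": b, "r": r,
             "call": "similar" if r >= r_threshold else "divergent"}
        )
    return pd.DataFrame(rows)


def cluster_expression_calls(
    clusters: list[list[str]], m: pd.DataFrame, r_threshold: float = 0.8
) -> dict[int, str]:
    """Cluster-level call: similar iff every member pair is similar."""
    out = {}
    for k, members in enumerate(clusters):
        pairs = [
            (a, b) for idx, a in enumerate(members) for b in members[idx + 1 :]
        ]
        calls = duplicate_expression_divergence(pairs, m, r_threshold)["call"]
        if (calls == "unevaluated").any():
            out[k] = "unevaluated"
        else:
            out[k] = "similar" if (calls == "similar").all() else "divergent"
    return out


def ddct(
    sample_target_ct: float,
    sample_reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    d_sample = sample_target_ct - sample_reference_ct
    d_cal = calibrator_target_ct - calibrator_reference_ct
    return float(2.0 ** (-(d_sample - d_cal)))
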