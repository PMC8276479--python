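"""Hierarchical clustering of individuals by CNVR presence vectors, with
clade support from ordinary and multiscale bootstrap resampling.

Individuals are clustered on their 0/1 CNVR presence vectors using
correlation distance (1 - Pearson r) and average-linkage (UPGMA) or
McQuitty (WPGMA) agglomeration. Support for every clade of the reference
tree comes from resampling CNVR columns with replacement:

* BP — bootstrap probability: the fraction of same-size resamples whose
  tree contains the clade;
* AU — approximately unbiased p-value: BP is re-estimated at several
  resample sizes r*m (multiscale bootstrap), the normal quantiles
  z_r = -Phi^-1(BP_r) are fitted with z(r) = v*sqrt(r) + c/sqrt(r) by
  weighted least squares, and AU = 1 - Phi(v - c). AU corrects the
  well-known conservative bias of BP for clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .models import CopyNumberMatrix

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


def presence_vectors(matrix: CopyNumberMatrix, *, use: str = "presence") -> np.ndarray:
    """Individual x CNVR matrix for clustering: binary presence vectors by
    default, or the normalized copy numbers (``use='cn'``)."""
    if use == "presence":
        return matrix.presence.T.astype(float)
    if use == "cn":
        return matrix.cn.T.astype(float)
    raise ValueError(f"use must be 'presence' or 'cn', got {use!r}")


def correlation_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation; a zero-variance vector has no defined
    correlation, its distance is fixed at 1 (uninformative)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("vectors need length >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def correlation_distance_matrix(data: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; rows with zero variance get
    distance 1 to every other row (0 on the diagonal)."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1)
    degenerate = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    dist = 1.0 - corr
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    # numerical noise can leave tiny negatives for identical rows
    np.clip(dist, 0.0, 2.0, out=dist)
    return dist


@dataclass
class ClusterNode:
    """Internal node of the dendrogram."""

    node_id: str
    height: float
    children: list  # ClusterNode or leaf-name str
    leaves: frozenset[str]
    bp: float | None = None
    au: float | None = None
    au_degenerate: bool = False


@dataclass
class ClusterTree:
    root: ClusterNode
    leaf_names: list[str]
    internal_nodes: list[ClusterNode] = field(default_factory=list)

    def clade_map(self) -> dict[frozenset[str], ClusterNode]:
        return {n.leaves: n for n in self.internal_nodes}

    def support_table(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n.node_id,
                "n_leaves": len(n.leaves),
                "height": n.height,
                "bp": n.bp,
                "au": n.au,
                "au_degenerate": n.au_degenerate,
                "leaves": ",".join(sorted(n.leaves)),
            }
            for n in self.internal_nodes
        ]
        return pd.DataFrame(rows)

    def to_newick(self, *, support_scale: float = 100.0) -> str:
        """Newick string; internal nodes labelled with 'AU,BP' (quoted,
        scaled by ``support_scale``) when support has been computed."""

        def fmt(node, parent_height: float | None) -> str:
            if isinstance(node, str):
                s = node
                h = 0.0
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                label = ""
                if node.bp is not None and node.au is not None:
                    label = (
                        f"'{node.au * support_scale:.0f},"
                        f"{node.bp * support_scale:.0f}'"
                    )
                s = f"({inner}){label}"
                h = node.height
            if parent_height is None:
                return s
            return f"{s}:{max(parent_height - h, 0.0):.6g}"

        return fmt(self.root, None) + ";"


def _agglomerate_merges(
    dist: np.ndarray, labels: Sequence[str], method: str
) -> list[tuple[frozenset[int], frozenset[int], float]]:
    """Deterministic agglomeration returning the merge list as leaf-index
    sets. Ties on the minimum distance are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    leaf label)."""
    if method not in {"average", "wpgma"}:
        raise ValueError(f"unknown linkage method {method!r}")
    n = len(labels)
    d = np.array(dist, dtype=float)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    # enforce bitwise symmetry (BLAS-computed correlation matrices can
    # differ in the last ulp across the diagonal, breaking exact tie scans)
    d = 0.5 * (d + d.T)
    if np.any(d < 0) or np.any(np.diag(d) != 0):
        raise ValueError("distances must be nonnegative with zero diagonal")

    active = list(range(n))
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    clabel = {i: labels[i] for i in range(n)}
    merges = []
    big = np.inf
    d = d.copy()
    np.fill_diagonal(d, big)

    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        dmin = sub.min()
        ii, jj = np.nonzero(sub == dmin)
        best = None
        for a, b in zip(ii.tolist(), jj.tolist()):
            if a == b:
                continue
            i, j = active[min(a, b)], active[max(a, b)]
            key = tuple(sorted((clabel[i], clabel[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merges.append((members[i], members[j], float(dmin)))
        # update distances into i (the surviving cluster)
        for k in active:
            if k in (i, j):
                continue
            if method == "average":
                d_new = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
            else:  # wpgma / McQuitty
                d_new = 0.5 * (d[i, k] + d[j, k])
            d[i, k] = d[k, i] = d_new
        members[i] = members[i] | members[j]
        sizes[i] += sizes[j]
        clabel[i] = min(clabel[i], clabel[j])
        active.remove(j)
    return merges


def agglomerate(
    dist: np.ndarray, labels: Sequence[str], method: str = "average"
) -> ClusterTree:
    """Build the dendrogram (UPGMA by default, WPGMA via ``method='wpgma'``)
    with deterministic tie-breaking; no support values attached."""
    labels = list(labels)
    merges = _agglomerate_merges(dist, labels, method)
    node_of: dict[frozenset[int], ClusterNode | str] = {
        frozenset([i]): labels[i] for i in range(len(labels))
    }
    internal = []
    for k, (mi, mj, h) in enumerate(merges, start=1):
        node = ClusterNode(
            node_id=f"N{k}",
            height=h,
            children=[node_of[mi], node_of[mj]],
            leaves=frozenset(labels[x] for x in (mi | mj)),
        )
        node_of[mi | mj] = node
        internal.append(node)
    root = internal[-1] if internal else node_of[frozenset([0])]
    return ClusterTree(root=root, leaf_names=labels, internal_nodes=internal)


def _clade_index_sets(dist: np.ndarray, method: str) -> set[frozenset[int]]:
    """Leaf-index clades of the tree on ``dist`` (fast path for bootstrap
    replicates: integer indices, no node objects)."""
    n = dist.shape[0]
    merges = _agglomerate_merges(dist, [f"{i:06d}" for i in range(n)], method)
    return {mi | mj for mi, mj, _ in merges}


def fit_multiscale(
    bp_by_scale: Sequence[float],
    scales: Sequence[float],
    n_boot: int,
    *,
    weighted: bool = True,
) -> dict:
    """Fit the multiscale-bootstrap model to per-scale clade probabilities.

    z_r = -Phi^-1(BP_r) is modelled as z(r) = v*sqrt(r) + c/sqrt(r); the fit
    is weighted least squares with the delta-method weights
    n_boot * phi(z_r)^2 / (BP_r (1 - BP_r)). Scales where BP_r is 0 or 1
    carry no information about z and are dropped; with fewer than two
    usable scales the fit is flagged degenerate and AU falls back to BP.

    Returns dict with au, v, c, se_v, se_c, degenerate.
    """
    bp = np.asarray(bp_by_scale, dtype=float)
    r = np.asarray(scales, dtype=float)
    if bp.shape != r.shape:
        raise ValueError("bp_by_scale and scales must have equal length")
    finite = (bp > 0.0) & (bp < 1.0)
    if finite.sum() < 2:
        return {
            "au": float("nan"),
            "v": float("nan"),
            "c": float("nan"),
            "se_v": float("nan"),
            "se_c": float("nan"),
            "degenerate": True,
        }
    bp_f, r_f = bp[finite], r[finite]
    z = -ndtri(bp_f)
    sq = np.sqrt(r_f)
    design = np.column_stack([sq, 1.0 / sq])
    if weighted:
        phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        w = n_boot * phi**2 / (bp_f * (1.0 - bp_f))
    else:
        w = np.ones_like(z)
    wd = design * w[:, None]
    xtx = design.T @ wd
    xtz = wd.T @ z
    try:
        beta = np.linalg.solve(xtx, xtz)
        cov = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return {
            "au": float("nan"),
            "v": float("nan"),
            "c": float("nan"),
            "se_v": float("nan"),
            "se_c": float("nan"),
            "degenerate": True,
        }
    v, c = float(beta[0]), float(beta[1])
    return {
        "au": float(1.0 - ndtr(v - c)),
        "v": v,
        "c": c,
        "se_v": float(np.sqrt(cov[0, 0])),
        "se_c": float(np.sqrt(cov[1, 1])),
        "degenerate": False,
    }


def bootstrap_support(
    data: np.ndarray,
    labels: Sequence[str],
    *,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
    method: str = "average",
    weighted_fit: bool = True,
) -> ClusterTree:
    """Cluster individuals (rows of ``data``) and attach BP and AU support.

    Columns (CNVRs — the units of evidence for the clustering) are resampled
    with replacement to round(r*m) for each scale r; BP is the clade
    frequency at r = 1.0 and AU comes from the multiscale fit. The same seed
    reproduces the tree and supports exactly.
    """
    data = np.asarray(data, dtype=float)
    labels = list(labels)
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    scales = [float(s) for s in scales]
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0 (ordinary bootstrap)")
    n, m = data.shape
    if n != len(labels):
        raise ValueError("labels do not match data rows")

    ref = agglomerate(correlation_distance_matrix(data), labels, method)
    leaf_index = {name: i for i, name in enumerate(labels)}
    ref_clades = [
        frozenset(leaf_index[x] for x in node.leaves) for node in ref.internal_nodes
    ]

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(ref_clades), len(scales)), dtype=np.int64)
    for si, r in enumerate(scales):
        m_r = max(2, int(round(r * m)))
        for _ in range(n_boot):
            cols = rng.integers(0, m, size=m_r)
            clades_b = _clade_index_sets(
                correlation_distance_matrix(data[:, cols]), method
            )
            for ci, clade in enumerate(ref_clades):
                if clade in clades_b:
                    counts[ci, si] += 1

    bp_all = counts / float(n_boot)
    s1 = scales.index(1.0)
    for ci, node in enumerate(ref.internal_nodes):
        node.bp = float(bp_all[ci, s1])
        fit = fit_multiscale(bp_all[ci], scales, n_boot, weighted=weighted_fit)
        if fit["degenerate"]:
            node.au = node.bp
            node.au_degenerate = True
        else:
            node.au = fit["au"]
    return ref
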