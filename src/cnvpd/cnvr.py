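"""CNVR construction: call filtering, reciprocal-overlap merging, the
recurrence filter, and per-individual copy-number genotyping.

A CNVR (copy number variation region) is the union span of a set of CNV
calls connected by >= 50% reciprocal overlap. Merging is single-linkage by
default (an edge between any two calls with sufficient reciprocal overlap,
connected components form regions), with an optional stricter clique-style
mode in which every call added to a region must reciprocally overlap all
calls already in it.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .models import CnvCall, CopyNumberMatrix, Cnvr, GenomeModel


def filter_calls(
    calls: Iterable[CnvCall],
    *,
    min_len_bp: int = 1000,
    max_pvalue: float = 1e-3,
    max_q0: float = 0.5,
    genome: GenomeModel | None = None,
) -> list[CnvCall]:
    """Apply the standard read-depth call filters.

    All thresholds are strict: a call survives iff length > ``min_len_bp``,
    pvalue < ``max_pvalue`` and q0 < ``max_q0``. With a genome model, calls on
    non-autosomal chromosomes are removed. Input order is preserved.
    """
    if min_len_bp <= 0 or max_pvalue <= 0 or max_q0 <= 0:
        raise ValueError("filter thresholds must be positive")
    out = []
    for c in calls:
        if c.length <= min_len_bp or c.pvalue >= max_pvalue or c.q0 >= max_q0:
            continue
        if genome is not None and not genome.is_autosome(c.chrom):
            continue
        out.append(c)
    return out


def reciprocal_overlap(a, b) -> float:
    """Reciprocal overlap of two intervals: overlap length divided by the
    *longer*-constraint form min(ov/len(a), ov/len(b)). Objects need
    ``chrom``/``start``/``end`` attributes; 0.0 across chromosomes."""
    if a.end <= a.start or b.end <= b.start:
        raise ValueError("intervals must satisfy end > start")
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _coarse_clusters(starts: np.ndarray, ends: np.ndarray) -> list[slice]:
    """Split calls sorted by start into runs with no bp overlap between runs
    (a sweep on the running max end). Reciprocal overlap is zero across runs,
    so the pairwise test only needs to run within each slice."""
    slices = []
    n = len(starts)
    lo = 0
    run_end = ends[0] if n else 0
    for i in range(1, n):
        if starts[i] >= run_end:
            slices.append(slice(lo, i))
            lo = i
            run_end = ends[i]
        else:
            run_end = max(run_end, ends[i])
    if n:
        slices.append(slice(lo, n))
    return slices


def merge_calls(
    calls: Sequence[CnvCall],
    min_reciprocal: float = 0.5,
    *,
    mode: str = "single",
    id_prefix: str = "CNVR",
) -> list[Cnvr]:
    """Merge calls into CNVRs by reciprocal overlap.

    mode="single": connected components of the >= ``min_reciprocal``
    reciprocal-overlap graph (transitive chains merge). mode="clique":
    greedy left-to-right clustering that requires a call to reciprocally
    overlap every call already in the cluster.

    Deletion and duplication calls may share a CNVR; per-individual type is
    kept on the region's ``type_profile``.
    """
    if not 0.0 < min_reciprocal <= 1.0:
        raise ValueError("min_reciprocal must be in (0, 1]")
    if mode not in {"single", "clique"}:
        raise ValueError(f"unknown merge mode {mode!r}")

    by_chrom: dict[str, list[CnvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)

    regions: list[Cnvr] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        starts = np.array([c.start for c in chrom_calls], dtype=np.int64)
        ends = np.array([c.end for c in chrom_calls], dtype=np.int64)
        lengths = (ends - starts).astype(np.float64)
        for sl in _coarse_clusters(starts, ends):
            sub = chrom_calls[sl]
            if len(sub) == 1:
                regions.append(_make_region(chrom, sub))
                continue
            s, e, ln = starts[sl], ends[sl], lengths[sl]
            # vectorized all-pairs reciprocal overlap within the run
            ov = np.minimum(e[:, None], e[None, :]) - np.maximum(s[:, None], s[None, :])
            np.clip(ov, 0, None, out=ov)
            ro = ov / np.maximum(ln[:, None], ln[None, :])
            adj = ro >= min_reciprocal
            if mode == "single":
                uf = _UnionFind(len(sub))
                ii, jj = np.nonzero(np.triu(adj, k=1))
                for i, j in zip(ii.tolist(), jj.tolist()):
                    uf.union(i, j)
                groups: dict[int, list[CnvCall]] = defaultdict(list)
                for i, call in enumerate(sub):
                    groups[uf.find(i)].append(call)
                for root in sorted(groups):
                    regions.append(_make_region(chrom, groups[root]))
            else:
                clusters: list[list[int]] = []
                for i in range(len(sub)):
                    placed = False
                    for cl in clusters:
                        if all(adj[i, j] for j in cl):
                            cl.append(i)
                            placed = True
                            break
                    if not placed:
                        clusters.append([i])
                for cl in clusters:
                    regions.append(_make_region(chrom, [sub[i] for i in cl]))

    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    width = max(5, len(str(len(regions))))
    for i, r in enumerate(regions, start=1):
        r.cnvr_id = f"{id_prefix}{i:0{width}d}"
    return regions


def _make_region(chrom: str, members: list[CnvCall]) -> Cnvr:
    return Cnvr(
        cnvr_id="",
        chrom=chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        member_calls=sorted(members, key=lambda c: (c.start, c.end, c.individual_id)),
    )


def recurrence_filter(cnvrs: Iterable[Cnvr], min_individuals: int = 3) -> list[Cnvr]:
    """Keep CNVRs carried by at least ``min_individuals`` distinct
    individuals (default 3, i.e. regions found in more than two animals)."""
    return [r for r in cnvrs if len(r.carriers) >= min_individuals]


def genotype_cnvrs(
    cnvrs: Sequence[Cnvr],
    individuals: Sequence[str],
    external_matrix: CopyNumberMatrix | None = None,
) -> CopyNumberMatrix:
    """Build the CNVR x individual copy-number and presence matrices.

    Copy number of a carrier is 2 x the length-weighted mean normalized read
    depth of that individual's member calls; non-carriers take the diploid
    baseline 2.0 with presence 0. If ``external_matrix`` is given (copy
    numbers re-estimated outside this pipeline), it is validated and used
    instead, with presence derived from call membership.
    """
    individuals = list(individuals)
    cnvr_ids = [r.cnvr_id for r in cnvrs]
    col = {ind: j for j, ind in enumerate(individuals)}

    presence = np.zeros((len(cnvrs), len(individuals)), dtype=np.int8)
    for i, r in enumerate(cnvrs):
        for ind in r.carriers:
            if ind not in col:
                raise ValueError(f"carrier {ind!r} missing from individual list")
            presence[i, col[ind]] = 1

    if external_matrix is not None:
        missing_r = set(cnvr_ids) - set(external_matrix.cnvr_ids)
        missing_i = set(individuals) - set(external_matrix.individual_ids)
        if missing_r or missing_i:
            raise ValueError(
                "external matrix is missing labels: "
                f"cnvrs={sorted(missing_r)} individuals={sorted(missing_i)}"
            )
        ridx = [external_matrix.cnvr_ids.index(r) for r in cnvr_ids]
        cidx = [external_matrix.individual_ids.index(i) for i in individuals]
        cn = external_matrix.cn[np.ix_(ridx, cidx)].astype(float)
    else:
        cn = np.full((len(cnvrs), len(individuals)), 2.0)
        for i, r in enumerate(cnvrs):
            acc: dict[str, list[float]] = defaultdict(lambda: [0.0, 0.0])
            for c in r.member_calls:
                a = acc[c.individual_id]
                a[0] += c.length * c.normalized_rd
                a[1] += c.length
            for ind, (wsum, lsum) in acc.items():
                cn[i, col[ind]] = 2.0 * wsum / lsum

    return CopyNumberMatrix(
        cnvr_ids=cnvr_ids, individual_ids=individuals, cn=cn, presence=presence
    )


def total_coverage_bp(cnvrs: Iterable[Cnvr]) -> int:
    """Total autosomal bp covered by CNVR spans (union; overlapping spans,
    possible under clique mode, are not double counted)."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in cnvrs:
        by_chrom[r.chrom].append((r.start, r.end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total
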