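"""Population-differentiation statistics on CNVR copy numbers.

Two statistics are combined:

* pairwise V_ST = (V_T - V_S) / V_T, the copy-number analogue of F_ST, where
  V_T is the variance of the two populations pooled and V_S the average of
  the within-population variances weighted by population size;
* the tie-corrected Kruskal-Wallis rank test across the four regional
  groups (EAT, ASI, AFT, AFH).

A CNVR is called population differentiated when at least one of its pairwise
V_ST values reaches the top 1% of the pooled V_ST distribution AND its
Kruskal-Wallis p-value is below 0.01. No multiple-testing correction is
applied to the Kruskal-Wallis p-values in this dual criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ANALYSIS_GROUPS, CopyNumberMatrix, Group, SampleMeta


@dataclass(frozen=True, slots=True)
class VstResult:
    v_total: float
    v_within: float
    vst_raw: float  # before clamping; may be negative when V_S > V_T
    vst: float  # clamped to [0, 1]


@dataclass(frozen=True, slots=True)
class KwResult:
    h_statistic: float
    df: int
    pvalue: float


def vst(values_a: Sequence[float], values_b: Sequence[float], *, ddof: int = 1) -> VstResult:
    """V_ST between two populations of copy numbers.

    Both populations need at least two members (single-individual breeds must
    be excluded upstream). Degenerate case V_T == 0 (all copy numbers equal)
    yields V_ST = 0: there is no variance to partition.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each population needs >= 2 individuals for V_ST")
    pooled = np.concatenate([a, b])
    v_t = float(np.var(pooled, ddof=ddof))
    v_s = float(
        (a.size * np.var(a, ddof=ddof) + b.size * np.var(b, ddof=ddof))
        / (a.size + b.size)
    )
    if v_t == 0.0:
        return VstResult(0.0, v_s, 0.0, 0.0)
    raw = (v_t - v_s) / v_t
    return VstResult(v_t, v_s, raw, float(min(1.0, max(0.0, raw))))


def _population_columns(
    metas: Iterable[SampleMeta],
    individual_ids: Sequence[str],
    grouping: str,
    exclude_singletons: bool,
    *,
    analysis_groups_only: bool = False,
) -> dict[str, np.ndarray]:
    """Map population label -> column indices in the matrix."""
    by_id = {m.individual_id: m for m in metas}
    missing = [i for i in individual_ids if i not in by_id]
    if missing:
        raise ValueError(f"individuals missing from metadata: {missing[:5]}")
    pops: dict[str, list[int]] = {}
    for j, ind in enumerate(individual_ids):
        m = by_id[ind]
        if grouping == "breed":
            label = m.breed
        elif grouping == "group":
            if analysis_groups_only and m.group not in ANALYSIS_GROUPS:
                continue
            label = m.group.value
        else:
            raise ValueError(f"grouping must be 'breed' or 'group', got {grouping!r}")
        pops.setdefault(label, []).append(j)
    if exclude_singletons:
        pops = {k: v for k, v in pops.items() if len(v) >= 2}
    if len(pops) < 2:
        raise ValueError("fewer than two usable populations after exclusion")
    return {k: np.asarray(v, dtype=int) for k, v in pops.items()}


def _pair_vst_vectors(cn_a: np.ndarray, cn_b: np.ndarray, ddof: int):
    """Vectorized V_ST over CNVR rows for one population pair."""
    n_a, n_b = cn_a.shape[1], cn_b.shape[1]
    var_a = cn_a.var(axis=1, ddof=ddof)
    var_b = cn_b.var(axis=1, ddof=ddof)
    pooled = np.concatenate([cn_a, cn_b], axis=1)
    v_t = pooled.var(axis=1, ddof=ddof)
    v_s = (n_a * var_a + n_b * var_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(v_t > 0, (v_t - v_s) / np.where(v_t > 0, v_t, 1.0), 0.0)
    return v_t, v_s, raw, np.clip(raw, 0.0, 1.0)


def pairwise_vst_matrix(
    matrix: CopyNumberMatrix,
    metas: Iterable[SampleMeta],
    *,
    grouping: str = "group",
    exclude_singletons: bool = True,
    analysis_groups_only: bool = True,
    ddof: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CNVR V_ST for every unordered population pair.

    Returns a long table (cnvr_id, pop_a, pop_b, v_total, v_within, vst_raw,
    vst) and the symmetric mean-V_ST population matrix (mean over CNVRs,
    zero diagonal) used for WPGMA display clustering at breed level.

    With grouping="group", only the four B. taurus regional groups enter when
    ``analysis_groups_only`` (outgroup individuals are left out); with
    grouping="breed" all breeds participate (the outgroup breed included),
    except single-individual breeds when ``exclude_singletons``.
    """
    metas = list(metas)
    pops = _population_columns(
        metas,
        matrix.individual_ids,
        grouping,
        exclude_singletons,
        analysis_groups_only=analysis_groups_only and grouping == "group",
    )
    labels = sorted(pops)
    frames = []
    for pop_a, pop_b in combinations(labels, 2):
        v_t, v_s, raw, clamped = _pair_vst_vectors(
            matrix.cn[:, pops[pop_a]], matrix.cn[:, pops[pop_b]], ddof
        )
        frames.append(
            pd.DataFrame(
                {
                    "cnvr_id": matrix.cnvr_ids,
                    "pop_a": pop_a,
                    "pop_b": pop_b,
                    "v_total": v_t,
                    "v_within": v_s,
                    "vst_raw": raw,
                    "vst": clamped,
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)

    mean = pd.DataFrame(0.0, index=labels, columns=labels)
    for (pop_a, pop_b), grp in long.groupby(["pop_a", "pop_b"]):
        m = float(grp["vst"].mean())
        mean.loc[pop_a, pop_b] = m
        mean.loc[pop_b, pop_a] = m
    return long, mean


def kruskal_wallis(values_by_group: Sequence[Sequence[float]]) -> KwResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from the chi-square upper tail
    with k-1 degrees of freedom. All observations identical across groups is
    not an error: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([g.size for g in groups])
    if np.any(sizes == 0):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    h = 0.0
    offset = 0
    for g, n_i in zip(groups, sizes):
        r_mean = ranks[offset : offset + n_i].mean()
        h += n_i * (r_mean - (n + 1) / 2.0) ** 2
        offset += n_i
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n) if n > 1 else 1.0
    if tie_corr == 0.0:  # every observation identical
        return KwResult(0.0, k - 1, 1.0)
    h /= tie_corr
    p = float(stats.chi2.sf(h, k - 1))
    return KwResult(float(h), k - 1, p)


def kruskal_wallis_table(
    matrix: CopyNumberMatrix,
    metas: Iterable[SampleMeta],
    groups: Sequence[Group] = ANALYSIS_GROUPS,
) -> pd.DataFrame:
    """Kruskal-Wallis across the regional groups for every CNVR.

    Returns a table with cnvr_id, h_statistic, df, pvalue.
    """
    by_id = {m.individual_id: m for m in metas}
    cols = {
        g: np.asarray(
            [j for j, ind in enumerate(matrix.individual_ids) if by_id[ind].group is g],
            dtype=int,
        )
        for g in groups
    }
    empty = [g.value for g, idx in cols.items() if idx.size == 0]
    if empty:
        raise ValueError(f"groups with no individuals: {empty}")
    rows = []
    for i, cnvr_id in enumerate(matrix.cnvr_ids):
        res = kruskal_wallis([matrix.cn[i, idx] for idx in cols.values()])
        rows.append((cnvr_id, res.h_statistic, res.df, res.pvalue))
    return pd.DataFrame(rows, columns=["cnvr_id", "h_statistic", "df", "pvalue"])


def vst_thresholds(
    vst_long: pd.DataFrame,
    quantiles: Sequence[float] = (0.99, 0.999),
    *,
    per_pair: bool = False,
):
    """Empirical quantile thresholds (linear interpolation between order
    statistics) of the pooled pairwise V_ST distribution — or per pair."""
    if per_pair:
        out: dict[tuple[str, str], dict[float, float]] = {}
        for (a, b), grp in vst_long.groupby(["pop_a", "pop_b"]):
            out[(a, b)] = {
                q: float(np.quantile(grp["vst"].to_numpy(), q)) for q in quantiles
            }
        return out
    vals = vst_long["vst"].to_numpy()
    return {q: float(np.quantile(vals, q)) for q in quantiles}


def call_differentiated(
    vst_long: pd.DataFrame,
    kw_table: pd.DataFrame,
    *,
    vst_quantile: float = 0.99,
    extreme_quantile: float = 0.999,
    kw_alpha: float = 0.01,
    per_pair: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Dual-criterion caller for population-differentiated CNVRs.

    A CNVR is differentiated iff any pairwise V_ST >= the ``vst_quantile``
    threshold of the pooled pairwise distribution AND its Kruskal-Wallis
    p-value < ``kw_alpha``. Pairs are annotated as top1/top0.1 classes.

    Returns (per-CNVR table, thresholds dict). The table columns:
    cnvr_id, max_pair_vst, max_pair, top_pairs, top01_pairs, h_statistic,
    kw_pvalue, vst_top, differentiated.
    """
    if vst_long.empty:
        return (
            pd.DataFrame(
                columns=[
                    "cnvr_id",
                    "max_pair_vst",
                    "max_pair",
                    "top_pairs",
                    "top01_pairs",
                    "h_statistic",
                    "kw_pvalue",
                    "vst_top",
                    "differentiated",
                ]
            ),
            {},
        )
    thresholds = vst_thresholds(
        vst_long, (vst_quantile, extreme_quantile), per_pair=per_pair
    )

    df = vst_long.copy()
    if per_pair:
        thr1 = df.apply(
            lambda r: thresholds[(r["pop_a"], r["pop_b"])][vst_quantile], axis=1
        )
        thr01 = df.apply(
            lambda r: thresholds[(r["pop_a"], r["pop_b"])][extreme_quantile], axis=1
        )
    else:
        thr1 = thresholds[vst_quantile]
        thr01 = thresholds[extreme_quantile]
    df["is_top1"] = df["vst"] >= thr1
    df["is_top01"] = df["vst"] >= thr01
    df["pair"] = df["pop_a"] + "-" + df["pop_b"]

    kw = kw_table.set_index("cnvr_id")
    missing = set(df["cnvr_id"]) - set(kw.index)
    if missing:
        raise ValueError(f"CNVRs missing Kruskal-Wallis results: {sorted(missing)[:5]}")

    rows = []
    for cnvr_id, grp in df.groupby("cnvr_id", sort=False):
        imax = grp["vst"].idxmax()
        top_pairs = grp.loc[grp["is_top1"], "pair"].tolist()
        top01_pairs = grp.loc[grp["is_top01"], "pair"].tolist()
        kw_p = float(kw.loc[cnvr_id, "pvalue"])
        vst_top = bool(grp["is_top1"].any())
        rows.append(
            {
                "cnvr_id": cnvr_id,
                "max_pair_vst": float(grp.loc[imax, "vst"]),
                "max_pair": grp.loc[imax, "pair"],
                "top_pairs": ",".join(top_pairs),
                "top01_pairs": ",".join(top01_pairs),
                "h_statistic": float(kw.loc[cnvr_id, "h_statistic"]),
                "kw_pvalue": kw_p,
                "vst_top": vst_top,
                "differentiated": vst_top and kw_p < kw_alpha,
            }
        )
    out = pd.DataFrame(rows).drop_duplicates(subset="cnvr_id")
    return out, thresholds
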