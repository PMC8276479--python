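"""Synthetic multi-population CNV call sets with known ground truth.

The generator emulates the post-calling layer of a population CNV survey:
each locus has a latent per-individual copy number drawn around its
population mean, individuals whose copy number is close to the diploid
baseline usually emit no call (call dropout at CN~2), emitted calls carry
read-depth ratios (CN/2), jittered boundaries and plausible p-value/q0
columns, and a configurable rate of false calls is sprinkled in with QC
values the default filters remove.

Differentiated loci follow the gradient profile seen at real
population-differentiated loci (one group strongly gained, another strongly
reduced, the rest near diploid), so each such locus has one dominant
population pair plus weaker secondary pairs — the structure the top-1%
V_ST rule operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import CnvCall, CnvType, Cnvr, GenomeModel, Group, SampleMeta
from .cnvr import reciprocal_overlap


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults describe the reference scenario: 4 regional groups x 5 breeds
    x 8 individuals over 5 autosomes of 10 Mb, 1000 CNVR loci of which 5%
    are population differentiated with per-group mean copy-number gaps of
    at least 2, within-population noise sd 0.4, 100 bp boundary jitter and
    strong call dropout at diploid copy number.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {str(i): 10_000_000 for i in range(1, 6)}
    )
    n_breeds_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"EAT": 5, "ASI": 5, "AFT": 5, "AFH": 5}
    )
    n_individuals_per_breed: int = 8
    n_cnvr_loci: int = 1000
    frac_differentiated: float = 0.05
    effect_gap: float = 2.0  # minimum per-group mean copy-number gap
    effect_profiles: Sequence[Mapping[str, float]] | None = None
    cn_sd: float = 0.4
    dropout_at_2: float = 0.9
    call_threshold: float = 0.5  # |CN - 2| below this may be dropped
    boundary_jitter_sd: float = 100.0  # bp
    false_call_rate: float = 2.0  # mean false calls per individual
    false_call_survivor_frac: float = 0.0
    locus_length_range: tuple[int, int] = (5_000, 20_000)
    null_means: Sequence[float] = (1.0, 3.0, 2.0)
    null_mean_probs: Sequence[float] = (0.4, 0.4, 0.2)
    integer_states: bool = False

    def __post_init__(self) -> None:
        for name in ("frac_differentiated", "dropout_at_2", "false_call_survivor_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.null_mean_probs) - 1.0) > 1e-9:
            raise ValueError("null_mean_probs must sum to 1")
        if self.cn_sd < 0 or self.boundary_jitter_sd < 0 or self.false_call_rate < 0:
            raise ValueError("noise parameters must be nonnegative")

    @property
    def genome(self) -> GenomeModel:
        return GenomeModel.from_autosomes(self.chrom_lengths)


@dataclass
class SimLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    differentiated: bool
    group_means: dict[str, float]

    @property
    def effect_gap(self) -> float:
        means = list(self.group_means.values())
        return max(means) - min(means)


@dataclass
class SimTruth:
    loci: list[SimLocus]
    individuals: list[str]
    latent_cn: np.ndarray  # (n_loci, n_individuals)
    emitted: np.ndarray  # bool, same shape

    def differentiated_loci(self) -> list[SimLocus]:
        return [l for l in self.loci if l.differentiated]

    def to_json(self, path) -> None:
        payload = {
            "individuals": self.individuals,
            "loci": [
                {
                    "locus_id": l.locus_id,
                    "chrom": l.chrom,
                    "start": l.start,
                    "end": l.end,
                    "differentiated": l.differentiated,
                    "group_means": l.group_means,
                }
                for l in self.loci
            ],
            "latent_cn": np.round(self.latent_cn, 6).tolist(),
            "emitted": self.emitted.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeModel
    metas: list[SampleMeta]
    calls: dict[str, list[CnvCall]]  # individual -> calls, sorted
    truth: SimTruth

    @property
    def individuals(self) -> list[str]:
        return [m.individual_id for m in self.metas]

    def all_calls(self) -> list[CnvCall]:
        out: list[CnvCall] = []
        for ind in self.individuals:
            out.extend(self.calls[ind])
        return out


def _make_metas(config: SimConfig) -> list[SampleMeta]:
    metas = []
    for group_name in config.n_breeds_per_group:
        group = Group(group_name)
        for b in range(1, config.n_breeds_per_group[group_name] + 1):
            breed = f"{group_name}_B{b}"
            for i in range(1, config.n_individuals_per_breed + 1):
                metas.append(
                    SampleMeta(
                        individual_id=f"{breed}_I{i:02d}", breed=breed, group=group
                    )
                )
    return metas


def _place_loci(config: SimConfig, rng: np.random.Generator) -> list[SimLocus]:
    """Place loci on the autosomes, disjoint with >= 1 kb gaps so distinct
    truth loci never reach 50% reciprocal overlap."""
    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    per_chrom = rng.multinomial(config.n_cnvr_loci, weights)
    min_gap = 1000
    loci: list[SimLocus] = []
    counter = 0
    lo_len, hi_len = config.locus_length_range
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(lo_len, hi_len + 1, size=k)
        needed = int(lengths.sum()) + (k + 1) * min_gap
        chrom_len = config.chrom_lengths[chrom]
        if needed > chrom_len:
            raise ValueError(
                f"cannot place {k} loci on chromosome {chrom}: "
                f"{needed} bp needed, {chrom_len} available"
            )
        free = chrom_len - needed
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        pos = min_gap
        prev_off = 0
        for j in range(k):
            pos += int(offsets[j]) - prev_off
            prev_off = int(offsets[j])
            start = int(pos)
            end = start + int(lengths[j])
            counter += 1
            loci.append(
                SimLocus(
                    locus_id=f"L{counter:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    differentiated=False,
                    group_means={},
                )
            )
            pos = end + min_gap
    return loci


def _assign_means(
    config: SimConfig, loci: list[SimLocus], rng: np.random.Generator
) -> None:
    groups = list(config.n_breeds_per_group)
    n_diff = int(round(config.frac_differentiated * len(loci)))
    diff_idx = set(
        rng.choice(len(loci), size=n_diff, replace=False).tolist() if n_diff else []
    )
    profile_cursor = 0
    for i, locus in enumerate(loci):
        if i in diff_idx:
            locus.differentiated = True
            if config.effect_profiles:
                profile = dict(
                    config.effect_profiles[profile_cursor % len(config.effect_profiles)]
                )
                profile_cursor += 1
                locus.group_means = {g: float(profile[g]) for g in groups}
            else:
                hi, lo = rng.choice(len(groups), size=2, replace=False)
                means = {g: 2.0 for g in groups}
                means[groups[hi]] = 2.0 + config.effect_gap
                means[groups[lo]] = max(0.0, 2.0 - config.effect_gap)
                locus.group_means = means
        else:
            base = float(
                rng.choice(np.asarray(config.null_means), p=config.null_mean_probs)
            )
            locus.group_means = {g: base for g in groups}


def simulate(config: SimConfig) -> SimResult:
    """Generate per-individual CNV calls, metadata and ground truth.

    Fully reproducible: the same config (including seed) yields identical
    calls, files and truth.
    """
    rng = np.random.default_rng(config.seed)
    metas = _make_metas(config)
    individuals = [m.individual_id for m in metas]
    group_of = np.array([m.group.value for m in metas])
    loci = _place_loci(config, rng)
    _assign_means(config, loci, rng)

    n_loci, n_ind = len(loci), len(individuals)
    latent = np.zeros((n_loci, n_ind))
    emitted = np.zeros((n_loci, n_ind), dtype=bool)
    calls: dict[str, list[CnvCall]] = {ind: [] for ind in individuals}
    jit_cap = 6.0 * config.boundary_jitter_sd

    for li, locus in enumerate(loci):
        means = np.array([locus.group_means[g] for g in group_of])
        cn = means + rng.normal(0.0, config.cn_sd, size=n_ind)
        np.clip(cn, 0.0, None, out=cn)
        if config.integer_states:
            cn = np.round(cn)
        latent[li] = cn

        near2 = np.abs(cn - 2.0) < config.call_threshold
        drop = rng.random(n_ind) < config.dropout_at_2
        emit = ~(near2 & drop)
        emitted[li] = emit

        jitter = rng.normal(0.0, config.boundary_jitter_sd, size=(n_ind, 2))
        np.clip(jitter, -jit_cap, jit_cap, out=jitter)
        pvals = 10.0 ** rng.uniform(-12.0, -4.0, size=n_ind)
        q0s = rng.uniform(0.0, 0.4, size=n_ind)
        chrom_len = config.chrom_lengths[locus.chrom]
        for j in np.nonzero(emit)[0]:
            start = int(max(0, round(locus.start + jitter[j, 0])))
            end = int(min(chrom_len, round(locus.end + jitter[j, 1])))
            if end <= start:
                end = start + 1
            calls[individuals[j]].append(
                CnvCall(
                    individual_id=individuals[j],
                    chrom=locus.chrom,
                    start=start,
                    end=end,
                    cnv_type=CnvType.DELETION if cn[j] < 2.0 else CnvType.DUPLICATION,
                    normalized_rd=float(cn[j] / 2.0),
                    pvalue=float(pvals[j]),
                    q0=float(q0s[j]),
                )
            )

    _add_false_calls(config, rng, individuals, calls)
    for ind in individuals:
        calls[ind].sort(key=lambda c: (c.chrom, c.start, c.end))

    truth = SimTruth(
        loci=loci, individuals=individuals, latent_cn=latent, emitted=emitted
    )
    return SimResult(
        config=config, genome=config.genome, metas=metas, calls=calls, truth=truth
    )


def _add_false_calls(config, rng, individuals, calls) -> None:
    """Spurious near-diploid calls. Non-survivors fail every default filter
    (short, large p-value, high q0); survivors pass them and exercise the
    recurrence filter downstream."""
    if config.false_call_rate == 0:
        return
    chroms = list(config.chrom_lengths)
    for ind in individuals:
        k = rng.poisson(config.false_call_rate)
        for _ in range(int(k)):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            survivor = rng.random() < config.false_call_survivor_frac
            if survivor:
                length = int(rng.integers(1200, 3000))
                pvalue = 10.0 ** float(rng.uniform(-8.0, -4.0))
                q0 = float(rng.uniform(0.0, 0.4))
            else:
                length = int(rng.integers(300, 900))
                pvalue = float(rng.uniform(0.01, 1.0))
                q0 = float(rng.uniform(0.5, 1.0))
            start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
            rd = float(rng.uniform(0.85, 1.15))
            calls[ind].append(
                CnvCall(
                    individual_id=ind,
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    cnv_type=CnvType.DELETION if rd < 1.0 else CnvType.DUPLICATION,
                    normalized_rd=rd,
                    pvalue=pvalue,
                    q0=q0,
                )
            )


def write_simulation(sim: SimResult, out_dir) -> dict[str, str]:
    """Write CNVnator-dialect call files, metadata, genome table and truth
    JSON under ``out_dir``; returns the paths written."""
    import os

    from . import io as cio

    os.makedirs(out_dir, exist_ok=True)
    calls_dir = os.path.join(out_dir, "calls")
    os.makedirs(calls_dir, exist_ok=True)
    paths = {}
    for ind in sim.individuals:
        p = os.path.join(calls_dir, f"{ind}.cnvnator.tsv")
        cio.write_cnvnator_calls(sim.calls[ind], p)
        paths[ind] = p
    meta_path = os.path.join(out_dir, "meta.tsv")
    cio.write_sample_meta(sim.metas, meta_path)
    genome_path = os.path.join(out_dir, "genome.tsv")
    cio.write_genome(sim.genome, genome_path)
    truth_path = os.path.join(out_dir, "truth.json")
    sim.truth.to_json(truth_path)
    return {
        "calls_dir": calls_dir,
        "meta": meta_path,
        "genome": genome_path,
        "truth": truth_path,
    }


@dataclass
class TruthEvaluation:
    precision: float
    recall: float
    n_called: int
    n_truth_differentiated: int
    n_matched_calls: int
    n_recovered_loci: int
    precision_defined: bool  # False when nothing was called (precision -> 1)
    per_locus: pd.DataFrame  # locus_id, effect_gap, recovered


def truth_eval(
    diff_table: pd.DataFrame,
    cnvrs: Sequence[Cnvr],
    truth: SimTruth,
    min_reciprocal: float = 0.5,
) -> TruthEvaluation:
    """Score the dual-criterion calls against the generator's ground truth.

    A called CNVR counts as a true positive when it has >= 50% reciprocal
    overlap with a differentiated truth locus; a truth locus is recovered
    when at least one called CNVR matches it. With an empty call set,
    precision is reported as 1.0 with ``precision_defined=False``.
    """
    called_ids = set(diff_table.loc[diff_table["differentiated"], "cnvr_id"])
    called = [r for r in cnvrs if r.cnvr_id in called_ids]
    diff_loci = truth.differentiated_loci()

    recovered = {l.locus_id: False for l in diff_loci}
    n_matched_calls = 0
    for r in called:
        hit = False
        for l in diff_loci:
            if reciprocal_overlap(r, l) >= min_reciprocal:
                recovered[l.locus_id] = True
                hit = True
        if hit:
            n_matched_calls += 1

    n_called = len(called)
    n_truth = len(diff_loci)
    recall = (
        sum(recovered.values()) / n_truth if n_truth else 1.0
    )
    precision_defined = n_called > 0
    precision = n_matched_calls / n_called if precision_defined else 1.0
    per_locus = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in diff_loci],
            "effect_gap": [l.effect_gap for l in diff_loci],
            "recovered": [recovered[l.locus_id] for l in diff_loci],
        }
    )
    return TruthEvaluation(
        precision=precision,
        recall=recall,
        n_called=n_called,
        n_truth_differentiated=n_truth,
        n_matched_calls=n_matched_calls,
        n_recovered_loci=int(sum(recovered.values())),
        precision_defined=precision_defined,
        per_locus=per_locus,
    )
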