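"""Core domain types shared across the pipeline.

All genomic intervals are 0-based half-open internally; conversion to and
from 1-based inclusive coordinates happens only at I/O boundaries
(the CNVnator call dialect is the sole 1-based format handled).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class CnvType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class Group(str, enum.Enum):
    """Regional cattle populations: Eurasian taurine, Asian indicine,
    African taurine, African humped, plus an outgroup (e.g. buffalo)."""

    EAT = "EAT"
    ASI = "ASI"
    AFT = "AFT"
    AFH = "AFH"
    OUTGROUP = "OUTGROUP"


#: The four Bos taurus groups entering the differentiation statistics.
ANALYSIS_GROUPS = (Group.EAT, Group.ASI, Group.AFT, Group.AFH)


@dataclass(frozen=True, slots=True)
class CnvCall:
    """One read-depth CNV call of one individual.

    ``normalized_rd`` is the read-depth ratio relative to the diploid
    autosomal baseline (1.0 = copy-number neutral, so copy number is
    ``2 * normalized_rd``). ``q0`` is the fraction of zero-mapping-quality
    reads in the called region (high values flag repeat-rich calls).
    """

    individual_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    normalized_rd: float
    pvalue: float
    q0: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                f"for {self.individual_id}: end must exceed start"
            )
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError(f"q0 must be in [0,1], got {self.q0}")
        if self.normalized_rd < 0:
            raise ValueError(f"normalized_rd must be >= 0, got {self.normalized_rd}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class SampleMeta:
    individual_id: str
    breed: str
    group: Group


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names, lengths and autosome flags.

    Only autosomes enter the analysis; calls on non-autosomal or unplaced
    sequences are dropped by the filtering stage.
    """

    lengths: Mapping[str, int]
    autosomes: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.autosomes - set(self.lengths)
        if unknown:
            raise ValueError(f"autosome names missing from lengths: {sorted(unknown)}")

    @classmethod
    def from_autosomes(cls, lengths: Mapping[str, int]) -> "GenomeModel":
        return cls(lengths=dict(lengths), autosomes=frozenset(lengths))

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.autosomes

    @property
    def autosome_length(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes)

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom]:
            raise ValueError(
                f"interval {chrom}:{start}-{end} exceeds chromosome "
                f"length {self.lengths[chrom]}"
            )


@dataclass(frozen=True, slots=True)
class FeatureRecord:
    """A BED-style annotation interval (gene, QTL, ...) with a category label."""

    chrom: str
    start: int
    end: int
    feature_id: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid feature interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class TypeClass(str, enum.Enum):
    """Per-individual or per-region CNV type summary."""

    DELETION = "deletion"
    DUPLICATION = "duplication"
    MIXED = "mixed"


@dataclass
class Cnvr:
    """A copy number variation region: the span of a connected set of calls.

    ``type_profile`` maps each carrier to deletion/duplication/mixed depending
    on the types of the calls that individual contributed.
    """

    cnvr_id: str
    chrom: str
    start: int
    end: int
    member_calls: list[CnvCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(c.individual_id for c in self.member_calls)

    @property
    def type_profile(self) -> dict[str, TypeClass]:
        profile: dict[str, TypeClass] = {}
        for call in self.member_calls:
            t = (
                TypeClass.DELETION
                if call.cnv_type is CnvType.DELETION
                else TypeClass.DUPLICATION
            )
            prev = profile.get(call.individual_id)
            if prev is None:
                profile[call.individual_id] = t
            elif prev is not t:
                profile[call.individual_id] = TypeClass.MIXED
        return profile

    @property
    def type_class(self) -> TypeClass:
        """Region-level summary: deletion/duplication if all member calls
        agree, mixed otherwise."""
        types = {c.cnv_type for c in self.member_calls}
        if types == {CnvType.DELETION}:
            return TypeClass.DELETION
        if types == {CnvType.DUPLICATION}:
            return TypeClass.DUPLICATION
        return TypeClass.MIXED


@dataclass
class CopyNumberMatrix:
    """CNVR x individual normalized copy numbers plus 0/1 presence.

    Copy numbers follow the read-depth convention that a diploid-neutral
    autosomal region has copy number 2.0; non-carriers are filled with 2.0.
    """

    cnvr_ids: list[str]
    individual_ids: list[str]
    cn: np.ndarray  # shape (n_cnvr, n_individuals), float
    presence: np.ndarray  # same shape, int8 in {0, 1}

    def __post_init__(self) -> None:
        n_r, n_c = len(self.cnvr_ids), len(self.individual_ids)
        if self.cn.shape != (n_r, n_c) or self.presence.shape != (n_r, n_c):
            raise ValueError("matrix shape does not match label lists")
        if len(set(self.cnvr_ids)) != n_r or len(set(self.individual_ids)) != n_c:
            raise ValueError("row/column labels must be unique")
        if np.any(self.cn < 0):
            raise ValueError("copy numbers must be nonnegative")

    def cn_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cn, index=self.cnvr_ids, columns=self.individual_ids)

    def presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=self.cnvr_ids, columns=self.individual_ids
        )

    def subset_individuals(self, ids: Iterable[str]) -> "CopyNumberMatrix":
        ids = list(ids)
        idx = [self.individual_ids.index(i) for i in ids]
        return CopyNumberMatrix(
            cnvr_ids=list(self.cnvr_ids),
            individual_ids=ids,
            cn=self.cn[:, idx].copy(),
            presence=self.presence[:, idx].copy(),
        )
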