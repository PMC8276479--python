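"""Readers and writers for every on-disk format the pipeline touches.

Internally everything is 0-based half-open. Two disk dialects exist:

* the CNVnator call table, whose ``chrom:start-end`` coordinates are 1-based
  inclusive — converted on read/write;
* BED-like tables (features, CNVRs) which are already 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    CnvCall,
    CnvType,
    CopyNumberMatrix,
    Cnvr,
    FeatureRecord,
    GenomeModel,
    Group,
    SampleMeta,
)

#: Column order of the CNVnator call dialect.
CNVNATOR_COLUMNS = (
    "CNV_type",
    "coordinates",
    "CNV_size",
    "normalized_RD",
    "e-val1",
    "e-val2",
    "e-val3",
    "e-val4",
    "q0",
)

_EVAL_INDEX = {"e-val1": 4, "e-val2": 5, "e-val3": 6, "e-val4": 7}


class ParseError(ValueError):
    """Raised for malformed input lines; carries file and line context."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _parse_region(token: str):
    """Parse ``chrom:start-end`` (1-based inclusive) into 0-based half-open."""
    try:
        chrom, span = token.rsplit(":", 1)
        lo, hi = span.split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError as exc:
        raise ValueError(f"malformed coordinate string {token!r}") from exc
    return chrom, start1 - 1, end1


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def read_cnvnator_calls(
    path,
    individual_id: str,
    *,
    eval_column: str = "e-val1",
    strip_chr_prefix: bool = False,
    genome: GenomeModel | None = None,
) -> list[CnvCall]:
    """Read one individual's CNVnator call table.

    ``eval_column`` selects which of the four e-value columns is used as the
    call's p-value (e-val1, CNVnator's primary t-test p-value, by default).
    """
    if eval_column not in _EVAL_INDEX:
        raise ValueError(f"unknown e-value column {eval_column!r}")
    col = _EVAL_INDEX[eval_column]
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            try:
                chrom, start, end = _parse_region(fields[1])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            try:
                size = int(float(fields[2]))
                rd = float(fields[3])
                pvalue = float(fields[col])
                q0 = float(fields[8])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad numeric field: {exc}") from exc
            if size < 0:
                raise ParseError(path, lineno, f"negative CNV size {size}")
            if strip_chr_prefix:
                chrom = _strip_chr(chrom)
            try:
                cnv_type = CnvType(fields[0])
            except ValueError as exc:
                raise ParseError(path, lineno, f"unknown CNV type {fields[0]!r}") from exc
            if genome is not None:
                genome.check_interval(chrom, start, end)
            # q0 of -1 marks CNVnator regions without mapped reads; clamp to 1
            # (maximally unreliable) so the filter removes them.
            q0 = 1.0 if q0 < 0 else q0
            calls.append(
                CnvCall(
                    individual_id=individual_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    normalized_rd=rd,
                    pvalue=pvalue,
                    q0=q0,
                )
            )
    return calls


def write_cnvnator_calls(calls: Iterable[CnvCall], path) -> None:
    """Write calls in the CNVnator dialect (coordinates back to 1-based
    inclusive). The selected p-value fills all four e-value columns."""
    with open(path, "w") as fh:
        for c in calls:
            region = f"{c.chrom}:{c.start + 1}-{c.end}"
            p = repr(c.pvalue)
            fh.write(
                "\t".join(
                    [
                        c.cnv_type.value,
                        region,
                        str(c.length),
                        repr(c.normalized_rd),
                        p,
                        p,
                        p,
                        p,
                        repr(c.q0),
                    ]
                )
                + "\n"
            )


def read_sample_meta(path) -> list[SampleMeta]:
    """Read the individual -> breed -> group table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "breed", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"{path}: duplicate individual_id values {dups}")
    metas = []
    for row in df.itertuples(index=False):
        try:
            group = Group(row.group)
        except ValueError as exc:
            raise ValueError(f"{path}: unknown group label {row.group!r}") from exc
        metas.append(
            SampleMeta(individual_id=row.individual_id, breed=row.breed, group=group)
        )
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tbreed\tgroup\n")
        for m in metas:
            fh.write(f"{m.individual_id}\t{m.breed}\t{m.group.value}\n")


def read_genome(path) -> GenomeModel:
    """Read a chromosome table: TSV of chrom, length, autosome flag (0/1)."""
    lengths: dict[str, int] = {}
    autosomes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected chrom<TAB>length[<TAB>flag]")
            chrom = fields[0]
            try:
                lengths[chrom] = int(fields[1])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad length {fields[1]!r}") from exc
            flag = fields[2] if len(fields) > 2 else "1"
            if flag not in {"0", "1"}:
                raise ParseError(path, lineno, f"autosome flag must be 0/1, got {flag!r}")
            if flag == "1":
                autosomes.add(chrom)
    return GenomeModel(lengths=lengths, autosomes=frozenset(autosomes))


def write_genome(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.lengths.items():
            flag = "1" if genome.is_autosome(chrom) else "0"
            fh.write(f"{chrom}\t{length}\t{flag}\n")


def read_features(
    path,
    *,
    strip_chr_prefix: bool = False,
    genome: GenomeModel | None = None,
) -> list[FeatureRecord]:
    """Read a BED-like interval table: chrom, start, end, id[, category].

    Features may overlap each other; only malformed lines are rejected.
    """
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected >= 4 columns, got {len(fields)}")
            chrom = _strip_chr(fields[0]) if strip_chr_prefix else fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from exc
            if end <= start:
                raise ParseError(path, lineno, f"empty/negative interval {start}-{end}")
            if genome is not None:
                genome.check_interval(chrom, start, end)
            category = fields[4] if len(fields) > 4 else ""
            records.append(
                FeatureRecord(
                    chrom=chrom, start=start, end=end, feature_id=fields[3], category=category
                )
            )
    return records


def write_features(features: Iterable[FeatureRecord], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t{f.category}\n")


def write_cnvr_bed(cnvrs: Sequence[Cnvr], path) -> None:
    """Write CNVRs as BED: chrom, start, end, id, carrier count, type class."""
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.cnvr_id}\t"
                f"{len(r.carriers)}\t{r.type_class.value}\n"
            )


def write_cnvr_membership(cnvrs: Sequence[Cnvr], path) -> None:
    """Write the call-level membership table of each CNVR."""
    with open(path, "w") as fh:
        fh.write(
            "cnvr_id\tindividual_id\tchrom\tstart\tend\tcnv_type\t"
            "normalized_rd\tpvalue\tq0\n"
        )
        for r in cnvrs:
            for c in r.member_calls:
                fh.write(
                    f"{r.cnvr_id}\t{c.individual_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                    f"{c.cnv_type.value}\t{c.normalized_rd!r}\t{c.pvalue!r}\t{c.q0!r}\n"
                )


def write_matrix(matrix: CopyNumberMatrix, cn_path, presence_path=None) -> None:
    """Write the copy-number (and optionally presence) matrix as TSV with
    CNVR ids as rows and individuals as columns."""
    matrix.cn_frame().to_csv(cn_path, sep="\t", index_label="cnvr_id")
    if presence_path is not None:
        matrix.presence_frame().to_csv(presence_path, sep="\t", index_label="cnvr_id")


def read_matrix(cn_path, presence_path=None) -> CopyNumberMatrix:
    cn = pd.read_csv(cn_path, sep="\t", index_col="cnvr_id")
    if presence_path is not None:
        presence = pd.read_csv(presence_path, sep="\t", index_col="cnvr_id")
        if not presence.index.equals(cn.index) or not presence.columns.equals(cn.columns):
            raise ValueError("presence matrix labels do not match copy-number matrix")
        pres = presence.to_numpy(dtype=np.int8)
    else:
        # derive presence from the 2.0 default-fill convention
        pres = (cn.to_numpy() != 2.0).astype(np.int8)
    return CopyNumberMatrix(
        cnvr_ids=[str(i) for i in cn.index],
        individual_ids=[str(c) for c in cn.columns],
        cn=cn.to_numpy(dtype=float),
        presence=pres,
    )


def write_newick(tree, path, *, support_scale: float = 100.0) -> None:
    """Write a :class:`~cnvpd.cluster.ClusterTree` as Newick with AU/BP
    support (scaled, quoted) as internal node labels."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick(support_scale=support_scale) + "\n")


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
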