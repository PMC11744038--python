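"""Fragment counting over subfamily meta-features and FPKM normalization.

Counting follows fragment-level, stranded, filtered semantics: one count per
sequenced fragment (template), MAPQ >= 20 primary non-duplicate alignments
only, reverse-stranded by default (the fragment must be antisense to the
repeat copy). All copies of one subfamily form a single meta-feature, so a
fragment touching any copy counts once toward the subfamily; a fragment
touching copies of two different subfamilies is ambiguous and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotations import ErvCopy, merged_length
from intervaltree import IntervalTree

__all__ = [
    "AlignedFragment",
    "CountingParams",
    "SampleRecord",
    "ExpressionMatrix",
    "CountResult",
    "load_fragments",
    "count_fragments",
    "count_fragments_bruteforce",
    "compute_fpkm",
    "read_sample_sheet",
    "write_sample_sheet",
]

VALID_STRANDEDNESS = ("reverse", "forward", "unstranded")


@dataclass(frozen=True)
class AlignedFragment:
    """One sequenced fragment: the template span for a proper pair, the read
    span otherwise. Strand is the strand of read 1 (or of the single read)."""

    query_name: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    is_primary: bool = True
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment {self.query_name}: end <= start")
        if self.mapq < 0:
            raise ValueError(f"fragment {self.query_name}: negative MAPQ")


@dataclass(frozen=True)
class CountingParams:
    """Filter flags for fragment counting.

    Defaults mirror stranded library preparation with fragment-level counting:
    MAPQ >= 20 as the operational "uniquely mapped" criterion, primary
    alignments only, PCR/optical duplicates ignored, reverse strandedness
    (dUTP protocol: read 1 is antisense to the transcribed strand).
    """

    min_mapq: int = 20
    primary_only: bool = True
    ignore_duplicates: bool = True
    strandedness: str = "reverse"
    ambiguous_policy: str = "drop"

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.strandedness not in VALID_STRANDEDNESS:
            raise ValueError(f"strandedness must be one of {VALID_STRANDEDNESS}")
        if self.ambiguous_policy != "drop":
            raise ValueError("only ambiguous_policy='drop' is supported")


VALID_SEVERITIES = ("none", "non_icu", "icu", "unknown")


@dataclass
class SampleRecord:
    sample_id: str
    cohort: str
    condition: str  # 'control' | 'covid'
    severity: str = "none"
    assigned_fragment_total: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("control", "covid"):
            raise ValueError(f"{self.sample_id}: condition must be control/covid")
        if self.severity not in VALID_SEVERITIES:
            raise ValueError(f"{self.sample_id}: bad severity {self.severity!r}")
        if self.severity in ("non_icu", "icu") and self.condition != "covid":
            raise ValueError(f"{self.sample_id}: ICU severity on a control sample")


@dataclass
class ExpressionMatrix:
    """Features x samples expression table.

    ``values`` is a DataFrame indexed by feature with one column per sample;
    ``value_kind`` is ``'count'`` or ``'fpkm'``; ``feature_lengths_bp`` records
    the lengths used for FPKM (provenance).
    """

    values: pd.DataFrame
    value_kind: str
    feature_lengths_bp: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in ("count", "fpkm"):
            raise ValueError("value_kind must be 'count' or 'fpkm'")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("expression values must be finite and non-negative")
        if self.value_kind == "count" and arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        if self.feature_lengths_bp is not None:
            missing = self.values.index.difference(self.feature_lengths_bp.index)
            if len(missing):
                raise ValueError(f"feature lengths missing for {list(missing)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, stream: IO[str], comments: Sequence[str] = ()) -> None:
        for c in comments:
            stream.write(f"# {c}\n")
        self.values.rename_axis("feature").to_csv(stream, sep="\t")

    @classmethod
    def from_tsv(cls, path_or_stream, value_kind: str,
                 feature_lengths_bp: pd.Series | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path_or_stream, sep="\t", comment="#", index_col=0)
        return cls(values=df, value_kind=value_kind, feature_lengths_bp=feature_lengths_bp)


def load_fragments(
    alignment: str | Path | IO[str],
    params: CountingParams = CountingParams(),
) -> list[AlignedFragment]:
    """Build one fragment per template from a SAM/BAM source.

    Records failing the filters (unmapped, secondary/supplementary when
    ``primary_only``, duplicate when ``ignore_duplicates``, MAPQ below
    ``min_mapq``) are dropped before pairing. Surviving proper mates on the
    same reference are combined into the template span with the strand of
    read 1; a read whose mate did not survive is kept as a single-read
    fragment (orphan), counted once.
    """
    mode_kwargs = {}
    af = pysam.AlignmentFile(str(alignment), "r", check_sq=False, **mode_kwargs)
    pending: dict[str, pysam.AlignedSegment] = {}
    fragments: list[AlignedFragment] = []

    def _single(rec: pysam.AlignedSegment) -> AlignedFragment:
        return AlignedFragment(
            query_name=rec.query_name,
            chrom=rec.reference_name,
            start=rec.reference_start,
            end=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
            mapq=rec.mapping_quality,
        )

    with af:
        for rec in af:
            if rec.is_unmapped:
                continue
            if params.primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            if params.ignore_duplicates and rec.is_duplicate:
                continue
            if rec.mapping_quality < params.min_mapq:
                continue
            if not rec.is_paired:
                fragments.append(_single(rec))
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            if mate.reference_name != rec.reference_name:
                # discordant survivors: count the template once via read 1
                r1 = rec if rec.is_read1 else mate
                fragments.append(_single(r1))
                continue
            r1 = rec if rec.is_read1 else mate
            start = min(rec.reference_start, mate.reference_start)
            end = max(rec.reference_end, mate.reference_end)
            fragments.append(
                AlignedFragment(
                    query_name=rec.query_name,
                    chrom=rec.reference_name,
                    start=start,
                    end=end,
                    strand="-" if r1.is_reverse else "+",
                    mapq=min(rec.mapping_quality, mate.mapping_quality),
                )
            )
    # orphans: the mate never appeared or was filtered out
    for rec in pending.values():
        fragments.append(_single(rec))
    return fragments


def _strand_compatible(fragment_strand: str, copy_strand: str, strandedness: str) -> bool:
    if strandedness == "unstranded":
        return True
    if strandedness == "reverse":
        return fragment_strand != copy_strand
    return fragment_strand == copy_strand


@dataclass
class CountResult:
    """Per-subfamily assigned fragment counts plus assignment bookkeeping.

    Conservation invariant: ``assigned_total + n_ambiguous + n_no_feature ==``
    number of input fragments.
    """

    counts: dict[str, int]
    assigned_total: int
    n_ambiguous: int
    n_no_feature: int

    def as_series(self, feature_order: Sequence[str] | None = None) -> pd.Series:
        order = list(feature_order) if feature_order is not None else sorted(self.counts)
        return pd.Series([self.counts.get(f, 0) for f in order], index=order, dtype="int64")


def count_fragments(
    fragments: Iterable[AlignedFragment],
    subfamily_copies: Mapping[str, Sequence[ErvCopy]],
    params: CountingParams = CountingParams(),
) -> CountResult:
    """Assign fragments to subfamily meta-features via an interval index.

    A fragment is assigned to a subfamily iff it overlaps >= 1 bp of >= 1
    strand-compatible copy of that subfamily. Overlapping several copies of
    the same subfamily counts once; strand-compatible overlap with two or more
    distinct subfamilies makes the fragment ambiguous and it is dropped.
    """
    trees: dict[str, IntervalTree] = {}
    for subfamily, copies in subfamily_copies.items():
        for c in copies:
            trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, (subfamily, c.strand))

    counts: dict[str, int] = {s: 0 for s in subfamily_copies}
    n_ambiguous = 0
    n_no_feature = 0
    assigned_total = 0
    for frag in fragments:
        tree = trees.get(frag.chrom)
        hits: set[str] = set()
        if tree is not None:
            for iv in tree.overlap(frag.start, frag.end):
                subfamily, copy_strand = iv.data
                if _strand_compatible(frag.strand, copy_strand, params.strandedness):
                    hits.add(subfamily)
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            assigned_total += 1
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_no_feature += 1
    return CountResult(counts, assigned_total, n_ambiguous, n_no_feature)


def count_fragments_bruteforce(
    fragments: Iterable[AlignedFragment],
    subfamily_copies: Mapping[str, Sequence[ErvCopy]],
    params: CountingParams = CountingParams(),
) -> CountResult:
    """Quadratic per-fragment x per-copy overlap scan (no interval index).

    Reference oracle for :func:`count_fragments`; identical assignment rules
    implemented without any spatial data structure.
    """
    counts: dict[str, int] = {s: 0 for s in subfamily_copies}
    n_ambiguous = 0
    n_no_feature = 0
    assigned_total = 0
    for frag in fragments:
        hits: set[str] = set()
        for subfamily, copies in subfamily_copies.items():
            for c in copies:
                if c.chrom != frag.chrom:
                    continue
                if c.start < frag.end and frag.start < c.end and _strand_compatible(
                    frag.strand, c.strand, params.strandedness
                ):
                    hits.add(subfamily)
        if len(hits) == 1:
            counts[next(iter(hits))] += 1
            assigned_total += 1
        elif len(hits) > 1:
            n_ambiguous += 1
        else:
            n_no_feature += 1
    return CountResult(counts, assigned_total, n_ambiguous, n_no_feature)


def compute_fpkm(
    counts: ExpressionMatrix | pd.DataFrame,
    feature_lengths_bp: Mapping[str, int] | pd.Series,
    assigned_totals: Mapping[str, int] | pd.Series,
) -> ExpressionMatrix:
    """Fragments per kilobase of feature per million counted fragments.

    ``fpkm[f, s] = count[f, s] * 1e9 / (length_bp[f] * assigned_total[s])``.
    Feature length is the merged (union) intergenic copy length of the
    subfamily. A sample with a zero total, or a zero-length feature with a
    nonzero count, is an error.
    """
    df = counts.values if isinstance(counts, ExpressionMatrix) else counts
    lengths = pd.Series(feature_lengths_bp).reindex(df.index)
    totals = pd.Series(assigned_totals).reindex(df.columns)
    if lengths.isna().any():
        raise ValueError("feature length missing for some features")
    if totals.isna().any() or (totals <= 0).any():
        bad = list(totals.index[totals.isna() | (totals <= 0)])
        raise ValueError(f"non-positive assigned totals for samples: {bad}")
    zero_len = lengths <= 0
    if zero_len.any() and (df.loc[zero_len].to_numpy() > 0).any():
        raise ValueError("zero-length feature with nonzero count")
    denom = np.outer(lengths.to_numpy(dtype=float), totals.to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        fpkm = df.to_numpy(dtype=float) * 1e9 / denom
    fpkm[np.asarray(zero_len), :] = 0.0
    out = pd.DataFrame(fpkm, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=out, value_kind="fpkm", feature_lengths_bp=lengths)


def feature_lengths_from_copies(subfamily_copies: Mapping[str, Sequence[ErvCopy]]) -> pd.Series:
    return pd.Series({s: merged_length(c) for s, c in subfamily_copies.items()}, dtype="int64")


def write_sample_sheet(samples: Sequence[SampleRecord], stream: IO[str]) -> None:
    stream.write("sample_id\tcohort\tcondition\tseverity\n")
    for s in samples:
        stream.write(f"{s.sample_id}\t{s.cohort}\t{s.condition}\t{s.severity}\n")


def read_sample_sheet(path_or_stream) -> list[SampleRecord]:
    df = pd.read_csv(path_or_stream, sep="\t", comment="#", dtype=str).fillna("none")
    required = {"sample_id", "cohort", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if "severity" not in df.columns:
        df["severity"] = "none"
    return [
        SampleRecord(
            sample_id=row.sample_id,
            cohort=row.cohort,
            condition=row.condition,
            severity=row.severity,
        )
        for row in df.itertuples()
    ]
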