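"""Repeat and gene annotation handling.

Parses RepeatMasker ``.out`` tables and GTF gene models, selects ERV
(endogenous retrovirus) copies by RepeatMasker class/family, restricts them to
intergenic space, and summarizes each subfamily (copy counts, merged length,
mean divergence from consensus).

All coordinates are 0-based half-open internally; the 1-based conventions of
the input formats are converted at parse time and restored only when writing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "ErvCopy",
    "GeneFeature",
    "SubfamilySummary",
    "AnnotationParseError",
    "DEFAULT_ERV_CLASS_PREFIXES",
    "parse_repeatmasker_out",
    "parse_gtf_features",
    "select_erv_copies",
    "filter_intergenic",
    "merge_intervals",
    "summarize_subfamilies",
    "group_by_subfamily",
    "write_bed",
    "read_bed",
    "write_subfamily_summary_tsv",
]


class AnnotationParseError(ValueError):
    """Raised when an annotation line cannot be parsed; names the line number."""


@dataclass(frozen=True)
class ErvCopy:
    """One RepeatMasker repeat instance.

    ``divergence_pct`` is the percent substitution from the subfamily
    consensus ("div." column); lower values mark evolutionarily younger
    insertions.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'
    subfamily: str
    class_family: str
    divergence_pct: float
    copy_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"copy {self.copy_id}: end {self.end} <= start {self.start}")
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"copy {self.copy_id}: divergence {self.divergence_pct} outside [0, 100]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"copy {self.copy_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    gene_id: str
    feature_type: str  # 'gene' or 'exon'

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene feature {self.gene_id}: end <= start")


@dataclass(frozen=True)
class SubfamilySummary:
    """Per-subfamily rollup over its genomic copies.

    ``mean_divergence_pct`` is the unweighted mean over intergenic copies and
    is NaN (with ``usable_for_expression`` False) when no copy survives the
    intergenic filter.
    """

    subfamily: str
    n_copies_total: int
    n_copies_intergenic: int
    merged_length_bp: int
    mean_divergence_pct: float

    @property
    def usable_for_expression(self) -> bool:
        return self.n_copies_intergenic > 0


# RepeatMasker class/family selectors for the ERV roster. The exact subfamily
# count is RepeatMasker-version-dependent, so membership is pattern-based and
# configurable rather than a hard-coded list.
DEFAULT_ERV_CLASS_PREFIXES: tuple[str, ...] = (
    "LTR/ERV1",
    "LTR/ERVK",
    "LTR/ERVL",
    "LTR/ERVL-MaLR",
    "LTR/ERV",
)

_RMSK_HEADER_LINES = 3


def _as_lines(stream: IO[str] | str | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(stream.splitlines())
    return iter(stream)


def parse_repeatmasker_out(stream: IO[str] | str | Iterable[str]) -> list[ErvCopy]:
    """Parse a RepeatMasker ``.out`` table into repeat records.

    The dialect has 3 header lines followed by whitespace-delimited columns
    (score, div, del, ins, query, qbegin, qend, qleft, strand, repeat,
    class/family, rbegin, rend, rleft, id). ``qbegin`` is 1-based inclusive and
    becomes ``start = qbegin - 1``; a strand of ``C`` (complement) maps to
    ``-``. An optional trailing ``*`` (higher-scoring overlap mark) is
    tolerated. A file with only its headers yields an empty list.
    """
    records: list[ErvCopy] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        if lineno <= _RMSK_HEADER_LINES:
            continue
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) == 16 and fields[15] == "*":
            fields = fields[:15]
        if len(fields) != 15:
            raise AnnotationParseError(
                f"line {lineno}: expected 15 RepeatMasker columns, got {len(fields)}"
            )
        try:
            div = float(fields[1])
            qbegin = int(fields[5])
            qend = int(fields[6])
        except ValueError as exc:
            raise AnnotationParseError(f"line {lineno}: non-numeric field ({exc})") from None
        strand_field = fields[8]
        if strand_field == "C":
            strand = "-"
        elif strand_field == "+":
            strand = "+"
        else:
            raise AnnotationParseError(f"line {lineno}: bad strand column {strand_field!r}")
        records.append(
            ErvCopy(
                chrom=fields[4],
                start=qbegin - 1,
                end=qend,
                strand=strand,
                subfamily=fields[9],
                class_family=fields[10],
                divergence_pct=div,
                copy_id=f"rm{lineno - _RMSK_HEADER_LINES:06d}",
            )
        )
    return records


def parse_gtf_features(stream: IO[str] | str | Iterable[str]) -> list[GeneFeature]:
    """Parse ``gene`` and ``exon`` rows from a GTF stream.

    GTF is 1-based inclusive; coordinates are converted to 0-based half-open.
    Other feature types are ignored. A retained row without a ``gene_id``
    attribute is a parse error.
    """
    features: list[GeneFeature] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationParseError(f"line {lineno}: expected 9 GTF columns, got {len(fields)}")
        feature_type = fields[2]
        if feature_type not in ("gene", "exon"):
            continue
        try:
            start = int(fields[3]) - 1
            end = int(fields[4])
        except ValueError:
            raise AnnotationParseError(f"line {lineno}: non-numeric coordinates") from None
        gene_id = _gtf_attribute(fields[8], "gene_id")
        if gene_id is None:
            raise AnnotationParseError(f"line {lineno}: missing gene_id attribute")
        features.append(
            GeneFeature(
                chrom=fields[0],
                start=start,
                end=end,
                strand=fields[6],
                gene_id=gene_id,
                feature_type=feature_type,
            )
        )
    return features


def _gtf_attribute(attributes: str, key: str) -> str | None:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " ") or chunk.startswith(key + "="):
            value = chunk[len(key):].strip(" =")
            return value.strip('"')
    return None


def select_erv_copies(
    records: Sequence[ErvCopy],
    erv_class_prefixes: Sequence[str] = DEFAULT_ERV_CLASS_PREFIXES,
) -> list[ErvCopy]:
    """Keep repeats whose class/family matches an ERV pattern, order preserved.

    A record matches if its class/family equals a pattern or starts with a
    pattern (so ``LTR/ERV`` pulls in every ``LTR/ERV*`` family).
    """
    prefixes = tuple(erv_class_prefixes)
    return [
        rec
        for rec in records
        if any(rec.class_family == p or rec.class_family.startswith(p) for p in prefixes)
    ]


def _gene_trees(genes: Iterable[GeneFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.feature_type != "gene":
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    return trees


def filter_intergenic(copies: Sequence[ErvCopy], genes: Iterable[GeneFeature]) -> list[ErvCopy]:
    """Drop any copy overlapping a gene-body interval by >= 1 bp (strand-blind).

    Restricting to intergenic copies attributes the counted transcription to
    the repeat itself rather than a host gene. Copies on chromosomes absent
    from the gene annotation are retained.
    """
    trees = _gene_trees(genes)
    out: list[ErvCopy] = []
    for c in copies:
        tree = trees.get(c.chrom)
        if tree is not None and tree.overlaps(c.start, c.end):
            continue
        out.append(c)
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended half-open intervals; returns sorted list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def group_by_subfamily(copies: Iterable[ErvCopy]) -> dict[str, list[ErvCopy]]:
    groups: dict[str, list[ErvCopy]] = {}
    for c in copies:
        groups.setdefault(c.subfamily, []).append(c)
    return groups


def merged_length(copies: Iterable[ErvCopy]) -> int:
    """Total genomic bases covered by the copies (per-chromosome interval union)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    return sum(
        e - s for ivs in by_chrom.values() for s, e in merge_intervals(ivs)
    )


def summarize_subfamilies(
    intergenic_copies: Sequence[ErvCopy],
    all_copies: Sequence[ErvCopy],
    weighted_divergence: bool = False,
) -> list[SubfamilySummary]:
    """Summarize each subfamily seen in ``all_copies``.

    Merged length and divergence are computed over the intergenic copies (the
    copies that will actually be quantified). ``weighted_divergence`` switches
    the unweighted copy mean to a copy-length-weighted mean. A subfamily with
    zero intergenic copies gets NaN divergence and is flagged unusable.
    """
    inter = group_by_subfamily(intergenic_copies)
    total = group_by_subfamily(all_copies)
    summaries: list[SubfamilySummary] = []
    for subfamily in sorted(total):
        copies = inter.get(subfamily, [])
        if copies:
            if weighted_divergence:
                w = sum(c.length for c in copies)
                mean_div = sum(c.divergence_pct * c.length for c in copies) / w
            else:
                mean_div = sum(c.divergence_pct for c in copies) / len(copies)
        else:
            mean_div = math.nan
        summaries.append(
            SubfamilySummary(
                subfamily=subfamily,
                n_copies_total=len(total[subfamily]),
                n_copies_intergenic=len(copies),
                merged_length_bp=merged_length(copies),
                mean_divergence_pct=mean_div,
            )
        )
    return summaries


def exon_union_features(
    genes: Iterable[GeneFeature],
    gene_ids: Iterable[str] | None = None,
) -> dict[str, list[ErvCopy]]:
    """Exon-union meta-features per gene, in the copy representation.

    Each gene becomes one meta-feature whose parts are its merged exon
    intervals, so genes (e.g. an innate-immune panel supplied as a plain
    gene-ID list) are counted with exactly the same fragment-assignment
    machinery as ERV subfamilies. Genes without exon rows fall back to the
    gene body. ``gene_ids`` restricts the output to a panel.
    """
    wanted = set(gene_ids) if gene_ids is not None else None
    exons: dict[str, list[GeneFeature]] = {}
    bodies: dict[str, list[GeneFeature]] = {}
    for g in genes:
        if wanted is not None and g.gene_id not in wanted:
            continue
        (exons if g.feature_type == "exon" else bodies).setdefault(g.gene_id, []).append(g)
    features: dict[str, list[ErvCopy]] = {}
    for gene_id in sorted(set(exons) | set(bodies)):
        parts = exons.get(gene_id) or bodies[gene_id]
        by_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for part in parts:
            by_chrom.setdefault((part.chrom, part.strand), []).append((part.start, part.end))
        copies = [
            ErvCopy(chrom=chrom, start=s, end=e, strand=strand, subfamily=gene_id,
                    class_family="gene", divergence_pct=0.0,
                    copy_id=f"{gene_id}:{s}-{e}")
            for (chrom, strand), ivs in sorted(by_chrom.items())
            for s, e in merge_intervals(ivs)
        ]
        features[gene_id] = copies
    if wanted is not None:
        missing = wanted - set(features)
        if missing:
            raise ValueError(f"gene ids absent from annotation: {sorted(missing)[:5]}")
    return features


def read_gene_id_list(stream: IO[str] | str | Iterable[str]) -> list[str]:
    """Plain-text gene-ID list (one per line, '#' comments); order kept, deduplicated."""
    seen: dict[str, None] = {}
    for raw in _as_lines(stream):
        line = raw.strip()
        if line and not line.startswith("#"):
            seen.setdefault(line)
    return list(seen)


def write_bed(copies: Iterable[ErvCopy], stream: IO[str]) -> None:
    """Write copies as BED6; name carries ``subfamily|copy_id|divergence``."""
    for c in copies:
        name = f"{c.subfamily}|{c.copy_id}|{c.divergence_pct:g}"
        stream.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t0\t{c.strand}\n")


def read_bed(stream: IO[str] | str | Iterable[str], class_family: str = "LTR/ERV1") -> list[ErvCopy]:
    """Re-read a BED6 written by :func:`write_bed`."""
    copies: list[ErvCopy] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise AnnotationParseError(f"line {lineno}: expected 6 BED columns")
        subfamily, copy_id, div = fields[3].split("|")
        copies.append(
            ErvCopy(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                strand=fields[5],
                subfamily=subfamily,
                class_family=class_family,
                divergence_pct=float(div),
                copy_id=copy_id,
            )
        )
    return copies


def write_subfamily_summary_tsv(summaries: Iterable[SubfamilySummary], stream: IO[str]) -> None:
    stream.write("subfamily\tn_copies_total\tn_copies_intergenic\tmerged_length_bp\tmean_divergence_pct\n")
    for s in summaries:
        div = "nan" if math.isnan(s.mean_divergence_pct) else f"{s.mean_divergence_pct:.6g}"
        stream.write(
            f"{s.subfamily}\t{s.n_copies_total}\t{s.n_copies_intergenic}\t{s.merged_length_bp}\t{div}\n"
        )


def read_subfamily_summary_tsv(stream: IO[str] | str | Iterable[str]) -> list[SubfamilySummary]:
    lines = list(_as_lines(stream))
    out: list[SubfamilySummary] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        sub, n_tot, n_int, mlen, mdiv = line.rstrip("\n").split("\t")
        out.append(
            SubfamilySummary(
                subfamily=sub,
                n_copies_total=int(n_tot),
                n_copies_intergenic=int(n_int),
                merged_length_bp=int(mlen),
                mean_divergence_pct=float(mdiv),
            )
        )
    return out
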