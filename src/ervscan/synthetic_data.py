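"""Synthetic annotation, count, and read-level data with planted truth.

Emulates the structure of the study cohorts this pipeline targets: an
age-structured repeat annotation (young subfamilies at low divergence from
consensus, old at high), gene models to exercise the intergenic filter,
negative-binomial subfamily counts with log-normal library size factors and
unequal group sizes, and condition-specific upregulation planted in a chosen
age tier. Every output is a pure function of (config, seed): the same config
yields byte-identical files.

Three entry points, usable independently:

* :func:`simulate_annotation` — RepeatMasker ``.out`` + GTF text plus truth;
* :func:`simulate_counts` — subfamily x sample count matrix + sample sheet;
* :func:`simulate_reads` — per-sample SAM text realizing a target count
  matrix, with optional spike-ins (low MAPQ, duplicates, wrong strand,
  cross-subfamily straddlers) whose expected fate is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations import ErvCopy, GeneFeature, group_by_subfamily

__all__ = [
    "SimulationConfig",
    "SpikeInConfig",
    "SimulationTruth",
    "AnnotationSet",
    "CountSimulation",
    "ReadSimulation",
    "simulate_truth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_reads",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the generator.

    Group sizes default to the platelet-like cohort (10 patients vs 5
    controls); the subfamily roster defaults to 578, the size of the analyzed
    ERV roster. Divergence tiers: young copies at 0.5-8% substitution from
    consensus, old at 8-30%. Counts are negative-binomial with variance
    ``mu + dispersion * mu^2`` and log-normal per-sample size factors.
    """

    seed: int = 0
    # genome geometry
    n_chromosomes: int = 4
    chromosome_length_bp: int = 5_000_000
    n_genes: int = 40
    gene_length_bp: tuple[int, int] = (2_000, 10_000)
    # repeat annotation
    n_subfamilies: int = 578
    copies_per_subfamily: tuple[int, int] = (3, 8)
    copy_length_bp: tuple[int, int] = (400, 1_500)
    genic_overlap_fraction: float = 0.0
    young_fraction: float = 0.5
    young_divergence_range: tuple[float, float] = (0.5, 8.0)
    old_divergence_range: tuple[float, float] = (8.0, 30.0)
    # cohort design
    cohort: str = "platelet"
    n_control: int = 5
    n_case: int = 10
    n_non_icu: int | None = None
    n_icu: int | None = None
    # count model
    baseline_mean_range: tuple[float, float] = (5.0, 200.0)
    dispersion: float = 0.1
    size_factor_sigma: float = 0.15
    # planted effect
    n_planted: int = 10
    planted_fold_change: float = 8.0
    planted_age_tier: str = "young"  # young | old | mixed
    # read geometry
    read_length: int = 100
    insert_mean: int = 250
    insert_sd: int = 30

    def __post_init__(self) -> None:
        if self.planted_fold_change < 1.0:
            raise ValueError("planted fold_change must be >= 1 (1 = null)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.planted_age_tier not in ("young", "old", "mixed"):
            raise ValueError("planted_age_tier must be young/old/mixed")
        lo, hi = self.young_divergence_range
        lo2, hi2 = self.old_divergence_range
        if not (0 <= lo < hi <= lo2 < hi2 <= 100):
            raise ValueError("divergence tiers must be ordered and non-overlapping")
        if self.n_control < 1 or self.n_case < 1 or self.n_subfamilies < 1:
            raise ValueError("counts must be >= 1")
        if (self.n_non_icu is None) != (self.n_icu is None):
            raise ValueError("give both n_non_icu and n_icu or neither")
        if self.n_non_icu is not None and self.n_non_icu + self.n_icu > self.n_case:
            raise ValueError("severity split exceeds n_case")


@dataclass(frozen=True)
class SpikeInConfig:
    """Deliberately defective fragments to exercise the counting filters."""

    n_low_mapq: int = 0
    n_duplicate: int = 0
    n_wrong_strand: int = 0
    n_cross_subfamily: int = 0
    low_mapq: int = 5


@dataclass
class SimulationTruth:
    """Planted ground truth.

    ``subfamilies``: one row per subfamily with age tier, divergence, planted
    flag, and true fold change. ``samples``: sample_id, cohort, condition,
    severity.
    """

    subfamilies: pd.DataFrame
    samples: pd.DataFrame

    @property
    def planted(self) -> list[str]:
        mask = self.subfamilies["planted"]
        return list(self.subfamilies.index[mask])


@dataclass
class AnnotationSet:
    rmsk_text: str
    gtf_text: str
    truth: SimulationTruth
    copies: list[ErvCopy]
    genes: list[GeneFeature]
    chrom_lengths: dict[str, int]


@dataclass
class CountSimulation:
    counts: pd.DataFrame  # subfamilies x samples, int
    sample_sheet: pd.DataFrame
    baseline_means: pd.Series
    size_factors: pd.Series


@dataclass
class ReadSimulation:
    sam_texts: dict[str, str]  # sample_id -> SAM
    spikein_truth: pd.DataFrame  # query_name, sample_id, kind, expected


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw the subfamily table (tiers, divergences, planted set) and samples."""
    rng = _rng(config, 1)
    n = config.n_subfamilies
    names = [f"SIM-LTR{i + 1}" for i in range(n)]
    n_young = int(round(config.young_fraction * n))
    tiers = np.array(["young"] * n_young + ["old"] * (n - n_young), dtype=object)
    rng.shuffle(tiers)
    div = np.where(
        tiers == "young",
        rng.uniform(*config.young_divergence_range, size=n),
        rng.uniform(*config.old_divergence_range, size=n),
    )
    planted = np.zeros(n, dtype=bool)
    if config.n_planted > 0:
        if config.planted_age_tier == "mixed":
            pool = np.arange(n)
        else:
            pool = np.flatnonzero(tiers == config.planted_age_tier)
        if pool.size < config.n_planted:
            raise ValueError(
                f"cannot plant {config.n_planted} subfamilies in tier "
                f"{config.planted_age_tier!r} of size {pool.size}"
            )
        planted[rng.choice(pool, size=config.n_planted, replace=False)] = True
    subfamilies = pd.DataFrame(
        {
            "age_tier": tiers,
            "divergence_pct": div,
            "planted": planted,
            "true_fold_change": np.where(planted, config.planted_fold_change, 1.0),
        },
        index=pd.Index(names, name="subfamily"),
    )

    rows = []
    for i in range(config.n_control):
        rows.append((f"ctrl{i + 1:02d}", config.cohort, "control", "none"))
    for i in range(config.n_case):
        if config.n_non_icu is not None:
            if i < config.n_non_icu:
                sev = "non_icu"
            elif i < config.n_non_icu + config.n_icu:
                sev = "icu"
            else:
                sev = "unknown"
        else:
            sev = "unknown"
        rows.append((f"case{i + 1:02d}", config.cohort, "covid", sev))
    samples = pd.DataFrame(rows, columns=["sample_id", "cohort", "condition", "severity"])
    return SimulationTruth(subfamilies=subfamilies, samples=samples)


def _place_interval(
    rng: np.random.Generator,
    length: int,
    chrom_names: Sequence[str],
    chrom_len: int,
    occupied: dict[str, IntervalTree],
    gene_trees: dict[str, IntervalTree],
    want_genic: bool,
    genes: Sequence[GeneFeature] = (),
    max_tries: int = 200,
) -> tuple[str, int]:
    gene_bodies = [g for g in genes if g.feature_type == "gene"]
    for _ in range(max_tries):
        if want_genic:
            if not gene_bodies:
                raise ValueError("genic placement requested but no genes exist")
            # anchor on a random gene so the overlap is guaranteed
            g = gene_bodies[int(rng.integers(len(gene_bodies)))]
            lo = max(0, g.start - length + 1)
            hi = min(chrom_len - length, g.end - 1)
            if hi < lo:
                continue
            chrom = g.chrom
            start = int(rng.integers(lo, hi + 1))
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if occupied[chrom].overlaps(start, end):
            continue
        if not want_genic and gene_trees[chrom].overlaps(start, end):
            continue
        return chrom, start
    raise ValueError("requested copies exceed placeable space (placement failed)")


def simulate_annotation(config: SimulationConfig) -> AnnotationSet:
    """Generate a RepeatMasker ``.out`` table and a gene GTF with known truth.

    Copies are placed uniformly at random, never overlapping one another; a
    ``genic_overlap_fraction`` of them is forced to overlap a gene body so the
    intergenic filter has work to do. Per-copy divergence scatters around the
    subfamily value (sd 0.5) clipped to the subfamily's tier range.
    """
    truth = simulate_truth(config)
    rng = _rng(config, 2)
    chrom_names = [f"chrSim{i + 1}" for i in range(config.n_chromosomes)]
    chrom_len = config.chromosome_length_bp
    chrom_lengths = {c: chrom_len for c in chrom_names}

    gene_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_names}
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_names}
    genes: list[GeneFeature] = []
    empty = {c: IntervalTree() for c in chrom_names}
    for gi in range(config.n_genes):
        glen = int(rng.integers(config.gene_length_bp[0], config.gene_length_bp[1] + 1))
        chrom, start = _place_interval(
            rng, glen, chrom_names, chrom_len, gene_trees, empty, want_genic=False
        )
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gi + 1:04d}"
        genes.append(GeneFeature(chrom, start, start + glen, strand, gid, "gene"))
        genes.append(GeneFeature(chrom, start, start + glen, strand, gid, "exon"))
        gene_trees[chrom].addi(start, start + glen)

    tier_ranges = {
        "young": config.young_divergence_range,
        "old": config.old_divergence_range,
    }
    copies: list[ErvCopy] = []
    copy_no = 0
    for subfamily, row in truth.subfamilies.iterrows():
        n_copies = int(
            rng.integers(config.copies_per_subfamily[0], config.copies_per_subfamily[1] + 1)
        )
        lo, hi = tier_ranges[row["age_tier"]]
        for _ in range(n_copies):
            length = int(rng.integers(config.copy_length_bp[0], config.copy_length_bp[1] + 1))
            want_genic = bool(rng.random() < config.genic_overlap_fraction)
            chrom, start = _place_interval(
                rng, length, chrom_names, chrom_len, occupied, gene_trees, want_genic,
                genes=genes,
            )
            occupied[chrom].addi(start, start + length)
            div = float(np.clip(rng.normal(row["divergence_pct"], 0.5), lo, hi))
            copy_no += 1
            copies.append(
                ErvCopy(
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    subfamily=str(subfamily),
                    class_family="LTR/ERV1",
                    divergence_pct=round(div, 1),
                    copy_id=f"rm{copy_no:06d}",
                )
            )

    return AnnotationSet(
        rmsk_text=_format_rmsk(copies),
        gtf_text=_format_gtf(genes),
        truth=truth,
        copies=copies,
        genes=genes,
        chrom_lengths=chrom_lengths,
    )


def _format_rmsk(copies: Sequence[ErvCopy]) -> str:
    lines = [
        "   SW   perc perc perc  query     position in query            matching repeat         position in repeat",
        "score   div. del. ins.  sequence  begin  end        (left)    repeat  class/family   begin  end    (left)  ID",
        "",
    ]
    for i, c in enumerate(sorted(copies, key=lambda c: (c.chrom, c.start)), start=1):
        strand = "+" if c.strand == "+" else "C"
        left = 0
        lines.append(
            f"{1000:>5} {c.divergence_pct:>5.1f}  0.0  0.0  {c.chrom}  {c.start + 1}  {c.end}  "
            f"({left})  {strand}  {c.subfamily}  {c.class_family}  1  {c.length}  (0)  {i}"
        )
    return "\n".join(lines) + "\n"


def _format_gtf(genes: Sequence[GeneFeature]) -> str:
    lines = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.feature_type != "gene")):
        attrs = f'gene_id "{g.gene_id}";'
        lines.append(
            f"{g.chrom}\tsim\t{g.feature_type}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"


def simulate_counts(config: SimulationConfig, truth: SimulationTruth) -> CountSimulation:
    """Negative-binomial subfamily counts with planted case-specific effects.

    ``count[f, s] ~ NB(mean = baseline_f * FC_f(condition_s) * sf_s,
    dispersion)`` with ``Var = mu + dispersion * mu^2`` and log-normal size
    factors centred on 1.
    """
    rng = _rng(config, 3)
    subs = truth.subfamilies
    n_f = len(subs)
    samples = truth.samples
    baselines = pd.Series(
        rng.uniform(*config.baseline_mean_range, size=n_f), index=subs.index, name="baseline_mean"
    )
    sf = pd.Series(
        np.exp(rng.normal(0.0, config.size_factor_sigma, size=len(samples))),
        index=samples["sample_id"].to_numpy(),
        name="size_factor",
    )
    fc = subs["true_fold_change"].to_numpy()
    is_case = (samples["condition"] == "covid").to_numpy()
    mu = (
        baselines.to_numpy()[:, None]
        * np.where(is_case[None, :], fc[:, None], 1.0)
        * sf.to_numpy()[None, :]
    )
    r = 1.0 / config.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=subs.index, columns=samples["sample_id"].to_numpy())
    return CountSimulation(
        counts=df, sample_sheet=samples.copy(), baseline_means=baselines, size_factors=sf
    )


def _sam_header(chrom_lengths: Mapping[str, int]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    return lines


def _pair_records(
    qname: str,
    chrom: str,
    frag_start: int,
    frag_end: int,
    frag_strand: str,
    read_length: int,
    mapq: int,
    duplicate: bool = False,
) -> list[tuple[int, str]]:
    """Two properly-paired SAM records for a fragment; read 1 on frag_strand.

    Returns (position, line) tuples for coordinate sorting.
    """
    flen = frag_end - frag_start
    rl = min(read_length, flen)
    seq = "A" * rl
    cigar = f"{rl}M"
    dup = 1024 if duplicate else 0
    left = frag_start + 1  # SAM is 1-based
    right = frag_end - rl + 1
    if frag_strand == "+":
        f1, p1, f2, p2 = 99 | dup, left, 147 | dup, right
        tl1, tl2 = flen, -flen
    else:
        f1, p1, f2, p2 = 83 | dup, right, 163 | dup, left
        tl1, tl2 = -flen, flen
    rec1 = f"{qname}\t{f1}\t{chrom}\t{p1}\t{mapq}\t{cigar}\t=\t{p2}\t{tl1}\t{seq}\t*"
    rec2 = f"{qname}\t{f2}\t{chrom}\t{p2}\t{mapq}\t{cigar}\t=\t{p1}\t{tl2}\t{seq}\t*"
    return [(p1, rec1), (p2, rec2)]


def _antisense(strand: str) -> str:
    return "-" if strand == "+" else "+"


def simulate_reads(
    annotation: AnnotationSet,
    target_counts: pd.DataFrame,
    config: SimulationConfig,
    spike_ins: SpikeInConfig = SpikeInConfig(),
) -> ReadSimulation:
    """Realize a target count matrix as per-sample paired-end SAM text.

    Every targeted fragment lies wholly inside one intergenic copy of its
    subfamily, antisense to the copy strand, so reverse-stranded counting
    assigns it. Spike-ins add fragments the filters must reject (low MAPQ,
    duplicate flag, sense strand) or drop as ambiguous (straddling copies of
    two subfamilies); each is recorded with its expected outcome. Without
    spike-ins, counting the output reproduces ``target_counts`` exactly.
    """
    rng = _rng(config, 4)
    min_flen = 2 * config.read_length
    from .annotations import filter_intergenic

    intergenic = filter_intergenic(annotation.copies, annotation.genes)
    by_sub = group_by_subfamily(intergenic)
    usable: dict[str, list[ErvCopy]] = {}
    for sub, copies in by_sub.items():
        ok = [c for c in copies if c.length >= min_flen]
        if ok:
            usable[sub] = ok

    sam_texts: dict[str, str] = {}
    spike_rows: list[dict] = []
    for sample in target_counts.columns:
        records: list[tuple[str, int, str]] = []  # (chrom, pos, line)
        frag_no = 0

        def draw_fragment(copy: ErvCopy) -> tuple[int, int]:
            flen = int(np.clip(rng.normal(config.insert_mean, config.insert_sd),
                               min_flen, copy.length))
            start = int(rng.integers(copy.start, copy.end - flen + 1))
            return start, start + flen

        for sub in target_counts.index:
            n = int(target_counts.loc[sub, sample])
            if n == 0:
                continue
            copies = usable.get(sub)
            if not copies:
                raise ValueError(
                    f"subfamily {sub} has no intergenic copy >= {min_flen} bp "
                    f"to place {n} fragments"
                )
            for _ in range(n):
                copy = copies[int(rng.integers(len(copies)))]
                fs, fe = draw_fragment(copy)
                frag_no += 1
                qname = f"{sample}_frag{frag_no:06d}"
                for pos, line in _pair_records(
                    qname, copy.chrom, fs, fe, _antisense(copy.strand),
                    config.read_length, mapq=60,
                ):
                    records.append((copy.chrom, pos, line))

        # spike-ins: place in any usable copy; expected outcomes recorded
        all_usable = [c for copies in usable.values() for c in copies]

        def add_spike(kind: str, n: int) -> None:
            nonlocal frag_no
            for _ in range(n):
                copy = all_usable[int(rng.integers(len(all_usable)))]
                fs, fe = draw_fragment(copy)
                frag_no += 1
                qname = f"{sample}_spike{frag_no:06d}"
                mapq, dup = 60, False
                strand = _antisense(copy.strand)
                if kind == "low_mapq":
                    mapq, expected = spike_ins.low_mapq, "filtered_mapq"
                elif kind == "duplicate":
                    dup, expected = True, "filtered_duplicate"
                elif kind == "wrong_strand":
                    strand, expected = copy.strand, "unassigned_strand"
                else:
                    raise AssertionError(kind)
                for pos, line in _pair_records(
                    qname, copy.chrom, fs, fe, strand, config.read_length, mapq, dup
                ):
                    records.append((copy.chrom, pos, line))
                spike_rows.append(
                    {"query_name": qname, "sample_id": sample, "kind": kind,
                     "expected": expected}
                )

        add_spike("low_mapq", spike_ins.n_low_mapq)
        add_spike("duplicate", spike_ins.n_duplicate)
        add_spike("wrong_strand", spike_ins.n_wrong_strand)

        if spike_ins.n_cross_subfamily > 0:
            pairs = _adjacent_cross_subfamily_pairs(all_usable)
            if not pairs:
                raise ValueError("no same-strand adjacent copy pair for cross-subfamily spike-in")
            for _ in range(spike_ins.n_cross_subfamily):
                c1, c2 = pairs[int(rng.integers(len(pairs)))]
                fs = c1.end - config.read_length
                fe = c2.start + config.read_length
                frag_no += 1
                qname = f"{sample}_spike{frag_no:06d}"
                for pos, line in _pair_records(
                    qname, c1.chrom, fs, fe, _antisense(c1.strand), config.read_length, 60
                ):
                    records.append((c1.chrom, pos, line))
                spike_rows.append(
                    {"query_name": qname, "sample_id": sample,
                     "kind": "cross_subfamily", "expected": "ambiguous"}
                )

        records.sort(key=lambda r: (r[0], r[1]))
        body = [line for _, _, line in records]
        sam_texts[sample] = "\n".join(_sam_header(annotation.chrom_lengths) + body) + "\n"

    spike_df = pd.DataFrame(
        spike_rows, columns=["query_name", "sample_id", "kind", "expected"]
    )
    return ReadSimulation(sam_texts=sam_texts, spikein_truth=spike_df)


def _adjacent_cross_subfamily_pairs(
    copies: Sequence[ErvCopy], max_gap: int = 5_000
) -> list[tuple[ErvCopy, ErvCopy]]:
    """Same-chromosome, same-strand copy pairs of different subfamilies whose
    gap a template span can straddle (fragment antisense to both)."""
    pairs: list[tuple[ErvCopy, ErvCopy]] = []
    by_chrom: dict[str, list[ErvCopy]] = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_copies in by_chrom.values():
        chrom_copies.sort(key=lambda c: c.start)
        for c1, c2 in zip(chrom_copies, chrom_copies[1:]):
            if (
                c1.subfamily != c2.subfamily
                and c1.strand == c2.strand
                and 0 <= c2.start - c1.end <= max_gap
            ):
                pairs.append((c1, c2))
    return pairs
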