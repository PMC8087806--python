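"""Editing quantification: base counts, site calling, per-read isoform tally.

The quantification follows the amplicon logic end to end:

1. anchored ungapped alignment of each full-length read against the amplicon
   (reads are one fixed target; no genome-scale alignment is involved);
2. a per-position nucleotide tally ("base count");
3. the editing percentage at a position, G / (G + A) × 100 — C/T/N reads are
   excluded from both numerator and denominator;
4. site calling: candidate A positions whose G-percentage is strictly above a
   detection threshold (default 0.1 %);
5. per-read co-editing patterns ("isoforms"): each read is classified by the
   set of called sites at which it carries G; the relative proportion of a
   pattern is its share of classified reads, and a site's level is the sum of
   proportions over all patterns containing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceAmplicon
from .simulate import ReadBatch, isoform_name

__all__ = [
    "SiteCallingConfig",
    "SiteCall",
    "BaseCountTable",
    "IsoformProfile",
    "AlignedReads",
    "read_fastq",
    "align_reads",
    "count_bases",
    "editing_percentage",
    "call_sites",
    "enumerate_isoforms",
    "site_level_from_isoforms",
    "aggregate_replicates",
    "quantify_sample",
    "analysis_site_set",
]


@dataclass(frozen=True)
class SiteCallingConfig:
    """Thresholds, in percent of reads.

    detection_threshold: a candidate A position is called a site when its
        G-percentage is strictly above this (default 0.1).
    isoform_threshold: patterns below this relative proportion are flagged
        below-threshold (kept in the table, excluded from headline analysis).
    exclusion_note_level: reporting-only level used to annotate positions
        whose signal is indistinguishable from background (default 0.05).
    max_mismatch: alignment acceptance cap on mismatches outside candidate
        positions.
    """

    detection_threshold: float = 0.1
    isoform_threshold: float = 0.1
    exclusion_note_level: float = 0.05
    max_mismatch: int = 5

    def __post_init__(self) -> None:
        for v in (self.detection_threshold, self.isoform_threshold, self.exclusion_note_level):
            if not 0 < v < 100:
                raise ValueError("thresholds must be in (0, 100)")


@dataclass(frozen=True)
class SiteCall:
    label: str
    offset: int
    percentage: float | None  # None when A+G = 0 at the position
    passed: bool


@dataclass
class BaseCountTable:
    """Per-position nucleotide counts over aligned reads."""

    counts: pd.DataFrame  # columns A, C, G, T, other; one row per offset
    total_reads: int

    def g_percentage(self, offset: int) -> float | None:
        row = self.counts.iloc[offset]
        return editing_percentage(int(row["A"]), int(row["G"]))

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "offset", np.arange(len(df)))
        df["depth"] = df[["A", "C", "G", "T", "other"]].sum(axis=1)
        ag = df["A"] + df["G"]
        with np.errstate(invalid="ignore", divide="ignore"):
            df["G_pct"] = np.where(ag > 0, 100.0 * df["G"] / ag, np.nan)
        return df


@dataclass
class IsoformProfile:
    """Relative proportions (percent of classified reads) of co-editing patterns."""

    proportions: dict[frozenset[str], float]
    classified_reads: int
    discarded_reads: int = 0
    below_threshold: set[frozenset[str]] = field(default_factory=set)

    def site_levels(self, labels: Iterable[str] | None = None) -> dict[str, float]:
        labs = list(labels) if labels is not None else sorted(
            {lab for s in self.proportions for lab in s}
        )
        return {
            lab: sum(p for s, p in self.proportions.items() if lab in s) for lab in labs
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "isoform": isoform_name(s),
                "proportion": p,
                "below_threshold": s in self.below_threshold,
            }
            for s, p in sorted(
                self.proportions.items(), key=lambda kv: (-kv[1], isoform_name(kv[0]))
            )
        ]
        return pd.DataFrame(rows)


@dataclass
class AlignedReads:
    """Accepted reads plus per-reason discard counts."""

    matrix: np.ndarray  # uint8 ASCII, shape (n_accepted, amplicon_length)
    reference: ReferenceAmplicon
    discarded: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())


def read_fastq(path: str | Path) -> ReadBatch:
    """Load a FASTQ file (gz-transparent) into a read batch."""
    import gzip as _gzip

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = _gzip.open if path.suffix == ".gz" else open
    ids, seqs = [], []
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            ids.append(title.split()[0])
            seqs.append(seq)
    if not seqs:
        raise ValueError(f"{path}: no reads")
    lengths = {len(s) for s in seqs}
    width = max(lengths)
    matrix = np.full((len(seqs), width), ord("N"), dtype=np.uint8)
    for i, s in enumerate(seqs):
        matrix[i, : len(s)] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    if len(lengths) > 1:
        # keep true lengths recoverable: pad char 'N' never matches reference
        pass
    return ReadBatch(ids=ids, matrix=matrix)


def _as_matrix(reads, length: int) -> np.ndarray:
    """Coerce FASTQ path(s), ReadBatch or sequence strings to a padded matrix."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    if isinstance(reads, ReadBatch):
        return reads.matrix
    if isinstance(reads, np.ndarray):
        return reads
    seqs = list(reads)
    if seqs and isinstance(seqs[0], (str, bytes)):
        width = max(max(len(s) for s in seqs), length)
        matrix = np.full((len(seqs), width), ord("N"), dtype=np.uint8)
        for i, s in enumerate(seqs):
            b = s.encode("ascii") if isinstance(s, str) else s
            matrix[i, : len(b)] = np.frombuffer(b, dtype=np.uint8)
        return matrix
    raise TypeError(f"unsupported read input {type(reads)!r}")


def align_reads(
    reads, ref: ReferenceAmplicon, max_mismatch: int = 5
) -> AlignedReads:
    """Anchored ungapped alignment of full-length reads at offset 0.

    A read is accepted when it has the amplicon length and its Hamming
    distance to the reference *outside candidate positions* is at most
    `max_mismatch`; otherwise it is discarded with a counted reason
    (never fatal).
    """
    matrix = _as_matrix(reads, len(ref))
    if matrix.shape[0] == 0:
        raise ValueError("no reads to align")
    length = len(ref)
    refv = ref.encoded()

    if matrix.shape[1] < length:
        pad = np.full((matrix.shape[0], length - matrix.shape[1]), ord("N"), np.uint8)
        matrix = np.hstack([matrix, pad])
    # reads longer than the amplicon (non-N beyond the target) are length mismatches
    too_long = (
        (matrix[:, length:] != ord("N")).any(axis=1)
        if matrix.shape[1] > length
        else np.zeros(matrix.shape[0], dtype=bool)
    )
    body = matrix[:, :length]
    too_short = (body == ord("N")).any(axis=1)
    bad_length = too_long | too_short

    mism = body != refv
    mism[:, ref.offsets] = False  # candidate positions never count as mismatches
    n_mism = mism.sum(axis=1)
    too_divergent = (n_mism > max_mismatch) & ~bad_length

    keep = ~(bad_length | too_divergent)
    discarded = {}
    if bad_length.any():
        discarded["length_mismatch"] = int(bad_length.sum())
    if too_divergent.any():
        discarded["too_many_mismatches"] = int(too_divergent.sum())
    return AlignedReads(matrix=body[keep].copy(), reference=ref, discarded=discarded)


def count_bases(aligned: AlignedReads) -> BaseCountTable:
    """Per-position nucleotide tally over the accepted reads."""
    if aligned.n_reads < 1:
        raise ValueError("need at least one aligned read")
    m = aligned.matrix
    cols = {}
    total_known = np.zeros(m.shape[1], dtype=np.int64)
    for base in "ACGT":
        c = (m == ord(base)).sum(axis=0)
        cols[base] = c
        total_known += c
    cols["other"] = m.shape[0] - total_known
    return BaseCountTable(counts=pd.DataFrame(cols), total_reads=m.shape[0])


def editing_percentage(a_count: int, g_count: int) -> float | None:
    """G / (G + A) × 100 at one position; None (undefined) when A + G = 0.

    Reads with C, T or N at the position enter neither numerator nor
    denominator; an undefined value is reported missing, never as 0.
    """
    denom = a_count + g_count
    if denom == 0:
        return None
    return 100.0 * g_count / denom


def call_sites(
    table: BaseCountTable, ref: ReferenceAmplicon, cfg: SiteCallingConfig | None = None
) -> list[SiteCall]:
    """Call editing sites: G-percentage strictly above the detection threshold.

    Every candidate A position receives a call (pass or fail); the comparison
    is strict, so a position at exactly the threshold does not pass.
    """
    cfg = cfg or SiteCallingConfig()
    calls = []
    for site in ref.sites:
        row = table.counts.iloc[site.offset]
        pct = editing_percentage(int(row["A"]), int(row["G"]))
        passed = pct is not None and pct > cfg.detection_threshold
        calls.append(SiteCall(label=site.label, offset=site.offset, percentage=pct, passed=passed))
    return calls


def enumerate_isoforms(
    aligned: AlignedReads,
    called_sites: Sequence[SiteCall],
    cfg: SiteCallingConfig | None = None,
) -> IsoformProfile:
    """Classify each read by the set of passing sites at which it carries G.

    Reads with C/T/N at any passing site are excluded from classification and
    counted as discarded; relative proportions are percentages of classified
    reads and sum to 100 before any threshold.  Patterns below the inclusion
    threshold are flagged but retained.
    """
    cfg = cfg or SiteCallingConfig()
    passing = [c for c in called_sites if c.passed]
    if not passing:
        return IsoformProfile(
            proportions={frozenset(): 100.0},
            classified_reads=aligned.n_reads,
            discarded_reads=0,
        )
    offs = np.array([c.offset for c in passing], dtype=np.intp)
    labels = [c.label for c in passing]
    sub = aligned.matrix[:, offs]
    is_g = sub == ord("G")
    is_a = sub == ord("A")
    ok = (is_g | is_a).all(axis=1)
    n_discard = int((~ok).sum())
    bits = is_g[ok]
    if bits.shape[0] == 0:
        raise ValueError("all reads carry non-A/G bases at called sites")
    # pack the per-read pattern into an integer code for a fast tally
    codes = bits @ (1 << np.arange(len(labels), dtype=np.int64))
    uniq, counts = np.unique(codes, return_counts=True)
    n_class = int(bits.shape[0])
    proportions: dict[frozenset[str], float] = {}
    for code, n in zip(uniq, counts):
        members = frozenset(lab for i, lab in enumerate(labels) if code >> i & 1)
        proportions[members] = 100.0 * n / n_class
    if frozenset() not in proportions:
        proportions[frozenset()] = 0.0
    below = {s for s, p in proportions.items() if p < cfg.isoform_threshold}
    return IsoformProfile(
        proportions=proportions,
        classified_reads=n_class,
        discarded_reads=n_discard,
        below_threshold=below,
    )


def site_level_from_isoforms(profile: IsoformProfile) -> dict[str, float]:
    """Site level = sum of pattern proportions over patterns containing the site."""
    return profile.site_levels()


def aggregate_replicates(profiles: Sequence[IsoformProfile]) -> IsoformProfile:
    """Combine technical replicates as the unweighted mean of proportions.

    Replicates are independent library preparations of the same sample, so
    each contributes equally regardless of its depth (pooling reads would
    weight deeper replicates more).
    """
    if not profiles:
        raise ValueError("need at least one replicate profile")
    keys = sorted({s for p in profiles for s in p.proportions}, key=isoform_name)
    mean = {
        s: float(np.mean([p.proportions.get(s, 0.0) for p in profiles])) for s in keys
    }
    thr_flags = {s for p in profiles for s in p.below_threshold}
    return IsoformProfile(
        proportions=mean,
        classified_reads=sum(p.classified_reads for p in profiles),
        discarded_reads=sum(p.discarded_reads for p in profiles),
        below_threshold={s for s in thr_flags if s in mean},
    )


def quantify_sample(
    replicate_reads: Iterable,
    ref: ReferenceAmplicon,
    cfg: SiteCallingConfig | None = None,
    site_set: Sequence[str] | None = None,
) -> tuple[IsoformProfile, list[list[SiteCall]], list[BaseCountTable]]:
    """Run the full per-sample pipeline over replicates and aggregate.

    When `site_set` is given (labels), patterns are enumerated over exactly
    those sites for every replicate — the shared-feature-space mode used in
    cohort analyses; otherwise sites are called per replicate.
    """
    cfg = cfg or SiteCallingConfig()
    profiles, all_calls, tables = [], [], []
    for reads in replicate_reads:
        aligned = align_reads(reads, ref, max_mismatch=cfg.max_mismatch)
        table = count_bases(aligned)
        calls = call_sites(table, ref, cfg)
        if site_set is not None:
            fixed = set(site_set)
            calls = [
                SiteCall(c.label, c.offset, c.percentage, c.label in fixed)
                for c in calls
            ]
        profiles.append(enumerate_isoforms(aligned, calls, cfg))
        all_calls.append(calls)
        tables.append(table)
    return aggregate_replicates(profiles), all_calls, tables


def analysis_site_set(
    control_site_pcts: pd.DataFrame, cfg: SiteCallingConfig | None = None
) -> list[str]:
    """Cohort analysis site set: sites whose control-group mean editing
    percentage is strictly above the detection threshold.

    `control_site_pcts`: one row per control subject, one column per site
    label (replicate-aggregated percentages).  Applying the threshold to the
    control mean keeps one feature space for all samples; per-sample pass
    flags remain available from `call_sites`.
    """
    cfg = cfg or SiteCallingConfig()
    means = control_site_pcts.mean(axis=0)
    chosen = [lab for lab, m in means.items() if m > cfg.detection_threshold]
    if not chosen:
        warnings.warn("no site above the detection threshold in the control mean")
    return chosen
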