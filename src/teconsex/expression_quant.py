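"""Read counting and RPKM-based expression calls.

Counting follows coverageBed semantics: a read interval overlapping a
feature by at least one base increments that feature's count, and a read
straddling two features increments both. Counts are normalized to RPKM
(reads per kilobase of feature per million library reads). Two expression
rules coexist, matching how TEs and transcripts are treated differently:

* TE rule: the RPKM values of the replicates are averaged and the feature
  is expressed when the mean is >= 1.
* transcript rule: every replicate individually must reach RPKM >= 1
  (strictly stricter than the TE rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

RPKM_CUTOFF = 1.0


def rpkm(count: float, length_bp: int, library_size: int) -> float:
    """count / ((length_bp / 1e3) * (library_size / 1e6))."""
    if length_bp <= 0:
        raise ValidationError(f"feature length must be positive, got {length_bp}")
    if library_size <= 0:
        raise ValidationError(f"library size must be positive, got {library_size}")
    return count * 1e9 / (length_bp * library_size)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-feature counts and RPKMs across replicates of one species."""

    feature_id: str
    length_bp: int
    counts: tuple[int, ...]
    library_sizes: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != len(self.library_sizes):
            raise ValidationError("counts and library_sizes must align")
        if not self.counts:
            raise ValidationError("at least one replicate required")
        if any(c < 0 for c in self.counts):
            raise ValidationError("negative count")

    @property
    def rpkms(self) -> tuple[float, ...]:
        return tuple(
            rpkm(c, self.length_bp, lib) for c, lib in zip(self.counts, self.library_sizes)
        )

    @property
    def mean_rpkm(self) -> float:
        vals = self.rpkms
        return sum(vals) / len(vals)


def te_expressed(record: ExpressionRecord, cutoff: float = RPKM_CUTOFF) -> bool:
    """Mean-over-replicates rule: mean RPKM >= cutoff (inclusive)."""
    return record.mean_rpkm >= cutoff


def transcript_expressed(record: ExpressionRecord, cutoff: float = RPKM_CUTOFF) -> bool:
    """All-replicates rule: every replicate's RPKM >= cutoff (inclusive)."""
    return all(v >= cutoff for v in record.rpkms)


def count_overlapping_reads(
    features: Sequence[tuple[str, str, int, int]],
    reads: Iterable[tuple[str, int, int]],
) -> dict[str, int]:
    """Count read intervals overlapping each feature by >=1 bp.

    ``features`` are (feature_id, chrom, start, end) in 0-based half-open
    coordinates; ``reads`` are (chrom, start, end). A read overlapping
    several features is counted once per feature (coverageBed behaviour).

    Uses the identity overlap(read, f) <=> read.start < f.end and
    read.end > f.start, so the count per feature is
    #(read starts < f.end) - #(read ends <= f.start) over sorted read
    boundaries; exact for any feature overlap structure.
    """
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, start, end in reads:
        starts_ends = by_chrom.setdefault(chrom, ([], []))
        starts_ends[0].append(start)
        starts_ends[1].append(end)
    sorted_bounds = {
        chrom: (np.sort(np.asarray(s, dtype=np.int64)), np.sort(np.asarray(e, dtype=np.int64)))
        for chrom, (s, e) in by_chrom.items()
    }
    counts: dict[str, int] = {}
    for fid, chrom, start, end in features:
        bounds = sorted_bounds.get(chrom)
        if bounds is None:
            counts[fid] = 0
            continue
        starts, ends = bounds
        n = int(np.searchsorted(starts, end, side="left")) - int(
            np.searchsorted(ends, start, side="right")
        )
        counts[fid] = n
    return counts


def expression_table(
    features: Sequence[tuple[str, str, int, int]],
    reads_per_replicate: Sequence[Iterable[tuple[str, int, int]]],
    library_sizes: Sequence[int],
    feature_lengths: dict[str, int] | None = None,
    mode: str = "te",
    cutoff: float = RPKM_CUTOFF,
) -> pd.DataFrame:
    """Count every replicate over the features and call expression.

    ``feature_lengths`` overrides the span length used for RPKM (for joined
    TE instances the summed fragment length is the appropriate denominator:
    reads cannot map to the nested interloper). ``mode`` selects the TE
    (mean) or transcript (all-replicates) rule.
    """
    if mode not in ("te", "transcript"):
        raise ValidationError(f"mode must be 'te' or 'transcript', got {mode!r}")
    if len(reads_per_replicate) != len(library_sizes):
        raise ValidationError("one library size per replicate required")
    per_rep = [count_overlapping_reads(features, reads) for reads in reads_per_replicate]
    rule = te_expressed if mode == "te" else transcript_expressed
    rows = []
    for fid, chrom, start, end in features:
        length = (feature_lengths or {}).get(fid, end - start)
        rec = ExpressionRecord(
            feature_id=fid,
            length_bp=length,
            counts=tuple(c[fid] for c in per_rep),
            library_sizes=tuple(library_sizes),
        )
        rows.append(
            {
                "feature_id": fid,
                "length_bp": length,
                **{f"count_{i + 1}": c for i, c in enumerate(rec.counts)},
                **{f"rpkm_{i + 1}": v for i, v in enumerate(rec.rpkms)},
                "mean_rpkm": rec.mean_rpkm,
                "expressed": rule(rec, cutoff),
            }
        )
    return pd.DataFrame(rows)


def read_reads_bed(path) -> list[tuple[str, int, int]]:
    """Load read intervals from a BED file (first three columns)."""
    reads = []
    with open(path) as handle:
        for raw in handle:
            if not raw.strip() or raw.startswith(("track", "#")):
                continue
            fields = raw.split("\t")
            reads.append((fields[0], int(fields[1]), int(fields[2])))
    return reads
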