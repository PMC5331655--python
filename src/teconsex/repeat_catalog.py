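"""Repeat catalog construction from RepeatMasker annotation tables.

RepeatMasker reports every aligned repeat fragment separately; a single old
insertion that was later disrupted by a nested younger insertion appears as
two or more fragments sharing the same ID. This module parses the ``.out``
table, joins same-ID fragments into insertion-level instances (singletons
pass through unchanged), converts the percent divergence from the family
consensus into a 0-1000 similarity score (higher = closer to consensus =
younger), derives family ages as the mean score over members, and removes
instances that overlap coding regions (the analysis concerns non-coding
transcription only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Number of header lines at the top of a RepeatMasker .out file.
_N_HEADER_LINES = 3


@dataclass(frozen=True)
class TEFragment:
    """One RepeatMasker alignment fragment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    perc_div: float
    sw_score: int
    rm_id: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TEInstance:
    """One repeat insertion, possibly joined from nested fragments.

    ``start``/``end`` delimit the genomic span (min fragment start to max
    fragment end); ``length_bp`` is the summed fragment length, which can be
    smaller than the span when a nested element interrupts the insertion.
    """

    instance_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    scaled_score: int
    length_bp: int
    fragments: list[TEFragment] = field(default_factory=list)

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FamilyAge:
    """Mean consensus-similarity score over family members (age surrogate)."""

    family: str
    mean_scaled_score: float
    n_instances: int


def scale_similarity(perc_div: float) -> int:
    """Convert percent divergence from consensus to a 0-1000 similarity score.

    Linear map ``round(1000 * (1 - perc_div/100))``: 0% divergence (identical
    to consensus, youngest) scores 1000; 100% scores 0. Strictly decreasing in
    divergence, so downstream uses that only rank families by age are
    insensitive to the exact functional form.
    """
    if not 0.0 <= perc_div <= 100.0:
        raise ValidationError(f"perc_div must be in [0, 100], got {perc_div}")
    return round(1000 * (1.0 - perc_div / 100.0))


def _open_maybe(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source), True
    return source, False


def parse_repeatmasker_out(source: str | Path | IO[str]) -> list[TEFragment]:
    """Parse a RepeatMasker ``.out`` table into fragments.

    The dialect: 3 header lines, then whitespace-delimited columns
    (swScore, percDiv, percDel, percIns, query, qBegin, qEnd, qLeft, strand,
    repeatName, class/family, rBegin, rEnd, rLeft, ID). qBegin/qEnd are
    1-based inclusive and are converted to 0-based half-open; strand ``C``
    (complement) becomes ``-``. The repeat name column is kept whole as the
    family name; the class is the part of class/family before ``/``.

    Raises :class:`ParseError` with the line number on malformed rows and on
    rows missing the ID column (the ID is required for fragment joining).
    """
    handle, close = _open_maybe(source)
    fragments: list[TEFragment] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            if lineno <= _N_HEADER_LINES:
                continue
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) == 14:
                raise ParseError("missing ID column", line=lineno)
            if len(fields) < 15:
                raise ParseError(
                    f"expected >=15 whitespace-delimited columns, got {len(fields)}",
                    line=lineno,
                )
            try:
                sw_score = int(fields[0])
                perc_div = float(fields[1])
                chrom = fields[4]
                q_begin = int(fields[5])
                q_end = int(fields[6])
                strand_tok = fields[8]
                family = fields[9]
                class_family = fields[10]
                rm_id = int(fields[14])
            except ValueError as exc:
                raise ParseError(f"bad field value ({exc})", line=lineno) from exc
            if strand_tok == "+":
                strand = "+"
            elif strand_tok in ("C", "-"):
                strand = "-"
            else:
                raise ParseError(f"bad strand token {strand_tok!r}", line=lineno)
            if not 0.0 <= perc_div <= 100.0:
                raise ParseError(f"percDiv {perc_div} outside [0, 100]", line=lineno)
            start, end = q_begin - 1, q_end
            if start >= end:
                raise ParseError(f"empty interval {q_begin}..{q_end}", line=lineno)
            te_class = class_family.split("/")[0]
            fragments.append(
                TEFragment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    family=family,
                    te_class=te_class,
                    perc_div=perc_div,
                    sw_score=sw_score,
                    rm_id=rm_id,
                )
            )
    finally:
        if close:
            handle.close()
    return fragments


def join_nested_repeats(fragments: Iterable[TEFragment]) -> list[TEInstance]:
    """Join fragments sharing a RepeatMasker ID into insertion instances.

    One instance is produced per (chrom, ID) group; singleton groups pass
    through unchanged. The instance score is the length-weighted mean of the
    fragments' scaled similarity scores. Fragments with the same ID on
    different chromosomes are never merged (a warning is logged): joining
    across chromosomes is biologically meaningless.
    """
    groups: dict[tuple[str, int], list[TEFragment]] = {}
    chroms_per_id: dict[int, set[str]] = {}
    for frag in fragments:
        groups.setdefault((frag.chrom, frag.rm_id), []).append(frag)
        chroms_per_id.setdefault(frag.rm_id, set()).add(frag.chrom)
    for rm_id, chroms in chroms_per_id.items():
        if len(chroms) > 1:
            logger.warning(
                "RepeatMasker ID %d appears on %d chromosomes; kept as separate instances",
                rm_id,
                len(chroms),
            )

    instances: list[TEInstance] = []
    for (chrom, rm_id), frags in groups.items():
        length_bp = sum(f.length for f in frags)
        weighted = sum(f.length * scale_similarity(f.perc_div) for f in frags)
        longest = max(frags, key=lambda f: f.length)
        instances.append(
            TEInstance(
                instance_id=f"{chrom}:{rm_id}",
                chrom=chrom,
                start=min(f.start for f in frags),
                end=max(f.end for f in frags),
                strand=longest.strand,
                family=longest.family,
                te_class=longest.te_class,
                scaled_score=round(weighted / length_bp),
                length_bp=length_bp,
                fragments=sorted(frags, key=lambda f: f.start),
            )
        )
    instances.sort(key=lambda i: (i.chrom, i.start, i.instance_id))
    return instances


def family_ages(instances: Iterable[TEInstance]) -> list[FamilyAge]:
    """Age surrogate per family: arithmetic mean of member similarity scores."""
    scores: dict[str, list[int]] = {}
    for inst in instances:
        scores.setdefault(inst.family, []).append(inst.scaled_score)
    return [
        FamilyAge(family=fam, mean_scaled_score=sum(vals) / len(vals), n_instances=len(vals))
        for fam, vals in sorted(scores.items())
    ]


def filter_coding_overlap(
    instances: Iterable[TEInstance],
    coding_regions: Iterable[tuple[str, int, int]],
) -> list[TEInstance]:
    """Drop instances whose span overlaps any coding interval by >=1 bp.

    Intervals are half-open, so a coding region starting exactly at an
    instance's end does not count as overlap. Idempotent.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in coding_regions:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    kept = []
    for inst in instances:
        tree = trees.get(inst.chrom)
        if tree is not None and tree.overlap(inst.start, inst.end):
            continue
        kept.append(inst)
    return kept


def write_instances_bed(instances: Iterable[TEInstance], path: str | Path) -> None:
    """Write instances as BED6: name = ``family|instanceId``, score = scaled score."""
    with open(path, "w") as out:
        for inst in instances:
            out.write(
                f"{inst.chrom}\t{inst.start}\t{inst.end}\t"
                f"{inst.family}|{inst.instance_id}\t{inst.scaled_score}\t{inst.strand}\n"
            )


def read_instances_bed(path: str | Path) -> list[TEInstance]:
    """Read instances written by :func:`write_instances_bed`.

    Fragment-level detail is not serialized; the reconstructed instance has
    an empty fragment list and ``length_bp`` equal to the span length. Span,
    strand, family and scaled score round-trip exactly. The TE class is not
    stored in BED6 and comes back empty.
    """
    instances = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("expected 6 BED columns", line=lineno)
            chrom, start, end, name, score, strand = fields[:6]
            family, _, instance_id = name.partition("|")
            instances.append(
                TEInstance(
                    instance_id=instance_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    family=family,
                    te_class="",
                    scaled_score=int(score),
                    length_bp=int(end) - int(start),
                )
            )
    return instances


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED file (extra columns ignored)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >=3 BED columns", line=lineno)
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
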