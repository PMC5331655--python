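"""Interval liftover through UCSC chain alignments.

A chain is an ordered list of gapped aligned blocks between a source and a
target assembly. An interval on the source maps to the target when at least
``min_match`` of its bases fall inside aligned blocks of some chain (the
UCSC LiftOver ``-minMatch`` rule; 0.1 is the between-species default). The
lifted interval spans the target positions of the first through last mapped
source base, matching LiftOver's region behaviour rather than the union of
mapped segments. Negative-strand chains follow the UCSC convention (target
coordinates counted from the far end of the chromosome) and results are
always reported on the target forward strand with a strand flag.

The module also classifies TE instances as sequence-conserved: an instance
is putatively conserved in a target species when its locus lifts and the
lifted locus overlaps a TE annotated independently in the target genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import ParseError, UndefinedStatisticError, ValidationError
from .repeat_catalog import TEInstance


@dataclass(frozen=True)
class ChainBlock:
    """One aligned block followed by its (source, target) gap lengths."""

    size: int
    source_gap: int = 0
    target_gap: int = 0


@dataclass
class Chain:
    """One pairwise alignment chain (UCSC chain format semantics).

    The UCSC header names the source assembly "target" (t) and the lifted-to
    assembly "query" (q); here they are called source and target in lift
    direction order. Source coordinates are always forward strand; target
    coordinates are in chain orientation (counted from the chromosome end
    when ``target_strand == '-'``).
    """

    chain_id: int
    score: int
    source_chrom: str
    source_size: int
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: list[ChainBlock]
    # lazily built numpy index over block starts, for O(log B) lifting
    _index: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> None:
        aligned = sum(b.size for b in self.blocks)
        sgaps = sum(b.source_gap for b in self.blocks)
        tgaps = sum(b.target_gap for b in self.blocks)
        if aligned + sgaps != self.source_end - self.source_start:
            raise ParseError(
                f"chain {self.chain_id}: source block sums ({aligned}+{sgaps}) "
                f"!= span {self.source_end - self.source_start}"
            )
        if aligned + tgaps != self.target_end - self.target_start:
            raise ParseError(
                f"chain {self.chain_id}: target block sums ({aligned}+{tgaps}) "
                f"!= span {self.target_end - self.target_start}"
            )
        if any(b.size < 1 for b in self.blocks):
            raise ParseError(f"chain {self.chain_id}: aligned block size < 1")
        if any(b.source_gap < 0 or b.target_gap < 0 for b in self.blocks):
            raise ParseError(f"chain {self.chain_id}: negative gap")

    def block_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(source starts, target starts, sizes) arrays per aligned block."""
        if self._index is None:
            n = len(self.blocks)
            s_starts = np.empty(n, dtype=np.int64)
            t_starts = np.empty(n, dtype=np.int64)
            sizes = np.empty(n, dtype=np.int64)
            s, t = self.source_start, self.target_start
            for i, b in enumerate(self.blocks):
                s_starts[i], t_starts[i], sizes[i] = s, t, b.size
                s += b.size + b.source_gap
                t += b.size + b.target_gap
            self._index = (s_starts, t_starts, sizes)
        return self._index


class LiftStatus(str, Enum):
    MAPPED = "mapped"
    UNMAPPED_BELOW_MINMATCH = "unmapped_below_minMatch"
    UNMAPPED_NO_CHAIN = "unmapped_no_chain"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LiftResult:
    status: LiftStatus
    mapped_bases: int = 0
    mapped_ratio: float = 0.0
    target_chrom: str | None = None
    target_start: int | None = None
    target_end: int | None = None
    target_strand: str | None = None
    chain_id: int | None = None

    @property
    def mapped(self) -> bool:
        return self.status is LiftStatus.MAPPED


@dataclass
class ConservationRecord:
    """Per-instance sequence-conservation flags against one target species.

    ``te_annotated_in_target`` implies ``lifted``; ``same_family_in_target``
    implies ``te_annotated_in_target``. ``expressed_in_target`` is filled by
    the expression stage (expression of the best-overlapping target TE).
    """

    instance_id: str
    family: str
    te_class: str
    lifted: bool
    te_annotated_in_target: bool = False
    same_family_in_target: bool = False
    expressed_in_target: bool = False
    target_species: str | None = None
    matched_target_instance: str | None = None
    lift: LiftResult | None = None


def parse_chain(source: str | Path | IO[str]) -> list[Chain]:
    """Parse UCSC chain text format; invariants are verified per chain."""
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    chains: list[Chain] = []
    current: Chain | None = None
    next_id = 1
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                fields = line.split()
                if len(fields) not in (12, 13):
                    raise ParseError("chain header needs 12 or 13 fields", line=lineno)
                if fields[4] != "+":
                    raise ParseError("source strand must be '+'", line=lineno)
                chain_id = int(fields[12]) if len(fields) == 13 else next_id
                next_id = chain_id + 1
                current = Chain(
                    chain_id=chain_id,
                    score=int(fields[1]),
                    source_chrom=fields[2],
                    source_size=int(fields[3]),
                    source_start=int(fields[5]),
                    source_end=int(fields[6]),
                    target_chrom=fields[7],
                    target_size=int(fields[8]),
                    target_strand=fields[9],
                    target_start=int(fields[10]),
                    target_end=int(fields[11]),
                    blocks=[],
                )
                chains.append(current)
            else:
                if current is None:
                    raise ParseError("alignment line before chain header", line=lineno)
                fields = line.split()
                if len(fields) == 3:
                    current.blocks.append(
                        ChainBlock(int(fields[0]), int(fields[1]), int(fields[2]))
                    )
                elif len(fields) == 1:
                    current.blocks.append(ChainBlock(int(fields[0])))
                else:
                    raise ParseError("alignment line needs 1 or 3 fields", line=lineno)
    finally:
        if close:
            handle.close()
    for chain in chains:
        chain.validate()
    return chains


def write_chains(chains: Iterable[Chain], path: str | Path) -> None:
    with open(path, "w") as out:
        for c in chains:
            out.write(
                f"chain {c.score} {c.source_chrom} {c.source_size} + "
                f"{c.source_start} {c.source_end} {c.target_chrom} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for i, b in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    out.write(f"{b.size}\n")
                else:
                    out.write(f"{b.size} {b.source_gap} {b.target_gap}\n")
            out.write("\n")


def _map_through(chain: Chain, start: int, end: int) -> tuple[int, int, int] | None:
    """Mapped bases and first/last mapped target positions (chain orientation).

    Returns None when no base of [start, end) falls in an aligned block.
    """
    s_starts, t_starts, sizes = chain.block_index()
    # blocks whose source span [s, s+size) can intersect [start, end)
    lo = int(np.searchsorted(s_starts, start + 1, side="left")) - 1
    lo = max(lo, 0)
    hi = int(np.searchsorted(s_starts, end, side="left"))
    mapped = 0
    t_first = t_last = None
    for i in range(lo, hi):
        s0 = int(s_starts[i])
        a = max(s0, start)
        b = min(s0 + int(sizes[i]), end)
        if a < b:
            mapped += b - a
            t0 = int(t_starts[i])
            if t_first is None:
                t_first = t0 + (a - s0)
            t_last = t0 + (b - 1 - s0)
    if mapped == 0:
        return None
    return mapped, t_first, t_last


def lift_interval(
    interval: tuple[str, int, int],
    chains: Sequence[Chain],
    min_match: float = 0.1,
) -> LiftResult:
    """Lift one source interval through a set of chains.

    Among chains overlapping the interval, the one maximizing the number of
    interval bases inside aligned blocks wins (chain score breaks ties; a
    residual tie pointing at different target loci is reported ambiguous).
    The lift succeeds when mapped_bases / interval_length >= ``min_match``.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValidationError(f"zero-length interval {chrom}:{start}-{end}")
    if not 0.0 < min_match <= 1.0:
        raise ValidationError(f"min_match must be in (0, 1], got {min_match}")
    length = end - start

    candidates = []
    for chain in chains:
        if chain.source_chrom != chrom:
            continue
        if chain.source_end <= start or chain.source_start >= end:
            continue
        hit = _map_through(chain, start, end)
        if hit is not None:
            candidates.append((hit[0], chain.score, chain, hit[1], hit[2]))
    if not candidates:
        return LiftResult(status=LiftStatus.UNMAPPED_NO_CHAIN)

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2].chain_id))
    mapped, _, chain, t_first, t_last = candidates[0]
    if len(candidates) > 1:
        m2, score2, chain2, tf2, tl2 = candidates[1]
        if m2 == mapped and score2 == chain.score:
            same_locus = (
                chain2.target_chrom == chain.target_chrom
                and chain2.target_strand == chain.target_strand
                and (tf2, tl2) == (t_first, t_last)
            )
            if not same_locus:
                return LiftResult(
                    status=LiftStatus.AMBIGUOUS,
                    mapped_bases=mapped,
                    mapped_ratio=mapped / length,
                )

    ratio = mapped / length
    if ratio < min_match:
        return LiftResult(
            status=LiftStatus.UNMAPPED_BELOW_MINMATCH,
            mapped_bases=mapped,
            mapped_ratio=ratio,
            chain_id=chain.chain_id,
        )
    if chain.target_strand == "-":
        t_start = chain.target_size - (t_last + 1)
        t_end = chain.target_size - t_first
    else:
        t_start, t_end = t_first, t_last + 1
    return LiftResult(
        status=LiftStatus.MAPPED,
        mapped_bases=mapped,
        mapped_ratio=ratio,
        target_chrom=chain.target_chrom,
        target_start=t_start,
        target_end=t_end,
        target_strand=chain.target_strand,
        chain_id=chain.chain_id,
    )


def build_instance_tree(instances: Iterable[TEInstance]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over instance spans (data = instance)."""
    trees: dict[str, IntervalTree] = {}
    for inst in instances:
        trees.setdefault(inst.chrom, IntervalTree()).addi(inst.start, inst.end, inst)
    return trees


def classify_conservation(
    instances: Iterable[TEInstance],
    chains: Sequence[Chain],
    target_instances: Iterable[TEInstance],
    min_match: float = 0.1,
    target_species: str | None = None,
) -> list[ConservationRecord]:
    """Flag each instance as lifted / TE-annotated / same-family in the target.

    ``te_annotated_in_target`` requires >=1 bp overlap between the lifted
    locus and any target TE instance; ``same_family_in_target`` compares the
    family of the maximally-overlapping target instance.
    """
    trees = build_instance_tree(target_instances)
    records = []
    for inst in instances:
        res = lift_interval((inst.chrom, inst.start, inst.end), chains, min_match)
        rec = ConservationRecord(
            instance_id=inst.instance_id,
            family=inst.family,
            te_class=inst.te_class,
            lifted=res.mapped,
            target_species=target_species,
            lift=res,
        )
        if res.mapped:
            tree = trees.get(res.target_chrom)
            hits = tree.overlap(res.target_start, res.target_end) if tree else ()
            if hits:
                best = max(
                    hits,
                    key=lambda iv: (
                        min(iv.end, res.target_end) - max(iv.begin, res.target_start),
                        iv.data.instance_id,
                    ),
                )
                rec.te_annotated_in_target = True
                rec.matched_target_instance = best.data.instance_id
                rec.same_family_in_target = best.data.family == inst.family
        records.append(rec)
    return records


def reannotation_concordance(family: str, records: Iterable[ConservationRecord]) -> float:
    """Fraction of lifted instances of ``family`` re-annotated as the same family.

    Validates the lift: for a family with no cross-species mislabelling this
    should be high (the HERVH-style check). Raises
    :class:`UndefinedStatisticError` when no instance of the family lifted.
    """
    lifted = [r for r in records if r.family == family and r.lifted]
    if not lifted:
        raise UndefinedStatisticError(f"no lifted instances for family {family!r}")
    return sum(r.same_family_in_target for r in lifted) / len(lifted)
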