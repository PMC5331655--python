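"""lncRNA catalog construction, TE annotation, and cross-species conservation.

The catalog starts from assembled transcript models (GTF) and applies a
filtering cascade: known non-lncRNA biotypes are removed (protein-coding
genes, pseudogenes, structural RNAs), then mono-exonic transcripts (too
prone to systematic assembly false positives), then transcripts with
protein-coding potential at or above a cutoff. The coding-potential score
comes from an input attribute when present; otherwise a simple longest-ORF
fraction computed from the transcript sequence stands in (a deliberately
transparent score, pluggable for a trained model).

Retained lncRNAs are annotated with the TEs they exapted: an exon/TE
intersection counts only when it covers at least ``min_exon_fraction``
(default 10%) of the exon, and each transcript is labelled with the single
dominant TE instance contributing the most overlapping sequence.
Contribution statistics compare each TE class's and family's share of
lncRNA exonic sequence against its genomic share. Finally, catalogs are
lifted to target species through alignment chains and tiered by where the
transcript is both lifted and expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .errors import UndefinedStatisticError, ValidationError
from .expression_quant import ExpressionRecord, transcript_expressed
from .orthology_lift import Chain, build_instance_tree, lift_interval
from .repeat_catalog import TEInstance

logger = logging.getLogger(__name__)

#: Biotypes never admitted to a lncRNA catalog. The exact blacklist used by
#: any particular annotation project varies; this default covers coding
#: genes, pseudogene subtypes and the short structural RNA classes.
DEFAULT_BIOTYPE_BLACKLIST = frozenset(
    {
        "protein_coding",
        "pseudogene",
        "tRNA",
        "rRNA",
        "snRNA",
        "snoRNA",
        "miRNA",
        "misc_RNA",
    }
)

#: Widely used human cutoff for CPAT-style coding probability; documented as
#: an arbitrary default — the proper value is training-set dependent.
DEFAULT_CODING_POTENTIAL_CUTOFF = 0.364

TIER_ALL_SPECIES = "all_species"
TIER_SOME_NHP = "some_nhp"
TIER_QUERY_ONLY = "query_only"


@dataclass
class LncTranscript:
    """A multi-exon transcript model with optional biotype/coding metadata."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str | None = None
    coding_potential: float | None = None
    sequence: str | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class ExonTEOverlap:
    te_instance_id: str
    family: str
    te_class: str
    exon_index: int
    overlap_bp: int


@dataclass
class TEOverlapAnnotation:
    transcript_id: str
    overlaps: list[ExonTEOverlap] = field(default_factory=list)
    dominant_instance: str | None = None
    dominant_family: str | None = None

    @property
    def has_te(self) -> bool:
        return bool(self.overlaps)


def orf_coding_score(sequence: str) -> float:
    """Longest forward-frame ORF (ATG through stop, inclusive) over length.

    Scans the three forward frames; an open reading frame requires an ATG
    start and an in-frame stop codon (TAA/TAG/TGA) — a start without a stop
    does not count. Returns a value in [0, 1]; sequences with no ATG score 0.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValidationError("sequence must be over A/C/G/T/N")
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for frame in range(3):
        orf_start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = pos
            elif codon in stops:
                best = max(best, pos + 3 - orf_start)
                orf_start = None
    return best / len(seq)


def read_transcripts_gtf(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
) -> list[LncTranscript]:
    """Load transcript models from a GTF file (exon features).

    Recognized attributes: ``transcript_id`` (required), ``transcript_biotype``
    and ``coding_potential`` (optional, taken from any exon of the
    transcript). ``sequences`` optionally attaches transcript sequences by id
    for the ORF-based coding score.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    collected: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = feat.attributes["transcript_id"][0]
        entry = collected.setdefault(
            tid, {"chrom": feat.seqid, "strand": feat.strand, "exons": [], "attrs": {}}
        )
        entry["exons"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
        for key in ("transcript_biotype", "coding_potential"):
            if key in feat.attributes:
                entry["attrs"][key] = feat.attributes[key][0]
    transcripts = []
    for tid, entry in collected.items():
        cp = entry["attrs"].get("coding_potential")
        transcripts.append(
            LncTranscript(
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=entry["exons"],
                biotype=entry["attrs"].get("transcript_biotype"),
                coding_potential=float(cp) if cp is not None else None,
                sequence=(sequences or {}).get(tid),
            )
        )
    transcripts.sort(key=lambda t: t.transcript_id)
    return transcripts


def write_catalog_gtf(catalog: Iterable[LncTranscript], path: str | Path) -> None:
    """Write a catalog as GTF2.2 exon records with biotype ``lncRNA``."""
    with open(path, "w") as out:
        for t in catalog:
            for i, (s, e) in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}"; transcript_biotype "lncRNA";'
                )
                out.write(
                    f"{t.chrom}\tteconsex\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


@dataclass
class CatalogFilterResult:
    """Catalog plus per-step removal counts of the filtering cascade."""

    catalog: list[LncTranscript]
    counts: dict[str, int]


def build_lncrna_catalog(
    transcripts: Sequence[LncTranscript],
    biotype_blacklist: frozenset[str] | set[str] = DEFAULT_BIOTYPE_BLACKLIST,
    coding_potential_cutoff: float = DEFAULT_CODING_POTENTIAL_CUTOFF,
    scorer=orf_coding_score,
) -> CatalogFilterResult:
    """Apply the lncRNA filtering cascade and log per-step counts.

    Steps, in order: (1) blacklisted biotypes (a biotype ending in
    ``_pseudogene`` matches the ``pseudogene`` entry); (2) mono-exonic
    transcripts; (3) coding potential >= cutoff, scored from the
    ``coding_potential`` attribute or, failing that, from the attached
    sequence via ``scorer``. A transcript with neither score nor sequence
    cannot be cleared and is removed with a warning.
    """
    counts = {
        "input": len(transcripts),
        "removed_biotype": 0,
        "removed_mono_exonic": 0,
        "removed_coding_potential": 0,
        "removed_unscoreable": 0,
    }

    def blacklisted(biotype: str | None) -> bool:
        if biotype is None:
            return False
        return biotype in biotype_blacklist or (
            "pseudogene" in biotype_blacklist and biotype.endswith("_pseudogene")
        )

    stage = [t for t in transcripts if not blacklisted(t.biotype)]
    counts["removed_biotype"] = counts["input"] - len(stage)

    multi = [t for t in stage if len(t.exons) >= 2]
    counts["removed_mono_exonic"] = len(stage) - len(multi)

    catalog = []
    for t in multi:
        score = t.coding_potential
        if score is None and t.sequence:
            score = scorer(t.sequence)
            t.coding_potential = score
        if score is None:
            logger.warning(
                "%s: no coding-potential score or sequence; removed", t.transcript_id
            )
            counts["removed_unscoreable"] += 1
            continue
        if score >= coding_potential_cutoff:
            counts["removed_coding_potential"] += 1
            continue
        catalog.append(t)
    counts["retained"] = len(catalog)
    for step, n in counts.items():
        logger.info("lncRNA filter %s: %d", step, n)
    return CatalogFilterResult(catalog=catalog, counts=counts)


def _exon_trees(transcripts: Iterable[LncTranscript]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        key = (t.chrom, t.strand)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in t.exons:
            tree.addi(s, e, t.transcript_id)
    return trees


def reference_overlap(
    catalog: Sequence[LncTranscript], reference: Sequence[LncTranscript]
) -> float:
    """Fraction of catalog transcripts with same-strand exonic overlap (>=1 bp)
    with any reference transcript."""
    if not catalog:
        raise UndefinedStatisticError("empty catalog")
    ref_trees = _exon_trees(reference)
    hit = 0
    for t in catalog:
        tree = ref_trees.get((t.chrom, t.strand))
        if tree is not None and any(tree.overlap(s, e) for s, e in t.exons):
            hit += 1
    return hit / len(catalog)


def annotate_te_overlap(
    catalog: Sequence[LncTranscript],
    te_instances: Sequence[TEInstance],
    min_exon_fraction: float = 0.1,
) -> list[TEOverlapAnnotation]:
    """Record exon/TE intersections covering >= ``min_exon_fraction`` of the exon.

    The dominant TE of a transcript is the instance with the largest total
    overlap summed over exons; ties go to the larger single-exon overlap,
    then the lexicographically smaller family name.
    """
    trees = build_instance_tree(te_instances)
    annotations = []
    for t in catalog:
        ann = TEOverlapAnnotation(transcript_id=t.transcript_id)
        tree = trees.get(t.chrom)
        per_instance: dict[str, dict] = {}
        if tree is not None:
            for idx, (es, ee) in enumerate(t.exons):
                exon_len = ee - es
                for iv in tree.overlap(es, ee):
                    ov = min(ee, iv.end) - max(es, iv.begin)
                    if ov >= min_exon_fraction * exon_len:
                        inst: TEInstance = iv.data
                        ann.overlaps.append(
                            ExonTEOverlap(
                                te_instance_id=inst.instance_id,
                                family=inst.family,
                                te_class=inst.te_class,
                                exon_index=idx,
                                overlap_bp=ov,
                            )
                        )
                        agg = per_instance.setdefault(
                            inst.instance_id,
                            {"total": 0, "max_single": 0, "family": inst.family},
                        )
                        agg["total"] += ov
                        agg["max_single"] = max(agg["max_single"], ov)
        if per_instance:
            ranked = sorted(
                per_instance.items(),
                key=lambda kv: (-kv[1]["total"], -kv[1]["max_single"], kv[1]["family"], kv[0]),
            )
            best_id, best = ranked[0]
            ann.dominant_instance = best_id
            ann.dominant_family = best["family"]
        ann.overlaps.sort(key=lambda o: (o.exon_index, o.te_instance_id))
        annotations.append(ann)
    return annotations


@dataclass
class ContributionStats:
    """Per-class and per-family TE contribution tables.

    ``class_table``: each class's share of the exonic sequence of
    TE-overlapping lncRNAs next to its genomic share. ``family_table`` adds
    the normalized contribution (lncRNA share / genomic share) and, for
    families with more than ``min_family_size`` members, the per-instance
    frequency of being a transcript's dominant TE.
    """

    class_table: pd.DataFrame
    family_table: pd.DataFrame
    total_exonic_bp: int


def contribution_stats(
    annotations: Sequence[TEOverlapAnnotation],
    catalog: Sequence[LncTranscript],
    te_instances: Sequence[TEInstance],
    genome_length: int,
    allow_double_count: bool = False,
    min_family_size: int = 10,
) -> ContributionStats:
    """TE class/family contribution to the exonic sequence of lncRNAs.

    Only TE-overlapping transcripts enter the denominator. When TE
    annotations overlap each other inside one exon, each exon base is
    attributed to the instance with the longest local overlap so no base is
    counted twice; ``allow_double_count`` restores raw intersectBed-style
    summation for comparability with that tool.
    """
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    by_tid = {t.transcript_id: t for t in catalog}
    overlapping = [a for a in annotations if a.has_te]
    if not overlapping:
        raise UndefinedStatisticError("no TE-overlapping transcripts")
    total_exonic = sum(by_tid[a.transcript_id].exonic_length for a in overlapping)

    inst_by_id = {i.instance_id: i for i in te_instances}
    class_bp: dict[str, int] = {}
    family_bp: dict[str, int] = {}
    for ann in overlapping:
        t = by_tid[ann.transcript_id]
        for idx, (es, ee) in enumerate(t.exons):
            segs = []
            for ov in ann.overlaps:
                if ov.exon_index != idx:
                    continue
                inst = inst_by_id[ov.te_instance_id]
                a, b = max(es, inst.start), min(ee, inst.end)
                segs.append((b - a, ov.te_instance_id, a, b, ov.family, ov.te_class))
            if not segs:
                continue
            if allow_double_count:
                for length, _, _, _, fam, cls in segs:
                    class_bp[cls] = class_bp.get(cls, 0) + length
                    family_bp[fam] = family_bp.get(fam, 0) + length
            else:
                segs.sort(key=lambda x: (-x[0], x[1]))
                covered: list[tuple[int, int]] = []
                for _, _, a, b, fam, cls in segs:
                    pieces = [(a, b)]
                    for ca, cb in covered:
                        pieces = [
                            (pa, pb)
                            for seg in pieces
                            for pa, pb in _subtract(seg, (ca, cb))
                        ]
                    gained = sum(pb - pa for pa, pb in pieces)
                    if gained:
                        class_bp[cls] = class_bp.get(cls, 0) + gained
                        family_bp[fam] = family_bp.get(fam, 0) + gained
                    covered.append((a, b))

    genomic_class_bp: dict[str, int] = {}
    genomic_family_bp: dict[str, int] = {}
    family_size: dict[str, int] = {}
    family_class: dict[str, str] = {}
    for inst in te_instances:
        genomic_class_bp[inst.te_class] = genomic_class_bp.get(inst.te_class, 0) + inst.length_bp
        genomic_family_bp[inst.family] = genomic_family_bp.get(inst.family, 0) + inst.length_bp
        family_size[inst.family] = family_size.get(inst.family, 0) + 1
        family_class[inst.family] = inst.te_class

    dominant_counts: dict[str, int] = {}
    for ann in overlapping:
        if ann.dominant_family:
            dominant_counts[ann.dominant_family] = dominant_counts.get(ann.dominant_family, 0) + 1

    class_rows = [
        {
            "te_class": cls,
            "lncrna_bp": class_bp.get(cls, 0),
            "lncrna_proportion": class_bp.get(cls, 0) / total_exonic,
            "genomic_proportion": genomic_class_bp.get(cls, 0) / genome_length,
        }
        for cls in sorted(set(class_bp) | set(genomic_class_bp))
    ]
    family_rows = []
    for fam in sorted(set(family_bp) | set(genomic_family_bp)):
        lnc_prop = family_bp.get(fam, 0) / total_exonic
        gen_prop = genomic_family_bp.get(fam, 0) / genome_length
        size = family_size.get(fam, 0)
        family_rows.append(
            {
                "family": fam,
                "te_class": family_class.get(fam, ""),
                "lncrna_bp": family_bp.get(fam, 0),
                "lncrna_proportion": lnc_prop,
                "genomic_proportion": gen_prop,
                "normalized_contribution": (lnc_prop / gen_prop) if gen_prop > 0 else float("nan"),
                "family_size": size,
                "n_dominant_transcripts": dominant_counts.get(fam, 0),
                "dominant_frequency_per_instance": (
                    dominant_counts.get(fam, 0) / size if size > min_family_size else float("nan")
                ),
            }
        )
    return ContributionStats(
        class_table=pd.DataFrame(class_rows),
        family_table=pd.DataFrame(family_rows),
        total_exonic_bp=total_exonic,
    )


def _subtract(seg: tuple[int, int], cover: tuple[int, int]) -> list[tuple[int, int]]:
    """Interval difference seg \\ cover as a list of non-empty intervals."""
    a, b = seg
    ca, cb = cover
    out = []
    if a < min(b, ca):
        out.append((a, min(b, ca)))
    if max(a, cb) < b:
        out.append((max(a, cb), b))
    return out


def percent_of(count: int, denom: int) -> float:
    """Percentage rounded to 2 decimals (report convention)."""
    if denom <= 0:
        raise UndefinedStatisticError("percentage with zero denominator")
    return round(100.0 * count / denom, 2)


def format_count_pct(count: int, denom: int) -> str:
    return f"{count} ({percent_of(count, denom):.2f}%)"


@dataclass
class TargetReads:
    """Target-species read data: one interval list per replicate."""

    reads_per_replicate: list[list[tuple[str, int, int]]]
    library_sizes: list[int]


def lncrna_conservation(
    catalog: Sequence[LncTranscript],
    chains_by_target: Mapping[str, Sequence[Chain]],
    reads_by_target: Mapping[str, TargetReads],
    te_by_target: Mapping[str, Sequence[TEInstance]],
    min_match: float = 0.1,
    min_exon_fraction: float = 0.1,
    rpkm_cutoff: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Lift the catalog to each target species and tier transcripts.

    Per target: the whole transcript span is lifted as one interval
    (transcript-level conservation); exons are additionally lifted one by
    one to re-apply the >=10%-of-exon TE rule against the target's own TE
    annotation. Expression in the target is quantified over the lifted span
    (all-replicates RPKM rule). Percentages in the returned table are of
    the lifted count. Tiers: ``all_species`` = lifted and expressed in every
    target, ``some_nhp`` = in at least one, ``query_only`` otherwise.
    """
    from .expression_quant import count_overlapping_reads

    targets = list(chains_by_target)
    expressed_somewhere: dict[str, int] = {t.transcript_id: 0 for t in catalog}
    rows = []
    for target in targets:
        chains = chains_by_target[target]
        if target not in reads_by_target:
            logger.warning("no expression data for target %s; skipped", target)
            continue
        treads = reads_by_target[target]
        te_tree = build_instance_tree(te_by_target.get(target, []))

        lifted: list[tuple[LncTranscript, object]] = []
        for t in catalog:
            s, e = t.span
            res = lift_interval((t.chrom, s, e), chains, min_match)
            if res.mapped:
                lifted.append((t, res))
        features = [
            (t.transcript_id, r.target_chrom, r.target_start, r.target_end)
            for t, r in lifted
        ]
        counts_per_rep = [
            count_overlapping_reads(features, reads) for reads in treads.reads_per_replicate
        ]

        n_lifted = len(lifted)
        n_te = n_expr = n_expr_te = 0
        for t, res in lifted:
            has_te = False
            for es, ee in t.exons:
                eres = lift_interval((t.chrom, es, ee), chains, min_match)
                if not eres.mapped:
                    continue
                exon_len = eres.target_end - eres.target_start
                tree = te_tree.get(eres.target_chrom)
                if tree is None:
                    continue
                for iv in tree.overlap(eres.target_start, eres.target_end):
                    ov = min(eres.target_end, iv.end) - max(eres.target_start, iv.begin)
                    if ov >= min_exon_fraction * exon_len:
                        has_te = True
                        break
                if has_te:
                    break
            rec = ExpressionRecord(
                feature_id=t.transcript_id,
                length_bp=res.target_end - res.target_start,
                counts=tuple(c[t.transcript_id] for c in counts_per_rep),
                library_sizes=tuple(treads.library_sizes),
            )
            expressed = transcript_expressed(rec, rpkm_cutoff)
            n_te += has_te
            n_expr += expressed
            n_expr_te += expressed and has_te
            if expressed:
                expressed_somewhere[t.transcript_id] += 1
        rows.append(
            {
                "target": target,
                "catalog_size": len(catalog),
                "n_lifted": n_lifted,
                "n_lifted_te": n_te,
                "n_lifted_expressed": n_expr,
                "n_lifted_expressed_te": n_expr_te,
                "pct_lifted_te": percent_of(n_te, n_lifted) if n_lifted else float("nan"),
                "pct_lifted_expressed": percent_of(n_expr, n_lifted) if n_lifted else float("nan"),
                "pct_lifted_expressed_te": (
                    percent_of(n_expr_te, n_lifted) if n_lifted else float("nan")
                ),
            }
        )

    n_targets_used = len(rows)
    tiers = {}
    for t in catalog:
        hits = expressed_somewhere[t.transcript_id]
        if n_targets_used and hits == n_targets_used:
            tiers[t.transcript_id] = TIER_ALL_SPECIES
        elif hits >= 1:
            tiers[t.transcript_id] = TIER_SOME_NHP
        else:
            tiers[t.transcript_id] = TIER_QUERY_ONLY
    return pd.DataFrame(rows), tiers
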