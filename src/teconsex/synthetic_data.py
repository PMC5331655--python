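"""Multi-species synthetic dataset generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without any real genome: each species is a pure coordinate space
(no nucleotide sequence is needed downstream, except short synthetic
transcript sequences for the coding-potential score). The query species
carries TE instances from configurable families laid out along one
chromosome; each target species independently loses each instance with the
family's per-branch loss probability, so young families (high consensus
similarity) can be made poorly retained. Pairwise chain files relate the
coordinate spaces: retained instances sit inside aligned blocks (with
occasional small indels, exercising the minimum-remap-ratio rule) while
lost instances fall into source gaps. Expression is planted per instance:
a query flag with the family's expression probability, and a target flag
whose probability given query expression is the family's expression
correlation (setting the correlation equal to the marginal probability
yields independence — the null for enrichment calibration). Reads are
emitted as fixed-length BED intervals (one record = one counted fragment;
paired-end structure is not simulated) with Poisson count noise, enough to
guarantee RPKM >= 1 for planted-expressed features in every replicate, and
a filler region absorbs the remaining library so library sizes are exact.
Multi-exon transcripts are partially built from TE sequence with
class-level enrichment (LTR/LINE over-represented, SINE under-represented
among exapted instances), alongside planted decoys for the lncRNA filter
cascade (coding biotypes, mono-exonic transcripts, high-coding-potential
transcripts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .orthology_lift import Chain, ChainBlock, lift_interval, write_chains

CHROM = "chr1"
_BASES = np.array(list("ACGT"))
_STOP = "TAA"
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


@dataclass
class FamilySpec:
    """Parameters of one simulated TE family.

    ``mean_perc_div`` is the age surrogate (percent divergence from
    consensus); ``loss_prob_per_branch`` is the probability that a target
    species lost a given instance (independently per target), so making it
    decrease with age reproduces the young-families-are-less-conserved
    trend; ``expr_prob_query`` is the marginal probability an instance is
    expressed in the query species; ``expr_correlation`` is the probability
    that a retained, query-expressed instance is also expressed in a target
    (a retained, non-query-expressed instance is target-expressed with the
    marginal probability, so correlation == marginal means independence).
    """

    name: str
    te_class: str
    n_instances: int
    mean_perc_div: float
    loss_prob_per_branch: float
    expr_prob_query: float
    expr_correlation: float

    def validate(self) -> None:
        if self.te_class not in ("DNA", "LTR", "LINE", "SINE", "Other"):
            raise ConfigurationError("teClass", f"unknown class {self.te_class!r}")
        if self.n_instances < 0:
            raise ConfigurationError("nInstances", "must be >= 0")
        if not 0.0 <= self.mean_perc_div <= 100.0:
            raise ConfigurationError("meanPercDiv", "must be in [0, 100]")
        for attr, label in (
            ("loss_prob_per_branch", "lossProbPerBranch"),
            ("expr_prob_query", "exprProbQuery"),
            ("expr_correlation", "exprCorrelation"),
        ):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise ConfigurationError(label, "must be a probability in [0, 1]")


def default_families() -> list[FamilySpec]:
    """An age ladder of 8 families across the main classes.

    Loss probability increases as divergence decreases (young families less
    retained), expression marginals sized so family tables pass the
    >=30-expressed filter at these instance counts.
    """
    return [
        FamilySpec("L2-sim", "LINE", 300, 30.0, 0.03, 0.3, 0.40),
        FamilySpec("MIR-sim", "SINE", 300, 28.0, 0.04, 0.3, 0.40),
        FamilySpec("MLT1-sim", "LTR", 300, 22.0, 0.06, 0.3, 0.50),
        FamilySpec("Tigger-sim", "DNA", 300, 18.0, 0.08, 0.3, 0.50),
        FamilySpec("HERVH-sim", "LTR", 300, 12.0, 0.12, 0.3, 0.60),
        FamilySpec("L1M-sim", "LINE", 300, 10.0, 0.15, 0.3, 0.40),
        FamilySpec("AluY-sim", "SINE", 300, 4.0, 0.35, 0.3, 0.30),
        FamilySpec("SVA-sim", "Other", 200, 3.0, 0.40, 0.3, 0.30),
    ]


def planted_enrichment_families() -> list[FamilySpec]:
    """Ten families for planted-recovery benchmarks: expression correlation
    0.8 (strong conservation), 0.5 (moderate) and 0.05 (near-none), across
    classes and ages, 250-400 instances each."""
    return [
        FamilySpec("HI-LTR-a", "LTR", 300, 15.0, 0.08, 0.3, 0.8),
        FamilySpec("HI-LINE-a", "LINE", 350, 25.0, 0.05, 0.3, 0.8),
        FamilySpec("HI-DNA-a", "DNA", 250, 20.0, 0.06, 0.3, 0.8),
        FamilySpec("MID-LTR-b", "LTR", 300, 12.0, 0.10, 0.3, 0.5),
        FamilySpec("MID-SINE-b", "SINE", 400, 28.0, 0.05, 0.3, 0.5),
        FamilySpec("MID-DNA-b", "DNA", 300, 18.0, 0.08, 0.3, 0.5),
        FamilySpec("NULL-SINE-c", "SINE", 400, 5.0, 0.25, 0.3, 0.05),
        FamilySpec("NULL-LINE-c", "LINE", 300, 10.0, 0.15, 0.3, 0.05),
        FamilySpec("NULL-LTR-c", "LTR", 250, 8.0, 0.12, 0.3, 0.05),
        FamilySpec("NULL-DNA-c", "DNA", 300, 22.0, 0.06, 0.3, 0.05),
    ]


def planted_enrichment_config(seed: int) -> SimConfig:
    """4-species dataset with the planted-enrichment families."""
    return SimConfig(
        seed=seed,
        n_species=4,
        genome_length=7_000_000,
        families=planted_enrichment_families(),
        n_reads_per_replicate=150_000,
        lncrna_count=60,
        coding_gene_count=20,
    )


def null_calibration_config(seed: int, n_families: int = 200) -> SimConfig:
    """Independence dataset for p-value calibration: every family's target
    expression correlation equals its marginal expression probability."""
    return SimConfig(
        seed=seed,
        n_species=2,
        genome_length=80_000_000,
        families=[
            FamilySpec(f"NULL{i:03d}", "DNA", 250, 15.0, 0.1, 0.3, 0.3)
            for i in range(n_families)
        ],
        n_reads_per_replicate=150_000,
        replicates_per_species=[2, 1],
        lncrna_count=0,
        coding_gene_count=0,
        coding_overlap_fraction=0.0,
        te_overlap_fraction=0.0,
    )


def _default_replicates(n_species: int) -> list[int]:
    # study design: 3 query replicates, then 1/2/1 for the targets
    pattern = [3, 1, 2, 1]
    return [pattern[i] if i < len(pattern) else 1 for i in range(n_species)]


@dataclass
class SimConfig:
    """Full generator configuration; same seed means byte-identical output."""

    seed: int = 0
    n_species: int = 4
    genome_length: int = 6_000_000
    families: list[FamilySpec] = field(default_factory=default_families)
    n_reads_per_replicate: int = 300_000
    replicates_per_species: list[int] | None = None
    lncrna_count: int = 60
    coding_gene_count: int = 20
    # shape parameters
    read_length: int = 100
    expressed_rpkm: float = 20.0
    background_rpkm: float = 0.01
    instance_length_range: tuple[int, int] = (300, 900)
    spacer_length_range: tuple[int, int] = (500, 1200)
    fragmentation_prob: float = 0.1
    coding_overlap_fraction: float = 0.05
    te_overlap_fraction: float = 0.7
    mono_exonic_fraction: float = 0.15
    high_coding_fraction: float = 0.1
    lncrna_expr_conservation: float = 0.5
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"LTR": 3.0, "LINE": 2.5, "DNA": 1.0, "Other": 1.0, "SINE": 0.3}
    )

    def validate(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("nSpecies", "need at least 2 species")
        if self.genome_length <= 0:
            raise ConfigurationError("genomeLength", "must be positive")
        if self.n_reads_per_replicate < 0:
            raise ConfigurationError("nReadsPerReplicate", "must be >= 0")
        if self.lncrna_count < 0:
            raise ConfigurationError("lncrnaCount", "must be >= 0")
        if self.coding_gene_count < 0:
            raise ConfigurationError("codingGeneCount", "must be >= 0")
        if self.read_length <= 0:
            raise ConfigurationError("readLength", "must be positive")
        if not self.families:
            raise ConfigurationError("families", "need at least one family")
        for fam in self.families:
            fam.validate()
        reps = self.replicates()
        if len(reps) != self.n_species or any(r < 1 for r in reps):
            raise ConfigurationError(
                "replicatesPerSpecies", "need one count >= 1 per species"
            )
        lo, hi = self.instance_length_range
        if lo < 3 * self.read_length:
            raise ConfigurationError(
                "instanceLengthRange", "instances must be >= 3 read lengths"
            )
        slo, _ = self.spacer_length_range
        if slo < 450:
            raise ConfigurationError("spacerLengthRange", "minimum spacer must be >= 450")

    def replicates(self) -> list[int]:
        if self.replicates_per_species is not None:
            return list(self.replicates_per_species)
        return _default_replicates(self.n_species)

    def species_names(self) -> list[str]:
        return [f"species{i + 1}" for i in range(self.n_species)]


@dataclass
class _Instance:
    idx: int
    spec: FamilySpec
    length: int
    perc_div: float
    strand: str
    q_start: int = 0
    q_end: int = 0
    fragmented: bool = False
    coding_overlap: bool = False
    length_bp: int = 0
    query_id: str = ""


@dataclass
class _Transcript:
    tid: str
    category: str  # te_lnc | plain_lnc | mono | high_cp | coding
    exons: list[tuple[int, int]]
    biotype: str | None
    sequence: str
    te_idx: int | None = None


@dataclass
class GroundTruth:
    """Planted truth, keyed by query-species instance ids (``chr1:<id>``)."""

    species: list[str]
    query: str
    family: dict[str, tuple[str, str]]  # query_id -> (family, class)
    length_bp: dict[str, int]
    coding_overlap: dict[str, bool]
    retention: dict[str, dict[str, bool]]  # target -> query_id -> retained
    target_instance_id: dict[str, dict[str, str]]
    te_expression: dict[str, dict[str, bool]]  # species -> query_id -> expressed
    transcripts: dict[str, dict]
    library_sizes: dict[str, list[int]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(asdict(self), out, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as handle:
            data = json.load(handle)
        data["family"] = {k: tuple(v) for k, v in data["family"].items()}
        return cls(**data)


@dataclass
class SimulatedDataset:
    config: SimConfig
    out_dir: Path
    species: list[str]
    files: dict
    ground_truth: GroundTruth


def simulate_expression_counts(
    lengths: Sequence[int],
    expressed: Sequence[bool],
    config: SimConfig,
    n_replicates: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[int]]:
    """Per-replicate counts for features with the given expression flags.

    Expressed features draw Poisson counts at the planted RPKM, floored so
    that RPKM >= 1.2 is guaranteed in every replicate at the nominal library
    size; non-expressed features draw Poisson background counts whose
    expected RPKM is the (small) background rate. Library sizes are the
    nominal per-replicate read count (a filler region tops up emitted reads
    to exactly that).
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    expressed = np.asarray(expressed, dtype=bool)
    lib = config.n_reads_per_replicate
    if lib == 0:  # annotation-only datasets: no reads at all
        zero = np.zeros(len(lengths), dtype=np.int64)
        return [zero.copy() for _ in range(n_replicates)], [0] * n_replicates
    lam_expr = config.expressed_rpkm * lengths * lib / 1e9
    lam_bg = config.background_rpkm * lengths * lib / 1e9
    min_count = np.maximum(1, np.ceil(1.2 * lengths * lib / 1e9)).astype(np.int64)
    counts = []
    for _ in range(n_replicates):
        expr_counts = np.maximum(rng.poisson(lam_expr), min_count)
        bg_counts = rng.poisson(lam_bg)
        counts.append(np.where(expressed, expr_counts, bg_counts).astype(np.int64))
    return counts, [lib] * n_replicates


def _noncoding_sequence(rng: np.random.Generator, n: int) -> str:
    """Random sequence with stop codons planted every ~30 nt in rotating
    frames, capping any ORF well below typical coding-potential cutoffs."""
    seq = list(rng.choice(_BASES, size=n))
    k = 0
    pos = 0
    while pos + 3 <= n:
        p = pos + (k % 3)
        if p + 3 <= n:
            seq[p : p + 3] = list(_STOP)
        k += 1
        pos += 30
    return "".join(seq)


def _coding_sequence(rng: np.random.Generator, n: int) -> str:
    """ATG + non-stop codons + TAA filling the length: ORF fraction ~1."""
    n_codons = n // 3
    if n_codons < 3:
        return "ATG" + "A" * max(0, n - 3)
    body = list(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
    seq = "ATG" + "".join(body) + _STOP
    return seq + "A" * (n - len(seq))


def _emit_spacer(n: int, rng: np.random.Generator, emit: Callable[[str, int], None]) -> None:
    if n >= 60 and rng.random() < 0.5:
        g = int(rng.integers(1, 21))
        a = int(rng.integers(20, n - 40 + 1))
        if rng.random() < 0.5:  # insertion in the target
            emit("m", a)
            emit("t", g)
            emit("m", n - a)
            return
        if a + g <= n - 20:  # deletion in the target
            emit("m", a)
            emit("s", g)
            emit("m", n - a - g)
            return
    emit("m", n)


def _emit_instance(length: int, rng: np.random.Generator, emit: Callable[[str, int], None]) -> None:
    if length >= 200 and rng.random() < 0.3:
        g = int(rng.integers(1, min(20, length // 10) + 1))
        a = int(rng.integers(50, length - 50 - g + 1))
        if rng.random() < 0.5:
            emit("m", a)
            emit("t", g)
            emit("m", length - a)
        else:
            emit("m", a)
            emit("s", g)
            emit("m", length - a - g)
        return
    emit("m", length)


def _ops_to_chain(ops, source_size: int, target_size: int, chain_id: int) -> Chain:
    blocks: list[ChainBlock] = []
    m = s = t = 0
    for kind, n in ops:
        if kind == "m":
            if s or t:
                blocks.append(ChainBlock(m, s, t))
                m = s = t = 0
            m += n
        elif kind == "s":
            s += n
        else:
            t += n
    blocks.append(ChainBlock(m, s, t))
    aligned = sum(b.size for b in blocks)
    chain = Chain(
        chain_id=chain_id,
        score=aligned,
        source_chrom=CHROM,
        source_size=source_size,
        source_start=0,
        source_end=source_size,
        target_chrom=CHROM,
        target_size=target_size,
        target_strand="+",
        target_start=0,
        target_end=target_size,
        blocks=blocks,
    )
    chain.validate()
    return chain


_RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching "
    "repeat      position in repeat\n"
    "score   div. del. ins.  sequence  begin  end   (left)  repeat   "
    "class/family  begin  end  (left)  ID\n"
    "\n"
)


def _write_rm_out(path: Path, rows: list[tuple]) -> None:
    """rows: (sw, div, chrom, begin1, end, left, strand, family, class_family, rm_id)."""
    with open(path, "w") as out:
        out.write(_RM_HEADER)
        for sw, div, chrom, begin1, end, left, strand, family, cls_fam, rm_id in rows:
            out.write(
                f"{sw:>6} {div:>5.1f}  0.0  0.0  {chrom} {begin1:>8} {end:>8} "
                f"({left}) {strand} {family:<16} {cls_fam:<18} 1 100 (0) {rm_id}\n"
            )


def _write_reads_bed(path: Path, records: list[tuple[int, int]]) -> None:
    with open(path, "w") as out:
        for i, (start, end) in enumerate(records):
            out.write(f"{CHROM}\t{start}\t{end}\tr{i}\t0\t+\n")


def _write_gtf(path: Path, transcripts: list[tuple[_Transcript, list[tuple[int, int]]]]) -> None:
    with open(path, "w") as out:
        for t, exons in transcripts:
            for i, (s, e) in enumerate(exons, start=1):
                attrs = f'gene_id "{t.tid}"; transcript_id "{t.tid}"; exon_number "{i}";'
                if t.biotype:
                    attrs += f' transcript_biotype "{t.biotype}";'
                out.write(f"{CHROM}\tsim\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n")


def _write_fasta(path: Path, entries: list[tuple[str, str]]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=tid, description="") for tid, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> SimulatedDataset:
    """Generate the full multi-species dataset and write every output file.

    Outputs per species: RepeatMasker-dialect ``.out`` repeat table, coding
    BED, read BED per replicate, transcript GTF and transcript FASTA; per
    query/target pair a UCSC chain file; plus a JSON ground-truth manifest.
    Identical configs (including the seed) produce byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    for sub in ("chains", "reads", "transcripts"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    species = config.species_names()
    query, targets = species[0], species[1:]
    replicates = config.replicates()

    # --- instances along the query genome ------------------------------
    lo, hi = config.instance_length_range
    slo, shi = config.spacer_length_range
    instances: list[_Instance] = []
    for spec in config.families:
        for _ in range(spec.n_instances):
            instances.append(
                _Instance(
                    idx=0,
                    spec=spec,
                    length=int(rng.integers(lo, hi + 1)),
                    perc_div=float(
                        np.round(np.clip(rng.normal(spec.mean_perc_div, 2.0), 0.5, 60.0), 1)
                    ),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    order = rng.permutation(len(instances))
    instances = [instances[i] for i in order]
    for idx, inst in enumerate(instances):
        inst.idx = idx

    pos = 0
    for inst in instances:
        pos += int(rng.integers(slo, shi + 1))
        inst.q_start = pos
        inst.q_end = pos + inst.length
        pos = inst.q_end
    te_region_end = pos

    # fragmentation (nested-repeat style: two fragments share one ID)
    for inst in instances:
        inst.fragmented = inst.length >= 300 and rng.random() < config.fragmentation_prob
        inst.length_bp = inst.length - 30 if inst.fragmented else inst.length

    # planted coding overlaps
    for inst in instances:
        inst.coding_overlap = rng.random() < config.coding_overlap_fraction

    # --- gene region ----------------------------------------------------
    cursor = te_region_end + 2000
    transcripts: list[_Transcript] = []
    coding_gene_exons: list[tuple[int, int]] = []

    for k in range(config.coding_gene_count):
        exons = [(cursor, cursor + 300), (cursor + 500, cursor + 800)]
        coding_gene_exons.extend(exons)
        n = sum(e - s for s, e in exons)
        transcripts.append(
            _Transcript(
                tid=f"CDG_{k:04d}",
                category="coding",
                exons=exons,
                biotype="protein_coding",
                sequence=_coding_sequence(rng, n),
            )
        )
        cursor += 1100

    n_te_lnc = round(config.te_overlap_fraction * config.lncrna_count)
    n_plain = config.lncrna_count - n_te_lnc
    n_mono = round(config.mono_exonic_fraction * config.lncrna_count)
    n_high = round(config.high_coding_fraction * config.lncrna_count)

    eligible = []
    weights = []
    for i, inst in enumerate(instances):
        next_start = instances[i + 1].q_start if i + 1 < len(instances) else te_region_end + 2000
        gap_after = next_start - inst.q_end
        if not inst.coding_overlap and inst.length >= 300 and gap_after >= 450 and inst.q_start >= 60:
            eligible.append(inst.idx)
            weights.append(config.class_weights.get(inst.spec.te_class, 1.0))
    if n_te_lnc > len(eligible):
        raise ConfigurationError(
            "lncrnaCount", f"only {len(eligible)} TE instances eligible for lncRNA overlap"
        )
    w = np.asarray(weights, dtype=float)
    chosen = rng.choice(len(eligible), size=n_te_lnc, replace=False, p=w / w.sum())
    chosen_idx = sorted(int(eligible[c]) for c in chosen)
    for k, idx in enumerate(chosen_idx):
        inst = instances[idx]
        s, e = inst.q_start, inst.q_end
        exons = [(s - 40, s + 160), (e + 50, e + 200)]
        if int(rng.integers(0, 2)) == 1:
            exons.append((e + 260, e + 410))
        n = sum(b - a for a, b in exons)
        transcripts.append(
            _Transcript(
                tid=f"LNCTE_{k:04d}",
                category="te_lnc",
                exons=exons,
                biotype=None,
                sequence=_noncoding_sequence(rng, n),
                te_idx=idx,
            )
        )
    for k in range(n_plain):
        exons = [(cursor, cursor + 250), (cursor + 400, cursor + 650)]
        transcripts.append(
            _Transcript(
                tid=f"LNCPL_{k:04d}",
                category="plain_lnc",
                exons=exons,
                biotype=None,
                sequence=_noncoding_sequence(rng, 500),
            )
        )
        cursor += 900
    for k in range(n_mono):
        transcripts.append(
            _Transcript(
                tid=f"MONO_{k:04d}",
                category="mono",
                exons=[(cursor, cursor + 400)],
                biotype=None,
                sequence=_noncoding_sequence(rng, 400),
            )
        )
        cursor += 600
    for k in range(n_high):
        exons = [(cursor, cursor + 250), (cursor + 400, cursor + 650)]
        transcripts.append(
            _Transcript(
                tid=f"HCP_{k:04d}",
                category="high_cp",
                exons=exons,
                biotype=None,
                sequence=_coding_sequence(rng, 500),
            )
        )
        cursor += 900

    filler_start = cursor + 1000
    if filler_start + 10_000 + config.read_length > config.genome_length:
        raise ConfigurationError(
            "genomeLength",
            f"layout needs at least {filler_start + 10_000 + config.read_length} bp",
        )

    # --- retention and target coordinate spaces -------------------------
    retention: dict[str, np.ndarray] = {}
    chains: dict[str, Chain] = {}
    t_coords: dict[str, dict[int, tuple[int, int]]] = {}
    t_sizes: dict[str, int] = {}
    for t_i, target in enumerate(targets):
        retained = np.array([rng.random() >= inst.spec.loss_prob_per_branch for inst in instances])
        retention[target] = retained
        ops: list[tuple[str, int]] = []
        coords: dict[int, tuple[int, int]] = {}
        t_cursor = 0

        def emit(kind: str, n: int) -> None:
            nonlocal t_cursor
            if n <= 0:
                return
            ops.append((kind, n))
            if kind in ("m", "t"):
                t_cursor += n

        prev_end = 0
        for inst in instances:
            _emit_spacer(inst.q_start - prev_end, rng, emit)
            if retained[inst.idx]:
                ts = t_cursor
                _emit_instance(inst.length, rng, emit)
                coords[inst.idx] = (ts, t_cursor)
            else:
                emit("s", inst.length)
            prev_end = inst.q_end
        emit("m", config.genome_length - prev_end)  # gene + filler region, fully aligned
        chain = _ops_to_chain(ops, config.genome_length, t_cursor, chain_id=t_i + 1)
        chains[target] = chain
        t_coords[target] = coords
        t_sizes[target] = t_cursor

    # --- expression flags ------------------------------------------------
    expr_query = np.array([rng.random() < inst.spec.expr_prob_query for inst in instances])
    expr_target: dict[str, np.ndarray] = {}
    for target in targets:
        draws = rng.random(len(instances))
        probs = np.array(
            [
                inst.spec.expr_correlation if expr_query[inst.idx] else inst.spec.expr_prob_query
                for inst in instances
            ]
        )
        expr_target[target] = retention[target] & (draws < probs)

    tx_expr: dict[str, dict[str, bool]] = {sp: {} for sp in species}
    for t in transcripts:
        if t.category == "coding":
            for sp in species:
                tx_expr[sp][t.tid] = True
        elif t.category == "te_lnc":
            tx_expr[query][t.tid] = bool(expr_query[t.te_idx])
            for target in targets:
                tx_expr[target][t.tid] = bool(expr_target[target][t.te_idx])
        else:
            tx_expr[query][t.tid] = True
            for target in targets:
                tx_expr[target][t.tid] = rng.random() < config.lncrna_expr_conservation

    # --- per-species annotation files -----------------------------------
    files: dict = {
        "repeats": {},
        "coding": {},
        "reads": {sp: [] for sp in species},
        "gtf": {},
        "fasta": {},
        "chains": {},
        "ground_truth": str(out_dir / "ground_truth.json"),
    }

    # query repeat table (instances already in coordinate order)
    rm_rows = []
    for inst in instances:
        rm_id = inst.idx + 1
        inst.query_id = f"{CHROM}:{rm_id}"
        strand = "+" if inst.strand == "+" else "C"
        cls_fam = f"{inst.spec.te_class}/{inst.spec.name}"
        left = config.genome_length - inst.q_end
        sw = 10 * inst.length
        if inst.fragmented:
            half = (inst.length - 30) // 2
            b1_end = inst.q_start + half
            b2_start = b1_end + 30
            rm_rows.append(
                (sw, inst.perc_div, CHROM, inst.q_start + 1, b1_end, left, strand,
                 inst.spec.name, cls_fam, rm_id)
            )
            rm_rows.append(
                (sw, inst.perc_div, CHROM, b2_start + 1, inst.q_end, left, strand,
                 inst.spec.name, cls_fam, rm_id)
            )
        else:
            rm_rows.append(
                (sw, inst.perc_div, CHROM, inst.q_start + 1, inst.q_end, left, strand,
                 inst.spec.name, cls_fam, rm_id)
            )
    path = out_dir / f"{query}.rm.out"
    _write_rm_out(path, rm_rows)
    files["repeats"][query] = str(path)

    target_ids: dict[str, dict[str, str]] = {}
    for target in targets:
        rows = []
        ids: dict[str, str] = {}
        retained_insts = [i for i in instances if retention[target][i.idx]]
        retained_insts.sort(key=lambda i: t_coords[target][i.idx][0])
        for rank, inst in enumerate(retained_insts, start=1):
            ts, te = t_coords[target][inst.idx]
            ids[inst.query_id] = f"{CHROM}:{rank}"
            div = float(np.round(np.clip(rng.normal(inst.spec.mean_perc_div, 2.0), 0.5, 60.0), 1))
            rows.append(
                (10 * (te - ts), div, CHROM, ts + 1, te, t_sizes[target] - te,
                 "+" if inst.strand == "+" else "C",
                 inst.spec.name, f"{inst.spec.te_class}/{inst.spec.name}", rank)
            )
        path = out_dir / f"{target}.rm.out"
        _write_rm_out(path, rows)
        files["repeats"][target] = str(path)
        target_ids[target] = ids

    # chains
    for target in targets:
        path = out_dir / "chains" / f"{query}.to.{target}.chain"
        write_chains([chains[target]], path)
        files["chains"][target] = str(path)

    # coding BED per species: coding-gene exons plus planted intra-TE intervals
    def _coding_intervals_query() -> list[tuple[int, int]]:
        out = list(coding_gene_exons)
        for inst in instances:
            if inst.coding_overlap:
                mid = (inst.q_start + inst.q_end) // 2
                out.append((mid - 25, mid + 25))
        return sorted(out)

    query_coding = _coding_intervals_query()
    path = out_dir / f"{query}.coding.bed"
    with open(path, "w") as out:
        for s, e in query_coding:
            out.write(f"{CHROM}\t{s}\t{e}\n")
    files["coding"][query] = str(path)
    for target in targets:
        intervals = []
        for s, e in coding_gene_exons:
            res = lift_interval((CHROM, s, e), [chains[target]], 0.1)
            intervals.append((res.target_start, res.target_end))
        for inst in instances:
            if inst.coding_overlap and retention[target][inst.idx]:
                ts, te = t_coords[target][inst.idx]
                mid = (ts + te) // 2
                intervals.append((mid - 25, mid + 25))
        path = out_dir / f"{target}.coding.bed"
        with open(path, "w") as out:
            for s, e in sorted(intervals):
                out.write(f"{CHROM}\t{s}\t{e}\n")
        files["coding"][target] = str(path)

    # transcript models per species
    tx_by_species: dict[str, list[tuple[_Transcript, list[tuple[int, int]]]]] = {
        query: [(t, t.exons) for t in transcripts]
    }
    for target in targets:
        rows = []
        for t in transcripts:
            if t.category == "te_lnc" and not retention[target][t.te_idx]:
                continue
            exons = []
            ok = True
            for s, e in t.exons:
                res = lift_interval((CHROM, s, e), [chains[target]], 0.1)
                if not res.mapped:
                    ok = False
                    break
                exons.append((res.target_start, res.target_end))
            if ok:
                rows.append((t, exons))
        tx_by_species[target] = rows
    for sp in species:
        path = out_dir / "transcripts" / f"{sp}.gtf"
        _write_gtf(path, tx_by_species[sp])
        files["gtf"][sp] = str(path)
        path = out_dir / "transcripts" / f"{sp}.fa"
        _write_fasta(path, [(t.tid, t.sequence) for t, _ in tx_by_species[sp]])
        files["fasta"][sp] = str(path)

    # --- reads ------------------------------------------------------------
    library_sizes: dict[str, list[int]] = {}
    for sp_i, sp in enumerate(species):
        if sp == query:
            te_feats = [
                (inst.q_start, inst.q_end, inst.length_bp, bool(expr_query[inst.idx]))
                for inst in instances
            ]
            genome_size = config.genome_length
            filler_lo = filler_start
        else:
            te_feats = [
                (*t_coords[sp][inst.idx],
                 t_coords[sp][inst.idx][1] - t_coords[sp][inst.idx][0],
                 bool(expr_target[sp][inst.idx]))
                for inst in instances
                if retention[sp][inst.idx]
            ]
            genome_size = t_sizes[sp]
            filler_lo = genome_size - (config.genome_length - filler_start)
        tx_feats = [
            (t, exons, bool(tx_expr[sp][t.tid])) for t, exons in tx_by_species[sp]
        ]
        lengths = [f[2] for f in te_feats] + [sum(e - s for s, e in ex) for _, ex, _ in tx_feats]
        flags = [f[3] for f in te_feats] + [f[2] for f in tx_feats]
        counts, libs = simulate_expression_counts(
            lengths, flags, config, replicates[sp_i], rng
        )
        library_sizes[sp] = libs
        rl = config.read_length
        for rep in range(replicates[sp_i]):
            records: list[tuple[int, int]] = []
            vec = counts[rep]
            for j, (s, e, _, _) in enumerate(te_feats):
                c = int(vec[j])
                if c == 0:
                    continue
                hi_start = max(s + 1, e - rl)
                starts = rng.integers(s, hi_start + 1, size=c)
                records.extend((int(a), min(int(a) + rl, e)) for a in starts)
            off = len(te_feats)
            for j, (t, exons, _) in enumerate(tx_feats):
                c = int(vec[off + j])
                if c == 0:
                    continue
                lens = np.array([e - s for s, e in exons], dtype=float)
                picks = rng.choice(len(exons), size=c, p=lens / lens.sum())
                for p in picks:
                    es, ee = exons[int(p)]
                    if ee - es <= rl:
                        records.append((es, ee))
                    else:
                        a = int(rng.integers(es, ee - rl + 1))
                        records.append((a, a + rl))
            n_filler = config.n_reads_per_replicate - len(records)
            if n_filler < 0:
                raise ConfigurationError(
                    "nReadsPerReplicate",
                    f"library size {config.n_reads_per_replicate} smaller than "
                    f"{len(records)} planted reads",
                )
            starts = rng.integers(filler_lo, genome_size - rl + 1, size=n_filler)
            records.extend((int(a), int(a) + rl) for a in starts)
            path = out_dir / "reads" / f"{sp}.rep{rep + 1}.bed"
            _write_reads_bed(path, records)
            files["reads"][sp].append(str(path))

    # --- ground truth -----------------------------------------------------
    tiers = {}
    for t in transcripts:
        if t.category not in ("te_lnc", "plain_lnc"):
            continue
        hits = sum(tx_expr[target][t.tid] for target in targets)
        if targets and hits == len(targets):
            tiers[t.tid] = "all_species"
        elif hits >= 1:
            tiers[t.tid] = "some_nhp"
        else:
            tiers[t.tid] = "query_only"
    gt = GroundTruth(
        species=species,
        query=query,
        family={i.query_id: (i.spec.name, i.spec.te_class) for i in instances},
        length_bp={i.query_id: i.length_bp for i in instances},
        coding_overlap={i.query_id: bool(i.coding_overlap) for i in instances},
        retention={
            target: {i.query_id: bool(retention[target][i.idx]) for i in instances}
            for target in targets
        },
        target_instance_id=target_ids,
        te_expression={
            query: {i.query_id: bool(expr_query[i.idx]) for i in instances},
            **{
                target: {i.query_id: bool(expr_target[target][i.idx]) for i in instances}
                for target in targets
            },
        },
        transcripts={
            t.tid: {
                "category": t.category,
                "te_instance": instances[t.te_idx].query_id if t.te_idx is not None else None,
                "te_family": instances[t.te_idx].spec.name if t.te_idx is not None else None,
                "expressed": {sp: bool(tx_expr[sp].get(t.tid, False)) for sp in species},
                "tier": tiers.get(t.tid),
            }
            for t in transcripts
        },
        library_sizes=library_sizes,
    )
    gt.to_json(files["ground_truth"])

    return SimulatedDataset(
        config=config,
        out_dir=out_dir,
        species=species,
        files=files,
        ground_truth=gt,
    )
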