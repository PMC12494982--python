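"""Synthetic transposon-insertion library generator.

Produces genomes, annotations, and serial-passage insertion samples for two
library designs (P: promoter-carrying, T: terminator-carrying) with the
statistical structure the downstream analysis assumes: four essentiality
classes with distinct insertion densities, per-class read survival across
passages, overdispersed read counts, shared passage-1 pools thinned into
replicates, planted genomic repeats, and a P-library retention bias upstream
of essential genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotationSet, Feature, Genome, revcomp
from .insertions import InsertionSample

CLASSES = ("E", "F1", "F2", "NE")

DEFAULT_DENSITY_P1 = {"E": 0.01, "F1": 0.15, "F2": 0.45, "NE": 0.92}
DEFAULT_DECAY_RATE = {"E": 0.05, "F1": 0.3, "F2": 0.7, "NE": 0.97}


@dataclass
class SimConfig:
    genome_length: int = 100_000
    n_genes: int = 100
    class_fractions: dict = field(
        default_factory=lambda: {"E": 0.25, "F1": 0.25, "F2": 0.25, "NE": 0.25}
    )
    density_p1: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY_P1))
    decay_rate: dict = field(default_factory=lambda: dict(DEFAULT_DECAY_RATE))
    read_dispersion: float = 0.5  # NB shape; smaller = more overdispersed
    mean_reads: float = 60.0
    termini_frac: float = 0.02
    n_repeats: int = 0
    repeat_k: int = 21
    p_regulatory_bias: float = 0.5
    upstream_bias_window: int = 100
    replicate_keep: float = 0.9
    intergenic_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if set(self.class_fractions) != set(CLASSES):
            raise ValueError(f"class_fractions must cover exactly {CLASSES}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        for name, d in (("class_fractions", self.class_fractions),
                        ("density_p1", self.density_p1),
                        ("decay_rate", self.decay_rate)):
            for cls, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{cls}]={v} outside [0,1]")
        for name in ("termini_frac", "p_regulatory_bias", "replicate_keep",
                     "intergenic_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.n_repeats < 0:
            raise ValueError("n_repeats must be >= 0")


@dataclass
class PlantedRepeat:
    """Ground truth for one planted duplicated k-mer (1-based start positions)."""

    source_start: int
    copy_start: int
    k: int
    reverse_complement: bool


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def generate_genome(cfg: SimConfig) -> tuple[Genome, list[PlantedRepeat]]:
    """Random A/C/G/T genome with ``cfg.n_repeats`` duplicated k-mers planted.

    Every other planted copy is inserted as the reverse complement of its
    source. Returns the genome and the ground-truth plant records.
    """
    k = cfg.repeat_k
    if cfg.n_repeats > 0 and cfg.genome_length < (2 * cfg.n_repeats + 1) * 2 * k:
        raise ValueError("genome too small to host the requested repeats")
    rng = _rng(cfg, 1)
    seq = rng.choice(list("ACGT"), size=cfg.genome_length)
    seq = "".join(seq)

    plants: list[PlantedRepeat] = []
    if cfg.n_repeats:
        # non-overlapping slots, 2 per repeat, spread over the genome
        n_slots = 2 * cfg.n_repeats
        slot_span = cfg.genome_length // n_slots
        chars = list(seq)
        for r in range(cfg.n_repeats):
            src = 2 * r * slot_span + slot_span // 4
            dst = (2 * r + 1) * slot_span + slot_span // 4
            motif = "".join(rng.choice(list("ACGT"), size=k))
            rc = bool(r % 2)
            copy = revcomp(motif) if rc else motif
            chars[src : src + k] = motif
            chars[dst : dst + k] = copy
            plants.append(PlantedRepeat(src + 1, dst + 1, k, rc))
        seq = "".join(chars)
    return Genome(id=f"sim_{cfg.seed}", sequence=seq), plants


def generate_annotation(cfg: SimConfig, genome: Genome) -> AnnotationSet:
    """Tile non-overlapping genes with gaps and assign true classes.

    Class labels live on a ``true_class`` attribute of each gene feature.
    All NE genes are flagged gold-NE (at least 20 are required downstream;
    configurations with too few NE genes simply flag what they have). A
    rotating subset of inter-genic gaps is labeled iGiO / UTR5 / UTR3 /
    promoter / TTS.
    """
    rng = _rng(cfg, 2)
    n = cfg.n_genes
    # largest-remainder apportionment of class counts
    quotas = {c: cfg.class_fractions[c] * n for c in CLASSES}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    rest = n - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: quotas[c] - counts[c], reverse=True)[:rest]:
        counts[c] += 1
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng.shuffle(labels)

    span = cfg.genome_length // n
    gap = max(2, int(span * cfg.intergenic_frac))
    gene_len = span - gap
    if gene_len < 30:
        raise ValueError("genome too short for the requested gene count")

    annot = AnnotationSet()
    for i, cls in enumerate(labels):
        start = i * span + gap // 2 + 1
        end = start + gene_len - 1
        strand = "+" if rng.random() < 0.5 else "-"
        g = Feature(
            id=f"g{i:04d}", ftype="gene", start=start, end=end, strand=strand,
            operon_id=f"op{i // 4:04d}",
            cog=chr(ord("A") + (i % 8)),
            gold_ne=(cls == "NE"),
        )
        g.true_class = cls
        annot.add(g)

    # label a rotating subset of the inter-genic gaps as regulatory elements
    reg_cycle = ("iGiO", "UTR5", "UTR3", "promoter", "TTS")
    genes = sorted(annot.genes, key=lambda f: f.start)
    for j, (a, b) in enumerate(zip(genes, genes[1:])):
        if b.start - a.end < 3:
            continue
        ftype = reg_cycle[j % len(reg_cycle)]
        start, end = a.end + 1, b.start - 1
        f = Feature(
            id=f"{ftype}_{j:04d}", ftype=ftype, start=start, end=end,
            strand=b.strand, operon_id=a.operon_id if ftype == "iGiO" else None,
        )
        f.true_class = None
        annot.add(f)
    return annot


def _class_arrays(cfg: SimConfig, genome: Genome, annot: AnnotationSet):
    """Per-base insertion probability and decay rate arrays (0-based index)."""
    n = genome.length
    density = np.full(n, cfg.density_p1["NE"])  # intergenic behaves as NE
    decay = np.full(n, cfg.decay_rate["NE"])
    for g in annot.genes:
        cls = getattr(g, "true_class", None) or "NE"
        s, e = g.start - 1, g.end  # 0-based half-open
        if cls == "E":
            # body is uninsertable; only the termini accept insertions
            t = max(1, int(round(g.length * cfg.termini_frac)))
            density[s:e] = 0.0
            density[s : s + t] = cfg.density_p1["E"]
            density[e - t : e] = cfg.density_p1["E"]
            decay[s:e] = cfg.decay_rate["E"]
        else:
            density[s:e] = cfg.density_p1[cls]
            decay[s:e] = cfg.decay_rate[cls]
    return density, decay


def _upstream_bias_mask(cfg: SimConfig, genome: Genome, annot: AnnotationSet):
    """Boolean mask of bases upstream of E genes subject to the P-library bias."""
    mask = np.zeros(genome.length, dtype=bool)
    for g in annot.genes:
        if getattr(g, "true_class", None) != "E":
            continue
        if g.strand == "-":
            s, e = g.end + 1, min(g.end + cfg.upstream_bias_window, genome.length)
        else:
            s, e = max(1, g.start - cfg.upstream_bias_window), g.start - 1
        if e >= s:
            mask[s - 1 : e] = True
    return mask


def simulate_library(
    cfg: SimConfig,
    genome: Genome,
    annot: AnnotationSet,
    library: str,
    passages: list[int],
    replicates: int = 2,
) -> list[InsertionSample]:
    """Simulate one library across passages and replicates.

    A shared passage-1 insertion pool is drawn per library; replicates are
    independent thinnings of that pool, and each surviving insertion carries a
    latent survival variate so that presence is monotone across passages
    within a replicate (an insertion lost at passage p stays lost at p+1).
    P-library insertions upstream of E genes decay more slowly, scaled by
    ``p_regulatory_bias``; the T library gets no such rescue.
    """
    if not passages:
        raise ValueError("empty passage list")
    if any(p < 1 or p > 10 for p in passages):
        raise ValueError("passages must be within 1..10")
    if library not in ("P", "T"):
        raise ValueError("library must be 'P' or 'T'")

    density, decay = _class_arrays(cfg, genome, annot)
    bias_mask = _upstream_bias_mask(cfg, genome, annot)

    lib_code = 0 if library == "P" else 1
    rng_pool = _rng(cfg, 3, lib_code)
    pool = np.nonzero(rng_pool.random(genome.length) < density)[0]  # 0-based

    eff_decay = decay[pool].copy()
    if library == "P":
        boosted = np.minimum(1.0, eff_decay[bias_mask[pool]] * (1.0 + cfg.p_regulatory_bias))
        eff_decay[bias_mask[pool]] = boosted

    samples = []
    shape = cfg.read_dispersion
    for rep in range(1, replicates + 1):
        rng = _rng(cfg, 4, lib_code, rep)
        keep = rng.random(pool.size) < cfg.replicate_keep
        u = rng.random(pool.size)  # latent survival variate per insertion
        for p in sorted(passages):
            surv = eff_decay ** (p - 1)
            alive = keep & (u < surv)
            positions = pool[alive] + 1
            # reads >= 2: floor + overdispersed gamma-poisson remainder;
            # seeded per passage so results do not depend on the passage list
            rng_p = _rng(cfg, 5, lib_code, rep, p)
            mean_extra = max(cfg.mean_reads - 2.0, 0.1)
            lam = rng_p.gamma(shape, mean_extra / shape, size=positions.size)
            reads = 2 + rng_p.poisson(lam)
            samples.append(
                InsertionSample(
                    library=library, passage=p, replicate=rep,
                    counts=dict(zip(positions.tolist(), reads.tolist())),
                )
            )
    return samples


def emit_reads(
    sample: InsertionSample,
    genome: Genome,
    ir_tag: str = "TACGGACTTTATC",
    read_length: int = 50,
    end_policy: str = "truncate",
) -> list[tuple[str, str]]:
    """Expand a sample into (read_id, sequence) pairs: IR tag + genomic suffix.

    One read per counted read at each insertion. The genomic part starts at
    the insertion position. Insertions too close to the genome end are
    truncated (``end_policy="truncate"``) or wrapped around a circular genome
    (``end_policy="wrap"``).
    """
    anchor_len = read_length - len(ir_tag)
    if anchor_len <= 20:
        raise ValueError("read_length must exceed the IR tag length by > 20")
    if end_policy not in ("truncate", "wrap"):
        raise ValueError(f"unknown end_policy {end_policy!r}")
    reads = []
    seq = genome.sequence
    n = genome.length
    for pos in sorted(sample.counts):
        suffix = seq[pos - 1 : pos - 1 + anchor_len]
        if len(suffix) < anchor_len and end_policy == "wrap":
            suffix = suffix + seq[: anchor_len - len(suffix)]
        for i in range(sample.counts[pos]):
            reads.append((f"ins{pos}_{i}", ir_tag + suffix))
    return reads


def write_fastq(reads: list[tuple[str, str]], path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


def write_class_sidecar(annot: AnnotationSet, path) -> None:
    """TSV sidecar with per-feature class/COG/gold-NE metadata."""
    with open(path, "w") as fh:
        fh.write("feature_id\tftype\ttrue_class\tcog\tgold_ne\n")
        for f in annot:
            cls = getattr(f, "true_class", None) or ""
            fh.write(f"{f.id}\t{f.ftype}\t{cls}\t{f.cog or ''}\t{int(f.gold_ne)}\n")
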