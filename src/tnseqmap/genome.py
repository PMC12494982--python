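"""Genome, repeat mask, and annotation data model.

Coordinates are 1-based closed intervals everywhere (GFF3 convention).
Insertion positions are 1-based genome coordinates. BED export converts
explicitly to 0-based half-open.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = set("ACGTN")

FEATURE_TYPES = frozenset(
    {
        "gene",
        "tRNA",
        "rRNA",
        "ncRNA",
        "promoter",
        "TSS",
        "TTS",
        "UTR5",
        "UTR3",
        "iGiO",
        "RBS",
        "binding_site",
        "noann",
        "noexp",
    }
)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Genome:
    """A single-contig genome sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise ValueError(f"invalid characters in genome sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based closed interval slice."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"interval [{start},{end}] outside genome of length {self.length}")
        return self.sequence[start - 1 : end]


@dataclass
class RepeatMask:
    """Per-base boolean repeat flags, index 0 of ``flags`` is genome position 1."""

    flags: np.ndarray
    k: int = 21

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_repeated(self) -> int:
        return int(self.flags.sum())

    def __len__(self) -> int:
        return len(self.flags)


def compute_repeat_mask(
    genome: Genome,
    k: int = 21,
    policy: str = "cover",
    include_revcomp_self: bool = True,
) -> RepeatMask:
    """Label genome positions whose k-mer context is non-unique.

    A window is repeated when its sequence occurs at least twice across the
    forward genome plus its reverse complement. ``policy`` controls labeling:
    ``"cover"`` flags every base covered by a repeated window, ``"start"``
    flags only the window start position.

    ``include_revcomp_self`` counts a window's own reverse-complement
    occurrence (only relevant for even ``k`` where a window can be its own
    reverse complement).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > genome.length:
        raise ValueError(f"k={k} exceeds genome length {genome.length}")
    if policy not in ("cover", "start"):
        raise ValueError(f"unknown repeat labeling policy: {policy!r}")

    seq = genome.sequence
    n = genome.length
    counts: Counter[str] = Counter(seq[i : i + k] for i in range(n - k + 1))
    rcseq = revcomp(seq)  # rc of window starting at i is rcseq[n-i-k : n-i]

    flags = np.zeros(n, dtype=bool)
    for i in range(n - k + 1):
        w = seq[i : i + k]
        rc = rcseq[n - i - k : n - i]
        occ = counts[w]
        if rc != w:
            occ += counts[rc]
        elif include_revcomp_self:
            occ += counts[w]
        if occ >= 2:
            if policy == "cover":
                flags[i : i + k] = True
            else:
                flags[i] = True
    return RepeatMask(flags=flags, k=k)


@dataclass
class Feature:
    id: str
    ftype: str
    start: int
    end: int
    strand: str = "."
    operon_id: Optional[str] = None
    cog: Optional[str] = None
    gold_ne: bool = False
    pct_repeated: float = 0.0

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates for {self.id}: [{self.start},{self.end}]")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


class AnnotationSet:
    """A collection of features indexed by id, with interval queries."""

    def __init__(self, features: Iterable[Feature] = ()):
        self._features: list[Feature] = []
        self._by_id: dict[str, Feature] = {}
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        if feature.id in self._by_id:
            raise ValueError(f"duplicate feature id {feature.id!r}")
        self._by_id[feature.id] = feature
        self._features.append(feature)
        self._sorted_cache: Optional[tuple] = None

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self._features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def of_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self._features if f.ftype in ftypes]

    @property
    def genes(self) -> list[Feature]:
        return self.of_type("gene", "tRNA", "rRNA", "ncRNA")

    def _sorted(self):
        cache = getattr(self, "_sorted_cache", None)
        if cache is None:
            feats = sorted(self._features, key=lambda f: f.start)
            starts = [f.start for f in feats]
            maxend = 0
            maxends = []
            for f in feats:
                maxend = max(maxend, f.end)
                maxends.append(maxend)
            cache = (feats, starts, maxends)
            self._sorted_cache = cache
        return cache

    def overlapping(self, start: int, end: int) -> list[Feature]:
        """All features intersecting the 1-based closed interval [start, end]."""
        feats, starts, maxends = self._sorted()
        hi = bisect.bisect_right(starts, end)
        out = []
        for i in range(hi - 1, -1, -1):
            if maxends[i] < start:
                break
            if feats[i].end >= start:
                out.append(feats[i])
        out.reverse()
        return out


def pct_repeated(feature: Feature, mask: RepeatMask) -> float:
    """Fraction of a feature's bases flagged as repeated."""
    if feature.end > len(mask):
        raise ValueError(f"feature {feature.id} extends beyond the mask")
    window = mask.flags[feature.start - 1 : feature.end]
    return float(window.sum()) / feature.length


def annotate_pct_repeated(annot: AnnotationSet, mask: RepeatMask) -> None:
    for f in annot:
        f.pct_repeated = pct_repeated(f, mask)


def derive_regulatory_elements(
    annot: AnnotationSet,
    genome_length: int,
    utr3_fallback: int = 150,
    tts_search: int = 500,
) -> AnnotationSet:
    """Derive UTR5/UTR3/iGiO elements from genes plus TSS/TTS point features.

    UTR5 spans from the nearest upstream TSS to the gene start; UTR3 from the
    gene end to the nearest TTS within ``tts_search`` bp downstream, falling
    back to a fixed ``utr3_fallback`` bp stretch when no TTS is found. iGiO
    elements are the gaps between consecutive non-overlapping genes that share
    an operon. All definitions are strand-aware: upstream of a minus-strand
    gene means higher coordinates.
    """
    out = AnnotationSet()
    tss_pos = sorted(f.start for f in annot.of_type("TSS"))
    tts_pos = sorted(f.start for f in annot.of_type("TTS"))
    genes = [g for g in annot.genes if g.strand in ("+", "-")]

    for g in genes:
        if g.strand == "+":
            # nearest TSS at or before gene start
            i = bisect.bisect_left(tss_pos, g.start) - 1
            if i >= 0 and tss_pos[i] < g.start:
                out.add(Feature(f"UTR5_{g.id}", "UTR5", tss_pos[i], g.start - 1, "+"))
            j = bisect.bisect_right(tts_pos, g.end)
            if j < len(tts_pos) and tts_pos[j] <= g.end + tts_search:
                end = tts_pos[j]
            else:
                end = min(g.end + utr3_fallback, genome_length)
            if end > g.end:
                out.add(Feature(f"UTR3_{g.id}", "UTR3", g.end + 1, end, "+"))
        else:
            i = bisect.bisect_right(tss_pos, g.end)
            if i < len(tss_pos):
                out.add(Feature(f"UTR5_{g.id}", "UTR5", g.end + 1, tss_pos[i], "-"))
            j = bisect.bisect_left(tts_pos, g.start) - 1
            if j >= 0 and tts_pos[j] >= g.start - tts_search:
                start = tts_pos[j]
            else:
                start = max(g.start - utr3_fallback, 1)
            if start < g.start:
                out.add(Feature(f"UTR3_{g.id}", "UTR3", start, g.start - 1, "-"))

    by_operon: dict[str, list[Feature]] = {}
    for g in genes:
        if g.operon_id:
            by_operon.setdefault(g.operon_id, []).append(g)
    for op_id, members in by_operon.items():
        members.sort(key=lambda f: f.start)
        for a, b in zip(members, members[1:]):
            if b.start > a.end + 1:
                out.add(
                    Feature(
                        f"iGiO_{a.id}_{b.id}", "iGiO", a.end + 1, b.start - 1,
                        a.strand, operon_id=op_id,
                    )
                )
    return out


def upstream_interval(gene: Feature, window: int, genome_length: int) -> tuple[int, int]:
    """Strand-aware interval of ``window`` bp upstream of a gene start."""
    if gene.strand == "-":
        return gene.end + 1, min(gene.end + window, genome_length)
    return max(1, gene.start - window), gene.start - 1


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> Genome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    if len(records) > 1:
        raise ValueError(f"expected a single-contig genome, got {len(records)} records")
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq))


def write_fasta(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(annot: AnnotationSet, genome_id: str, path) -> None:
    rows = []
    for f in sorted(annot, key=lambda f: (f.start, f.end)):
        attrs = [f"ID={f.id}"]
        if f.operon_id:
            attrs.append(f"operon={f.operon_id}")
        rows.append(
            "\t".join(
                [
                    genome_id, "tnseqmap", f.ftype, str(f.start), str(f.end),
                    ".", f.strand, ".", ";".join(attrs),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def read_gff3(path, sidecar=None) -> AnnotationSet:
    """Read a GFF3 file, optionally joining a TSV sidecar with class metadata.

    The sidecar carries columns that GFF3 does not model directly:
    ``feature_id``, ``true_class``, ``cog``, ``gold_ne``.
    """
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"start": int, "end": int},
    )
    side = None
    if sidecar is not None:
        side = pd.read_csv(str(sidecar), sep="\t").set_index("feature_id")
    annot = AnnotationSet()
    for _, row in df.iterrows():
        attrs = dict(
            kv.split("=", 1) for kv in str(row["attributes"]).split(";") if "=" in kv
        )
        fid = attrs.get("ID")
        if fid is None:
            raise ValueError(f"feature without ID attribute in {path}")
        cog, gold = None, False
        if side is not None and fid in side.index:
            rec = side.loc[fid]
            cog = rec.get("cog") if isinstance(rec.get("cog"), str) else None
            gold = bool(rec.get("gold_ne", False))
        annot.add(
            Feature(
                id=fid,
                ftype=row["type"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"] if row["strand"] in ("+", "-") else ".",
                operon_id=attrs.get("operon"),
                cog=cog,
                gold_ne=gold,
            )
        )
    return annot


def mask_to_bed(mask: RepeatMask, genome_id: str, path) -> None:
    """Write repeated runs as BED (0-based, half-open)."""
    flags = mask.flags
    with open(path, "w") as fh:
        i = 0
        n = len(flags)
        while i < n:
            if flags[i]:
                j = i
                while j < n and flags[j]:
                    j += 1
                fh.write(f"{genome_id}\t{i}\t{j}\trepeat\n")
                i = j
            else:
                i += 1
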