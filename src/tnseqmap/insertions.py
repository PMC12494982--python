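"""Insertion tables, IR-tagged read calling, and sample merging."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .genome import Genome, revcomp

IR_TAG = "TACGGACTTTATC"


@dataclass
class InsertionSample:
    """One library x passage x replicate map of 1-based position -> read count."""

    library: str = "P"
    passage: int = 1
    replicate: int = 1
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_insertions(self) -> int:
        return len(self.counts)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def positions(self) -> set[int]:
        return set(self.counts)

    def label(self) -> str:
        return f"{self.library}{self.passage}_r{self.replicate}"


@dataclass
class MergedDataset:
    """Union of post-trim samples with pooled per-position read counts."""

    counts: dict[int, int]
    provenance: dict

    @property
    def positions(self) -> set[int]:
        return set(self.counts)

    @property
    def n_insertions(self) -> int:
        return len(self.counts)


def read_insertion_table(
    path, library: str = "P", passage: int = 1, replicate: int = 1
) -> InsertionSample:
    """Parse a 2-column TSV ``position<TAB>reads`` with a header line."""
    counts: dict[int, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position"):
            raise ValueError(f"{path}:1: expected header 'position\\treads'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                pos, reads = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer field") from None
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position {pos} out of range")
            if pos in counts:
                raise ValueError(f"{path}:{lineno}: duplicate position {pos}")
            counts[pos] = reads
    return InsertionSample(library=library, passage=passage, replicate=replicate, counts=counts)


def write_insertion_table(sample: InsertionSample, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\treads\n")
        for pos in sorted(sample.counts):
            fh.write(f"{pos}\t{sample.counts[pos]}\n")


def filter_min_reads(sample: InsertionSample, min_reads: int = 2) -> InsertionSample:
    """Drop insertions supported by fewer than ``min_reads`` reads."""
    return InsertionSample(
        library=sample.library,
        passage=sample.passage,
        replicate=sample.replicate,
        counts={p: r for p, r in sample.counts.items() if r >= min_reads},
    )


def _find_approx(haystack: str, needle: str, max_mismatch: int) -> list[int]:
    """0-based start offsets of matches of ``needle`` with <= max_mismatch
    substitutions, found by pigeonhole seeding on exact halves."""
    hits = set()
    if max_mismatch == 0:
        start = haystack.find(needle)
        while start != -1:
            hits.add(start)
            start = haystack.find(needle, start + 1)
        return sorted(hits)
    half = len(needle) // 2
    seeds = [(needle[:half], 0), (needle[half:], half)]
    for seed, offset in seeds:
        start = haystack.find(seed)
        while start != -1:
            cand = start - offset
            if 0 <= cand <= len(haystack) - len(needle):
                window = haystack[cand : cand + len(needle)]
                mm = sum(a != b for a, b in zip(window, needle))
                if mm <= max_mismatch:
                    hits.add(cand)
            start = haystack.find(seed, start + 1)
    return sorted(hits)


def call_insertions(
    fastq_path,
    genome: Genome,
    ir: str = IR_TAG,
    max_mismatch: int = 1,
    anchor_len: int = 30,
    library: str = "P",
    passage: int = 1,
    replicate: int = 1,
) -> tuple[InsertionSample, dict]:
    """Call insertion positions from IR-tagged reads.

    For each read containing the IR tag, the post-tag anchor is located in
    the genome (forward or reverse complement) allowing up to ``max_mismatch``
    substitutions. The genomic base adjacent to the tag (in forward-strand
    coordinates) is the insertion position. Reads whose anchor places equally
    well at two or more loci are discarded as ambiguous and tallied in the
    returned report.
    """
    seq = genome.sequence
    rcseq = revcomp(seq)
    n = genome.length
    report = {"reads": 0, "tagged": 0, "mapped": 0, "ambiguous": 0, "unmapped": 0,
              "short_anchor": 0}
    counts: dict[int, int] = {}
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        report["reads"] += 1
        read = str(rec.seq).upper()
        idx = read.find(ir)
        if idx == -1:
            continue
        report["tagged"] += 1
        anchor = read[idx + len(ir) : idx + len(ir) + anchor_len]
        if len(anchor) < min(anchor_len, 20):
            report["short_anchor"] += 1
            continue
        loci = []  # (position, mismatches)
        for off in _find_approx(seq, anchor, max_mismatch):
            window = seq[off : off + len(anchor)]
            mm = sum(a != b for a, b in zip(window, anchor))
            loci.append((off + 1, mm))
        for off in _find_approx(rcseq, anchor, max_mismatch):
            window = rcseq[off : off + len(anchor)]
            mm = sum(a != b for a, b in zip(window, anchor))
            # junction base in forward coordinates: last base of the rc match
            loci.append((n - off, mm))
        if not loci:
            report["unmapped"] += 1
            continue
        best = min(mm for _, mm in loci)
        best_loci = {pos for pos, mm in loci if mm == best}
        if len(best_loci) > 1:
            report["ambiguous"] += 1
            continue
        pos = best_loci.pop()
        counts[pos] = counts.get(pos, 0) + 1
        report["mapped"] += 1
    sample = InsertionSample(library=library, passage=passage, replicate=replicate,
                             counts=counts)
    return sample, report


def trim_sample(sample: InsertionSample, trim: float) -> InsertionSample:
    """Drop positions in the top/bottom ``trim`` read-count quantiles.

    Rank-based: with n positions, at most floor(trim*n) are dropped on each
    side; ties at the quantile boundary are kept on the retain side.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    n = len(sample.counts)
    k = int(np.floor(trim * n))
    if k == 0:
        return sample
    values = np.sort(np.fromiter(sample.counts.values(), dtype=np.int64, count=n))
    lo, hi = values[k], values[n - 1 - k]
    kept = {p: r for p, r in sample.counts.items() if lo <= r <= hi}
    return InsertionSample(sample.library, sample.passage, sample.replicate, kept)


def merge_samples(samples: Iterable[InsertionSample], trim: float = 0.05) -> MergedDataset:
    """Merge samples after per-sample read-count quantile trimming.

    The merged position set is the union of post-trim positions; pooled reads
    are summed over contributing samples.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample to merge")
    counts: dict[int, int] = {}
    prov = {"trim": trim, "samples": [], "dropped": {}}
    for s in samples:
        trimmed = trim_sample(s, trim)
        prov["samples"].append(s.label())
        prov["dropped"][s.label()] = s.n_insertions - trimmed.n_insertions
        for p, r in trimmed.counts.items():
            counts[p] = counts.get(p, 0) + r
    return MergedDataset(counts=counts, provenance=prov)
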