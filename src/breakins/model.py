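"""Reference genome, break-locus amplicon design, and feature annotations.

All internal coordinates are 0-based half-open on the plus strand. Minus-strand
alignments store plus-strand (start, end) with a strand flag. The only
conversions to the 1-based inclusive convention of alignment-tabular files live
in :mod:`breakins.align`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Donor source classes, in classification precedence order (see annotate module).
SOURCE_CLASSES = ("locus", "mtDNA", "plasmid_2micron", "Ty", "rDNA", "nuclear")

_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True iff the half-open intervals share at least 1 bp."""
    return a_start < b_end and b_start < a_end


@dataclass
class ReferenceGenome:
    """Reference sequences with a donor source class per sequence.

    ``class_intervals`` carries interval-defined classes (rDNA, Ty) living on
    nuclear sequences: a donor hit is classed rDNA/Ty when it overlaps one of
    those intervals by at least 1 bp; otherwise the per-sequence class applies.
    """

    sequences: dict[str, str]
    source_class_map: dict[str, str]
    class_intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} contains non-DNA characters {sorted(bad)}")
            if name not in self.source_class_map:
                raise ValueError(f"sequence {name!r} has no source class")
        for name, cls in self.source_class_map.items():
            if cls not in SOURCE_CLASSES:
                raise ValueError(f"unknown source class {cls!r} for sequence {name!r}")
        for cls, ivals in self.class_intervals.items():
            if cls not in ("rDNA", "Ty"):
                raise ValueError(f"interval-defined class must be rDNA or Ty, got {cls!r}")
            for seq_name, start, end in ivals:
                if seq_name not in self.sequences:
                    raise ValueError(f"{cls} interval on unknown sequence {seq_name!r}")
                if not (0 <= start < end <= len(self.sequences[seq_name])):
                    raise ValueError(f"{cls} interval ({start},{end}) outside {seq_name!r}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, name: str, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end) from a sequence; minus strand reverse-complements."""
        seq = self.sequences[name][start:end]
        return seq if strand == "+" else revcomp(seq)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.sequences:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class AmpliconDesign:
    """Model of the break-locus amplicon.

    The break point is a single cut offset within the amplicon; junction
    arithmetic downstream is defined relative to it. ``left_flank_len`` and
    ``right_flank_len`` are the distances from the inner primer 3' ends to the
    break (assay values 11 and 18 bp). The dedup junction key takes
    ``junction_flank_locus`` bp of locus sequence and ``junction_flank_donor``
    bp of insert at each junction (11 + 19 -> a 60 bp combined key).
    """

    locus_name: str
    amplicon_start: int
    amplicon_end: int
    break_point: int  # offset within the amplicon, 0-based
    left_flank_len: int = 11
    right_flank_len: int = 18
    home_index_len: int = 3
    junction_flank_locus: int = 11
    junction_flank_donor: int = 19
    # sample-id -> (illumina index pair, home index pair); each index pair is a
    # (i5-like, i7-like) tuple of short sequences
    sample_indexes: dict[str, tuple[tuple[str, str], tuple[str, str]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not 0 < self.break_point < self.amplicon_end - self.amplicon_start:
            raise ValueError("break_point must lie strictly inside the amplicon")
        if self.left_flank_len < self.junction_flank_locus:
            raise ValueError("left_flank_len must be >= junction_flank_locus")
        if self.right_flank_len < self.junction_flank_locus:
            raise ValueError("right_flank_len must be >= junction_flank_locus")
        home = [h for _, h in self.sample_indexes.values()]
        if len(set(home)) != len(home):
            raise ValueError("home-index pairs must be mutually distinct across samples")
        for sid, (ill, hom) in self.sample_indexes.items():
            for idx in hom:
                if len(idx) != self.home_index_len:
                    raise ValueError(f"home index {idx!r} of sample {sid!r} has wrong length")

    @property
    def amplicon_len(self) -> int:
        return self.amplicon_end - self.amplicon_start

    def amplicon_seq(self, genome: ReferenceGenome) -> str:
        return genome.fetch(self.locus_name, self.amplicon_start, self.amplicon_end)

    def illumina_lookup(self) -> dict[tuple[str, str], str]:
        return {ill: sid for sid, (ill, _hom) in self.sample_indexes.items()}

    def home_lookup(self) -> dict[tuple[str, str], str]:
        return {hom: sid for sid, (_ill, hom) in self.sample_indexes.items()}


@dataclass
class FeatureSet:
    """Named genomic interval sets (ARS, telomere, tRNA, R-loop, ...) for enrichment.

    ``excluded_sources`` lists donor source classes whose donors are removed
    before any enrichment analysis (retroelement, mtDNA, rDNA, the break locus
    itself, and the 2-micron plasmid).
    """

    features: dict[str, list[tuple[str, int, int, str]]]
    excluded_sources: tuple[str, ...] = ("Ty", "mtDNA", "rDNA", "locus", "plasmid_2micron")

    def __post_init__(self) -> None:
        for name, ivals in self.features.items():
            self.features[name] = sorted(ivals, key=lambda t: (t[0], t[1], t[2]))

    def counts(self) -> dict[str, int]:
        return {name: len(ivals) for name, ivals in self.features.items()}


def load_reference(
    fasta_paths: Sequence[str | Path],
    class_map: Mapping[str, str],
    class_intervals: Mapping[str, Iterable[tuple[str, int, int]]] | None = None,
) -> ReferenceGenome:
    """Load one or more FASTA files into a :class:`ReferenceGenome`.

    Lowercase input is uppercased; a duplicated record name (within or across
    files) is a hard error, as is any non-DNA character.
    """
    sequences: dict[str, str] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
            sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {list(map(str, fasta_paths))}")
    genome = ReferenceGenome(
        sequences=sequences,
        source_class_map=dict(class_map),
        class_intervals={k: list(v) for k, v in (class_intervals or {}).items()},
    )
    return genome


def load_features(
    bed_paths: Mapping[str, str | Path],
    genome: ReferenceGenome,
    excluded_sources: tuple[str, ...] = ("Ty", "mtDNA", "rDNA", "locus", "plasmid_2micron"),
) -> FeatureSet:
    """Load BED files (0-based half-open, 3+ columns) as a :class:`FeatureSet`.

    Intervals on unknown sequences are skipped with a warning; intervals
    extending past the sequence end are clipped with a warning; a malformed
    line is a hard error naming the line number.
    """
    features: dict[str, list[tuple[str, int, int, str]]] = {}
    for fname, path in bed_paths.items():
        ivals: list[tuple[str, int, int, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
                chrom = cols[0]
                try:
                    start, end = int(cols[1]), int(cols[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
                if start < 0 or end <= start:
                    raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end})")
                strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
                if chrom not in genome.sequences:
                    log.warning("%s:%d: unknown sequence %r, interval skipped", path, lineno, chrom)
                    continue
                chrom_len = len(genome.sequences[chrom])
                if end > chrom_len:
                    log.warning(
                        "%s:%d: interval end %d clipped to %s length %d",
                        path, lineno, end, chrom, chrom_len,
                    )
                    end = chrom_len
                    if end <= start:
                        continue
                ivals.append((chrom, start, end, strand))
        features[fname] = ivals
        log.info("feature %s: %d intervals", fname, len(ivals))
    return FeatureSet(features=features, excluded_sources=excluded_sources)


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return first - 1, last
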