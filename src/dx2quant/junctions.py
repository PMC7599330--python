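"""Splice-junction read counting for exon-skipping isoform ratios.

Targeted RNA-seq reads aligned across the AIMP2 locus (hg19 chr7) are
classified by their CIGAR N (skipped-region) gaps: a read whose gap joins
the last base of exon 1 to the first base of exon 2 (chr7:6009499-6015145)
supports the full-length transcript, while a gap joining exon 1 to exon 3
(chr7:6009499-6017814, a longer skipped lesion) supports the
exon-2-skipping variant (AIMP2-DX2). The per-sample expression ratio is
n_skip / n_full. A seeded SAM read generator provides exact ground truth.

Coordinates follow the flank convention: each printed span is (last exonic
base before the intron, first exonic base after it), 1-based inclusive, so
the implied N lengths are 5645 (full) and 8314 (skip). Both coordinates and
the chromosome name are configuration, not constants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = [
    "GeneModel",
    "JunctionCounts",
    "Classification",
    "CigarError",
    "extract_junctions",
    "classify_read",
    "quantify_sample",
    "quantify_sam",
    "simulate_reads",
    "write_sam",
    "parse_cigar",
]

# hg19 chr7 length, used only for the synthetic SAM header
_CHR7_LEN = 159_138_663

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


class CigarError(ValueError):
    """Malformed CIGAR string."""


class Classification(Enum):
    FULL = "full"  # exon1-2 junction: full-length transcript
    SKIP = "skip"  # exon1-3 junction: exon-2-skipping variant
    OTHER = "other"  # spliced, but matching neither junction
    UNSPLICED = "unspliced"  # no N operation
    OFF_TARGET = "off_target"  # aligned to a different reference


@dataclass(frozen=True)
class GeneModel:
    """Donor/acceptor coordinates of the two competing junctions.

    ``donor`` is the last base of exon 1; ``acceptor_full`` / ``acceptor_skip``
    are the first bases of exons 2 and 3 (1-based). ``tolerance`` (bp) allows
    slop on both junction ends; it must keep the two classes disjoint.
    ``normalize_chrom`` treats "chr7" and "7" as the same reference.
    """

    chrom: str = "chr7"
    donor: int = 6_009_499
    acceptor_full: int = 6_015_145
    acceptor_skip: int = 6_017_814
    tolerance: int = 0
    normalize_chrom: bool = True

    def __post_init__(self) -> None:
        if not (self.donor < self.acceptor_full < self.acceptor_skip):
            raise ValueError("require donor < acceptor_full < acceptor_skip")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if 2 * self.tolerance >= self.acceptor_skip - self.acceptor_full:
            raise ValueError(
                "tolerance large enough to make FULL and SKIP classes overlap"
            )

    @property
    def gap_full(self) -> int:
        """Implied N length of the exon1-2 junction."""
        return self.acceptor_full - self.donor - 1

    @property
    def gap_skip(self) -> int:
        """Implied N length of the exon1-3 junction (the longer skipped lesion)."""
        return self.acceptor_skip - self.donor - 1

    def same_chrom(self, name: str | None) -> bool:
        if name is None:
            return False
        if self.normalize_chrom:
            return name.removeprefix("chr") == self.chrom.removeprefix("chr")
        return name == self.chrom

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "donor": self.donor,
            "acceptor_full": self.acceptor_full,
            "acceptor_skip": self.acceptor_skip,
            "tolerance": self.tolerance,
        }


@dataclass(frozen=True)
class JunctionCounts:
    """Per-sample junction-read tally and skip/full expression ratio."""

    n_full: int = 0
    n_skip: int = 0
    n_other: int = 0
    n_unspliced: int = 0
    n_filtered: int = 0

    @property
    def n_counted(self) -> int:
        return self.n_full + self.n_skip + self.n_other + self.n_unspliced

    @property
    def ratio(self) -> float | None:
        """n_skip / n_full; None (undefined) when no full-length reads."""
        if self.n_full == 0:
            return None
        return self.n_skip / self.n_full

    def to_dict(self) -> dict:
        return {
            "n_full": self.n_full,
            "n_skip": self.n_skip,
            "n_other": self.n_other,
            "n_unspliced": self.n_unspliced,
            "n_filtered": self.n_filtered,
            "ratio": self.ratio,
        }


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) pairs, validating every token."""
    if not cigar or cigar == "*":
        raise CigarError("empty CIGAR")
    pairs: list[tuple[str, int]] = []
    pos = 0
    for match in _CIGAR_TOKEN.finditer(cigar):
        if match.start() != pos:
            raise CigarError(f"malformed CIGAR near {cigar[pos:match.start()]!r}")
        pairs.append((match.group(2), int(match.group(1))))
        pos = match.end()
    if pos != len(cigar):
        raise CigarError(f"malformed CIGAR near {cigar[pos:]!r}")
    return pairs


def extract_junctions(
    pos: int, cigar: str | Sequence[tuple[str, int]]
) -> list[tuple[int, int]]:
    """Junctions of one alignment as (donor_base, acceptor_base), 1-based.

    ``pos`` is the 1-based leftmost aligned reference position. For each N
    operation the donor is the last reference base consumed before the gap
    and the acceptor the first base consumed after it; insertions and clips
    consume no reference. Order of gaps is preserved.
    """
    ops = parse_cigar(cigar) if isinstance(cigar, str) else list(cigar)
    ref = pos  # next reference base to be consumed
    junctions: list[tuple[int, int]] = []
    for op, length in ops:
        if length <= 0:
            raise CigarError(f"non-positive CIGAR length: {length}{op}")
        if op == "N":
            junctions.append((ref - 1, ref + length))
            ref += length
        elif op in _REF_CONSUMING:
            ref += length
    return junctions


def _read_fields(read) -> tuple[str | None, int, str | None]:
    """(reference name, 1-based pos, cigar) from a pysam segment or mapping."""
    if isinstance(read, pysam.AlignedSegment):
        cigar = read.cigarstring
        return read.reference_name, read.reference_start + 1, cigar
    return read["chrom"], int(read["pos"]), read["cigar"]


def classify_read(read, model: GeneModel) -> Classification:
    """Classify one aligned read against the two-junction gene model.

    FULL/SKIP require a junction matching (donor, acceptor) within the
    model's tolerance on both ends; the first matching junction decides for
    multi-gap reads. Spliced reads matching neither are OTHER; reads without
    an N gap are UNSPLICED; reads on another reference are OFF_TARGET
    (refused, never counted as unspliced).
    """
    chrom, pos, cigar = _read_fields(read)
    if not model.same_chrom(chrom):
        return Classification.OFF_TARGET
    junctions = extract_junctions(pos, cigar)
    if not junctions:
        return Classification.UNSPLICED
    tol = model.tolerance
    for donor, acceptor in junctions:
        if abs(donor - model.donor) <= tol and abs(acceptor - model.acceptor_full) <= tol:
            return Classification.FULL
        if abs(donor - model.donor) <= tol and abs(acceptor - model.acceptor_skip) <= tol:
            return Classification.SKIP
    return Classification.OTHER


def _passes_filters(read, min_mapq: int) -> bool:
    if isinstance(read, pysam.AlignedSegment):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return False
        return read.mapping_quality >= min_mapq
    return int(read.get("mapq", 60)) >= min_mapq


def quantify_sample(
    reads: Iterable, model: GeneModel | None = None, min_mapq: int = 0
) -> JunctionCounts:
    """Tally FULL/SKIP/OTHER/UNSPLICED over reads passing flag/mapq filters.

    Unmapped, secondary and supplementary alignments are excluded, as are
    off-target reads; both are reported under ``n_filtered``. Empty input
    yields zero counts with an undefined ratio.
    """
    model = model or GeneModel()
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    tally = {c: 0 for c in Classification}
    n_filtered = 0
    for read in reads:
        if not _passes_filters(read, min_mapq):
            n_filtered += 1
            continue
        cls = classify_read(read, model)
        if cls is Classification.OFF_TARGET:
            n_filtered += 1
        else:
            tally[cls] += 1
    return JunctionCounts(
        n_full=tally[Classification.FULL],
        n_skip=tally[Classification.SKIP],
        n_other=tally[Classification.OTHER],
        n_unspliced=tally[Classification.UNSPLICED],
        n_filtered=n_filtered,
    )


def quantify_sam(
    path: str | Path, model: GeneModel | None = None, min_mapq: int = 0
) -> JunctionCounts:
    """Quantify a SAM (or BAM) file on disk."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return quantify_sample(fh, model=model, min_mapq=min_mapq)


def _sam_header(model: GeneModel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": model.chrom, "LN": _CHR7_LEN}],
        }
    )


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    pos1: int,
    cigar: str,
    read_len: int,
    rng,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = "".join(rng.choice(list("ACGT"), size=read_len))
    seg.flag = 0
    seg.reference_id = 0
    seg.reference_start = pos1 - 1
    seg.mapping_quality = 60
    seg.cigarstring = cigar
    seg.query_qualities = pysam.qualitystring_to_array("I" * read_len)
    return seg


def simulate_reads(
    model: GeneModel | None = None,
    n_full: int = 0,
    n_skip: int = 0,
    n_other: int = 0,
    n_unspliced: int = 0,
    read_len: int = 75,
    seed: int = 0,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Generate spliced SAM records with known junction classes.

    Each FULL/SKIP read places its junction at a seeded-random offset inside
    the read with exactly the N length implied by the model, so a roundtrip
    through :func:`quantify_sample` recovers the planted counts exactly.
    OTHER reads carry a spliced gap from the same donor to a decoy acceptor;
    UNSPLICED reads are contiguous matches near the locus.
    """
    import numpy as np

    model = model or GeneModel()
    for name, n in (
        ("n_full", n_full),
        ("n_skip", n_skip),
        ("n_other", n_other),
        ("n_unspliced", n_unspliced),
    ):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    if read_len < 2:
        raise ValueError("read_len must be >= 2 to span a junction")
    rng = np.random.default_rng(seed)
    header = _sam_header(model)
    reads: list[pysam.AlignedSegment] = []

    def spliced(tag: str, i: int, acceptor: int) -> pysam.AlignedSegment:
        gap = acceptor - model.donor - 1
        m1 = int(rng.integers(1, read_len))  # >=1 matched base on each side
        m2 = read_len - m1
        pos1 = model.donor - m1 + 1
        cigar = f"{m1}M{gap}N{m2}M"
        return _make_read(header, f"{tag}_{i}", pos1, cigar, read_len, rng)

    for i in range(n_full):
        reads.append(spliced("full", i, model.acceptor_full))
    for i in range(n_skip):
        reads.append(spliced("skip", i, model.acceptor_skip))
    for i in range(n_other):
        decoy = model.acceptor_skip + 1000 + int(rng.integers(0, 500))
        reads.append(spliced("other", i, decoy))
    for i in range(n_unspliced):
        pos1 = model.donor - read_len + 1 + int(rng.integers(0, read_len))
        reads.append(
            _make_read(header, f"unspliced_{i}", max(1, pos1), f"{read_len}M", read_len, rng)
        )
    return header, reads


def write_sam(
    header: pysam.AlignmentHeader,
    reads: Iterable[pysam.AlignedSegment],
    path: str | Path,
) -> None:
    """Write records as SAM text."""
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for read in reads:
            fh.write(read)
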