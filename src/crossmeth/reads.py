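"""Read QC and SNP-based allele assignment in bisulfite space.

Amplicon reads are primer-defined, so no general alignment is needed:
each mate sits at a fixed offset (R1 at the amplicon start, R2 —
reverse-complemented back to the top strand — at its end) and is
compared ungapped against both allele references. Comparison happens
in bisulfite space: a reference C matched by a read C or T is never a
mismatch, any other disagreement is one mismatch. A read is assigned
to the allele with the strictly smaller mismatch count, provided that
count is within ``max_mismatch`` and the read covers at least one
informative SNP; ties or no informative SNP give ``ambiguous``, and
reads far from both references are ``unmapped``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import COL, LER, Region

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str  # Phred+33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"{self.read_id}: sequence/quality length mismatch"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def phred(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode(), dtype=np.uint8) - 33


@dataclass(frozen=True)
class ReadPairRecord:
    r1: FastqRead
    r2: FastqRead


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    try:
        with open(path) as fh:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise FastqParseError(f"{path}: record {i}: length mismatch")
                reads.append(FastqRead(title.split()[0], seq.upper(), qual))
    except ValueError as exc:  # biopython raises ValueError on malformed records
        raise FastqParseError(f"{path}: {exc}") from exc
    return reads


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPairRecord]:
    """Read mate files in lockstep; mate ids must agree up to a /1 /2 tag."""
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise FastqParseError(
            f"mate files differ in record count ({len(r1)} vs {len(r2)})"
        )
    strip_mate = lambda rid: re.sub(r"/[12]$", "", rid)
    pairs = []
    for a, b in zip(r1, r2):
        if strip_mate(a.read_id) != strip_mate(b.read_id):
            raise FastqParseError(f"mate id mismatch: {a.read_id} vs {b.read_id}")
        pairs.append(ReadPairRecord(a, b))
    return pairs


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------


def trim_trailing(read: FastqRead, min_quality: int) -> FastqRead:
    """Trim 3'-terminal bases whose quality is below ``min_quality``."""
    q = read.phred()
    keep = len(q)
    while keep > 0 and q[keep - 1] < min_quality:
        keep -= 1
    if keep == len(q):
        return read
    return FastqRead(read.read_id, read.sequence[:keep], read.quality[:keep])


def quality_filter(
    pairs: Sequence[ReadPairRecord], min_quality: int = 20, min_length: int = 100
) -> tuple[list[ReadPairRecord], int]:
    """Trim trailing low-quality bases and drop short pairs.

    Both mates are dropped if either falls below ``min_length`` after
    trimming. Returns the kept pairs and the number of dropped pairs.
    """
    kept: list[ReadPairRecord] = []
    dropped = 0
    for pair in pairs:
        t1 = trim_trailing(pair.r1, min_quality)
        t2 = trim_trailing(pair.r2, min_quality)
        if len(t1) < min_length or len(t2) < min_length:
            dropped += 1
        else:
            kept.append(ReadPairRecord(t1, t2))
    return kept, dropped


# ---------------------------------------------------------------------------
# Bisulfite-space matching
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def bisulfite_mismatches(read_seq: str, ref_seq: str, offset: int = 0) -> int:
    """Ungapped bisulfite-space mismatch count at a fixed offset.

    A reference C matched by read C or T does not count; every other
    disagreement counts one.
    """
    if offset < 0 or offset + len(read_seq) > len(ref_seq):
        raise ValueError(
            f"read span [{offset}, {offset + len(read_seq)}) outside reference "
            f"of length {len(ref_seq)}"
        )
    r = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    t = np.frombuffer(ref_seq.encode(), dtype=np.uint8)[offset : offset + len(read_seq)]
    mismatch = (r != t) & ~((t == ord("C")) & (r == ord("T")))
    return int(mismatch.sum())


@dataclass(frozen=True)
class AssignedRead:
    """Per-read allele call with evidence.

    ``site_bases`` maps shared-site positions (1-based, within the
    read's span) to the observed base, later tallied into
    methylated/unmethylated counts.
    """

    read_id: str
    mate: int
    region_id: str
    allele: str  # Col / Ler / ambiguous / unmapped
    mm_col: int
    mm_ler: int
    offset: int
    site_bases: dict[int, str] = field(default_factory=dict)


def assign_allele(
    read_seq: str,
    offset: int,
    region: Region,
    max_mismatch: int = 5,
    read_id: str = "",
    mate: int = 1,
) -> AssignedRead:
    """Assign one (top-strand-oriented) read to Col or Ler.

    The strictly smaller bisulfite mismatch count wins when it is
    within ``max_mismatch`` and the read covers at least one
    informative SNP; ties or no informative SNP covered give
    ``ambiguous``; both counts above the threshold give ``unmapped``.
    """
    mm_col = bisulfite_mismatches(read_seq, region.col.sequence, offset)
    mm_ler = bisulfite_mismatches(read_seq, region.ler.sequence, offset)
    span = range(offset + 1, offset + len(read_seq) + 1)  # 1-based
    covers_informative = any(s.position in span for s in region.informative_snps)

    best = min(mm_col, mm_ler)
    if best > max_mismatch:
        allele = UNMAPPED
    elif mm_col == mm_ler or not covers_informative:
        allele = AMBIGUOUS
    else:
        allele = COL if mm_col < mm_ler else LER

    site_bases = {}
    if allele in (COL, LER):
        for site in region.shared_sites:
            if site.position in span:
                site_bases[site.position] = read_seq[site.position - 1 - offset]
    return AssignedRead(
        read_id=read_id,
        mate=mate,
        region_id=region.region_id,
        allele=allele,
        mm_col=mm_col,
        mm_ler=mm_ler,
        offset=offset,
        site_bases=site_bases,
    )


def assign_pair(
    pair: ReadPairRecord,
    regions: Sequence[Region],
    max_mismatch: int = 5,
) -> tuple[AssignedRead, AssignedRead]:
    """Assign both mates of a pair, resolving the source region first.

    R1 is matched at the amplicon start and the reverse-complemented R2
    at its end. With several amplicons in the run, the pair is
    attributed to the region with the smallest combined best-allele
    mismatch count (competitive matching). Mates whose allele calls
    disagree are both demoted to ambiguous.
    """
    candidates = []
    for region in regions:
        L = region.length
        s1 = pair.r1.sequence[: min(len(pair.r1), L)]
        s2 = reverse_complement(pair.r2.sequence)[-min(len(pair.r2), L) :]
        a1 = assign_allele(
            s1, 0, region, max_mismatch, read_id=pair.r1.read_id, mate=1
        )
        a2 = assign_allele(
            s2, L - len(s2), region, max_mismatch, read_id=pair.r2.read_id, mate=2
        )
        score = min(a1.mm_col, a1.mm_ler) + min(a2.mm_col, a2.mm_ler)
        candidates.append((score, a1, a2))
    _, a1, a2 = min(candidates, key=lambda c: c[0])
    if a1.allele in (COL, LER) and a2.allele in (COL, LER) and a1.allele != a2.allele:
        a1 = replace(a1, allele=AMBIGUOUS, site_bases={})
        a2 = replace(a2, allele=AMBIGUOUS, site_bases={})
    return a1, a2


# ---------------------------------------------------------------------------
# Mapping summary and the 5% mapping-error rule
# ---------------------------------------------------------------------------


@dataclass
class MappingSummary:
    """Per individual x region read-accounting.

    ``n_col``/``n_ler`` count mates assigned to each allele; mapped
    total is their sum. ``excluded_allele`` is set by
    :func:`filter_mapping_error` when the minor allele's reads are
    treated as mapping error.
    """

    individual: str
    region_id: str
    n_col: int = 0
    n_ler: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0
    n_quality_dropped: int = 0  # mates dropped by the quality filter
    excluded_allele: str | None = None
    n_discarded: int = 0
    failed_qc: bool = False

    @property
    def total_mapped(self) -> int:
        return self.n_col + self.n_ler

    @property
    def minor_fraction(self) -> float:
        if self.total_mapped == 0:
            return float("nan")
        return min(self.n_col, self.n_ler) / self.total_mapped

    def allele_count(self, allele: str) -> int:
        return self.n_col if allele == COL else self.n_ler


def summarize_assignments(
    individual: str,
    region_id: str,
    assigned: Iterable[AssignedRead],
    n_quality_dropped: int = 0,
) -> MappingSummary:
    s = MappingSummary(
        individual=individual,
        region_id=region_id,
        n_quality_dropped=n_quality_dropped,
    )
    for a in assigned:
        if a.allele == COL:
            s.n_col += 1
        elif a.allele == LER:
            s.n_ler += 1
        elif a.allele == AMBIGUOUS:
            s.n_ambiguous += 1
        else:
            s.n_unmapped += 1
    return s


def filter_mapping_error(
    summary: MappingSummary, threshold: float = 0.05
) -> MappingSummary:
    """Apply the mapping-error rule to one individual x region.

    If the minor allele holds strictly less than ``threshold`` of the
    mapped reads, those reads are regarded as mapping error: they are
    excluded from genotyping and methylation quantification and their
    count recorded. An individual with zero mapped reads is flagged
    failed-QC.
    """
    s = replace(summary)
    if s.total_mapped == 0:
        s.failed_qc = True
        logger.warning("%s/%s: no mapped reads; failed QC", s.individual, s.region_id)
        return s
    minor = COL if s.n_col < s.n_ler else LER
    minor_n = min(s.n_col, s.n_ler)
    if 0 < minor_n and minor_n / s.total_mapped < threshold:
        s.excluded_allele = minor
        s.n_discarded = minor_n
        if minor == COL:
            s.n_col = 0
        else:
            s.n_ler = 0
    elif minor_n == 0:
        # single-allele individual: nothing to discard
        s.excluded_allele = None
    return s
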