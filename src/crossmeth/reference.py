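"""Amplicon allele references and cytosine-site models.

The analysis works on short PCR amplicons of two nuclear insertions of
mitochondrial DNA (NUMTs) in *Arabidopsis thaliana*, each present as two
haplotypes (the Columbia and Landsberg erecta alleles). This module
represents those references, enumerates cytosines with their sequence
context (CpG / CpHpG / CpHpH, H in {A, T, C}), locates the SNPs that tell
the two alleles apart, and selects the cytosine sites shared by both
alleles that methylation quantification is restricted to.

Conventions
-----------
* The amplicon is analysed on the top strand only; cytosines on the
  bottom strand (G positions on the top strand) are ignored.
* Positions are 1-based. Genomic coordinates are 1-based inclusive.
* Context is determined solely by the two bases downstream of the
  cytosine on the analysed strand; a cytosine within 2 bases of the
  3' end is resolved through ``flank3`` when provided, otherwise it is
  dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
CONTEXTS = ("CpG", "CpHpG", "CpHpH")

COL = "Col"
LER = "Ler"


class InvalidSequenceError(ValueError):
    """Sequence contains characters other than A/C/G/T."""


class AlignmentRequiredError(ValueError):
    """Allele sequences differ in length; indels are unsupported."""


@dataclass(frozen=True)
class AlleleRef:
    """One haplotype sequence of one amplicon region.

    Parameters
    ----------
    region_id : str
        Identifier of the amplicon region.
    allele_id : str
        ``"Col"`` or ``"Ler"``.
    sequence : str
        Uppercase DNA (A/C/G/T only).
    chrom, start, end :
        Optional genomic location, 1-based inclusive.
    flank5, flank3 : str
        Optional flanking bases (>= 2 on the 3' side to resolve
        edge-cytosine contexts).
    """

    region_id: str
    allele_id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InvalidSequenceError(
                f"{self.region_id}|{self.allele_id}: non-ACGT characters {sorted(bad)}"
            )
        for fl in (self.flank5, self.flank3):
            if set(fl) - VALID_BASES:
                raise InvalidSequenceError(
                    f"{self.region_id}|{self.allele_id}: non-ACGT flank"
                )
        if self.start is not None and self.end is not None:
            if self.end - self.start + 1 != len(self.sequence):
                raise ValueError(
                    f"{self.region_id}|{self.allele_id}: coordinate span "
                    f"{self.start}..{self.end} does not match sequence length "
                    f"{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CytosineSite:
    """A top-strand cytosine with its motif context.

    ``shared`` marks sites that are cytosines with identical context in
    both alleles (set by :func:`shared_cytosines`).
    """

    position: int  # 1-based offset within the amplicon
    context: str  # CpG / CpHpG / CpHpH
    shared: bool = False


@dataclass(frozen=True)
class SnpSite:
    """A substitution between the Col and Ler alleles.

    ``informative`` is true iff the alleles remain distinguishable at
    this position after bisulfite conversion under every methylation
    state: a reference C may be read as either C or T, any other base
    only as itself, and the SNP is informative iff the two possible
    read-base sets do not intersect.
    """

    position: int
    col_base: str
    ler_base: str
    informative: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.col_base == self.ler_base:
            raise ValueError(f"position {self.position}: bases are equal")


def read_base_set(base: str) -> frozenset[str]:
    """Possible read bases for a reference base after bisulfite conversion."""
    return frozenset({"C", "T"}) if base == "C" else frozenset({base})


def _context_of(duplet: str) -> str:
    """Motif context from the two bases downstream of a cytosine."""
    if duplet[0] == "G":
        return "CpG"
    return "CpHpG" if duplet[1] == "G" else "CpHpH"


def classify_contexts(ref: AlleleRef) -> list[CytosineSite]:
    """Enumerate top-strand cytosines of ``ref`` with their contexts.

    Cytosines within 2 bases of the 3' end are resolved through
    ``ref.flank3``; if the flank is too short their context is
    unresolvable and they are excluded (logged as a warning).
    """
    if not ref.sequence:
        raise InvalidSequenceError("empty sequence")
    extended = ref.sequence + ref.flank3
    sites: list[CytosineSite] = []
    n_dropped = 0
    for i, base in enumerate(ref.sequence):
        if base != "C":
            continue
        duplet = extended[i + 1 : i + 3]
        if len(duplet) < 2:
            n_dropped += 1
            continue
        sites.append(CytosineSite(position=i + 1, context=_context_of(duplet)))
    if n_dropped:
        logger.warning(
            "%s|%s: dropped %d cytosine(s) with unresolvable 3'-edge context "
            "(no flank3)",
            ref.region_id,
            ref.allele_id,
            n_dropped,
        )
    return sites


def find_snps(col: AlleleRef, ler: AlleleRef) -> list[SnpSite]:
    """Locate substitutions between equal-length Col and Ler alleles.

    Raises
    ------
    AlignmentRequiredError
        If the sequences differ in length (indels unsupported).
    """
    if len(col.sequence) != len(ler.sequence):
        raise AlignmentRequiredError(
            f"allele lengths differ ({len(col.sequence)} vs {len(ler.sequence)}); "
            "indel-containing amplicons are unsupported"
        )
    snps = []
    for i, (cb, lb) in enumerate(zip(col.sequence, ler.sequence)):
        if cb == lb:
            continue
        informative = read_base_set(cb).isdisjoint(read_base_set(lb))
        snps.append(
            SnpSite(position=i + 1, col_base=cb, ler_base=lb, informative=informative)
        )
    return snps


def shared_cytosines(
    col_sites: Sequence[CytosineSite],
    ler_sites: Sequence[CytosineSite],
    snps: Iterable[SnpSite],
) -> list[CytosineSite]:
    """Select cytosine sites shared by both alleles with equal context.

    Positions overlapping a SNP are excluded. The result is symmetric in
    the two site lists.
    """
    snp_positions = {s.position for s in snps}
    ler_by_pos = {s.position: s.context for s in ler_sites}
    shared = []
    for site in col_sites:
        if site.position in snp_positions:
            continue
        if ler_by_pos.get(site.position) == site.context:
            shared.append(
                CytosineSite(position=site.position, context=site.context, shared=True)
            )
    return shared


def context_counts(sites: Iterable[CytosineSite]) -> dict[str, int]:
    """Number of sites per motif context, in fixed CpG/CpHpG/CpHpH order."""
    counts = {c: 0 for c in CONTEXTS}
    for s in sites:
        counts[s.context] += 1
    return counts


# ---------------------------------------------------------------------------
# Region container and FASTA / TSV I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A two-allele amplicon region with derived site annotations."""

    region_id: str
    col: AlleleRef
    ler: AlleleRef
    snps: tuple[SnpSite, ...]
    col_sites: tuple[CytosineSite, ...]
    ler_sites: tuple[CytosineSite, ...]
    shared_sites: tuple[CytosineSite, ...]

    @property
    def length(self) -> int:
        return len(self.col.sequence)

    @property
    def informative_snps(self) -> tuple[SnpSite, ...]:
        return tuple(s for s in self.snps if s.informative)

    def allele_ref(self, allele: str) -> AlleleRef:
        if allele == COL:
            return self.col
        if allele == LER:
            return self.ler
        raise KeyError(allele)

    def allele_sites(self, allele: str) -> tuple[CytosineSite, ...]:
        return self.col_sites if allele == COL else self.ler_sites


def build_region(col: AlleleRef, ler: AlleleRef) -> Region:
    """Derive SNPs, per-allele contexts and shared sites for an allele pair."""
    if col.region_id != ler.region_id:
        raise ValueError(
            f"allele region ids differ: {col.region_id!r} vs {ler.region_id!r}"
        )
    snps = find_snps(col, ler)
    col_sites = classify_contexts(col)
    ler_sites = classify_contexts(ler)
    shared = shared_cytosines(col_sites, ler_sites, snps)
    return Region(
        region_id=col.region_id,
        col=col,
        ler=ler,
        snps=tuple(snps),
        col_sites=tuple(col_sites),
        ler_sites=tuple(ler_sites),
        shared_sites=tuple(shared),
    )


def read_region_fasta(
    path: str | Path,
    flanks: dict[str, tuple[str, str]] | None = None,
    coordinates: dict[str, tuple[str, int, int]] | None = None,
) -> list[Region]:
    """Read amplicon allele references from a FASTA file.

    Record IDs follow ``<region_id>|<allele_id>`` with allele_id Col or
    Ler; every region must supply both alleles. ``flanks`` optionally
    maps region_id to (flank5, flank3) and ``coordinates`` maps
    region_id to (chrom, start, end).
    """
    flanks = flanks or {}
    coordinates = coordinates or {}
    by_region: dict[str, dict[str, AlleleRef]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            region_id, allele_id = rec.id.split("|", 1)
        except ValueError:
            raise ValueError(
                f"FASTA id {rec.id!r} does not match '<region_id>|<allele_id>'"
            ) from None
        if allele_id not in (COL, LER):
            raise ValueError(f"unknown allele id {allele_id!r} in {rec.id!r}")
        f5, f3 = flanks.get(region_id, ("", ""))
        chrom, start, end = coordinates.get(region_id, (None, None, None))
        by_region.setdefault(region_id, {})[allele_id] = AlleleRef(
            region_id=region_id,
            allele_id=allele_id,
            sequence=str(rec.seq).upper(),
            chrom=chrom,
            start=start,
            end=end,
            flank5=f5,
            flank3=f3,
        )
    regions = []
    for region_id, alleles in by_region.items():
        missing = {COL, LER} - set(alleles)
        if missing:
            raise ValueError(f"region {region_id}: missing allele(s) {sorted(missing)}")
        regions.append(build_region(alleles[COL], alleles[LER]))
    return regions


def write_region_fasta(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for region in regions:
            for ref in (region.col, region.ler):
                fh.write(f">{ref.region_id}|{ref.allele_id}\n{ref.sequence}\n")


def sites_table(region: Region):
    """Per-position annotation table: position, context, shared, snp flags."""
    import pandas as pd

    shared_pos = {s.position for s in region.shared_sites}
    snp_pos = {s.position for s in region.snps}
    rows = []
    for allele, sites in ((COL, region.col_sites), (LER, region.ler_sites)):
        for s in sites:
            rows.append(
                {
                    "region": region.region_id,
                    "allele": allele,
                    "position": s.position,
                    "context": s.context,
                    "shared": s.position in shared_pos,
                    "snp": s.position in snp_pos,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Default synthetic regions
# ---------------------------------------------------------------------------

#: Genomic spans of the two NUMT amplicons (1-based inclusive).
REGION_COORDS = {
    "region1": ("Chr3", 16574335, 16574467),  # 133 bp
    "region2": ("Chr4", 6341088, 6341288),  # 201 bp
}


def _make_synthetic_pair(
    region_id: str,
    length: int,
    n_snps: int,
    seed: int,
    snp_window: tuple[int, int],
) -> tuple[AlleleRef, AlleleRef]:
    """Build one synthetic Col/Ler allele pair.

    Stand-in for the study's (undeposited) amplicon sequences: a seeded
    random top strand plus ``n_snps`` informative A<->G substitutions
    placed inside ``snp_window`` so that both 150-base mates of a
    paired-end fragment cover at least one informative SNP.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    # C-rich-ish composition so all three motifs occur at useful density
    seq = rng.choice(bases, size=length, p=[0.28, 0.27, 0.20, 0.25])
    col = "".join(seq)
    lo, hi = snp_window
    candidates = [i for i in range(lo - 1, hi) if col[i] in "AG"]
    snp_idx = sorted(rng.choice(len(candidates), size=n_snps, replace=False))
    positions = [candidates[i] for i in snp_idx]
    ler_list = list(col)
    for i in positions:
        ler_list[i] = "G" if col[i] == "A" else "A"
    ler = "".join(ler_list)
    chrom, start, end = REGION_COORDS[region_id]
    flank3 = "".join(rng.choice(bases, size=2))
    kwargs = dict(chrom=chrom, start=start, end=end, flank3=flank3)
    return (
        AlleleRef(region_id, COL, col, **kwargs),
        AlleleRef(region_id, LER, ler, **kwargs),
    )


def default_regions() -> list[Region]:
    """The two default amplicon regions (synthetic sequences).

    The real amplicons are a 133 bp NUMT on Chr3 with 4 allele-
    distinguishing SNPs and a 201 bp NUMT on Chr4 with 2; their
    sequences are not deposited, so deterministic synthetic pairs with
    the same lengths and SNP counts stand in. SNPs are placed so that
    both mates of a 150x2 fragment always cover an informative SNP.
    """
    r1 = _make_synthetic_pair("region1", 133, 4, seed=20181203, snp_window=(10, 124))
    # 201 bp amplicon: mate overlap is positions 52..150
    r2 = _make_synthetic_pair("region2", 201, 2, seed=20181204, snp_window=(60, 145))
    return [build_region(*r1), build_region(*r2)]
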