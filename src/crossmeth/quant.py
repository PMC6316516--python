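"""Methylation quantification: site counts and the two level estimators.

From allele-assigned reads, every shared cytosine site accumulates a
methylated count C_i (read base C) and an unmethylated count T_i (read
base T); A/G observations are sequencing errors and are tallied
separately. Two estimators summarise a set of sites:

* weighted methylation level  M = sum_i C_i / sum_i (C_i + T_i),
  the per-individual, per-allele, per-motif statistic of the cross
  analysis (coverage-weighted);
* fractional methylation level, the unweighted mean of per-site
  ratios C_i/(C_i+T_i), used for the region-level comparison of
  wild type against epigenetic-regulation mutants.

The two agree exactly when all sites have identical coverage. Motif
contexts always come from the reference annotation, never from the
(conversion-distorted) reads.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import CONTEXTS, CytosineSite
from .reads import AssignedRead, COL, LER

logger = logging.getLogger(__name__)

#: Accepted spellings of the non-CpG contexts in external site tables.
CONTEXT_ALIASES = {
    "CPG": "CpG",
    "CG": "CpG",
    "CHG": "CpHpG",
    "CPHPG": "CpHpG",
    "CHH": "CpHpH",
    "CPHPH": "CpHpH",
}


def normalize_context(value: str) -> str | None:
    return CONTEXT_ALIASES.get(str(value).strip().upper())


def extract_calls(
    assigned: Iterable[AssignedRead],
    shared_sites: Sequence[CytosineSite],
    individual: str = "",
) -> pd.DataFrame:
    """Tally per-site methylation counts from allele-assigned reads.

    Returns one row per allele x shared site with columns
    ``n_meth`` (C_i), ``n_unmeth`` (T_i) and ``n_other`` (A/G
    sequencing-error observations, excluded from both counts). Sites a
    read does not span contribute nothing.
    """
    context_of = {s.position: s.context for s in shared_sites}
    counts: dict[tuple[str, int], list[int]] = {}
    for read in assigned:
        if read.allele not in (COL, LER):
            continue
        for pos, base in read.site_bases.items():
            key = (read.allele, pos)
            c = counts.setdefault(key, [0, 0, 0])
            if base == "C":
                c[0] += 1
            elif base == "T":
                c[1] += 1
            else:
                c[2] += 1
    rows = []
    for (allele, pos), (n_meth, n_unmeth, n_other) in sorted(counts.items()):
        rows.append(
            {
                "individual": individual,
                "allele": allele,
                "position": pos,
                "context": context_of[pos],
                "n_meth": n_meth,
                "n_unmeth": n_unmeth,
                "n_other": n_other,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual",
            "allele",
            "position",
            "context",
            "n_meth",
            "n_unmeth",
            "n_other",
        ],
    )


def weighted_methylation(counts: Iterable[tuple[float, float]]) -> float:
    """Weighted methylation level over (C_i, T_i) site counts.

    Returns NaN (undefined) when total coverage is zero; such levels
    are excluded from population summaries.
    """
    c_sum = 0.0
    total = 0.0
    for c_i, t_i in counts:
        if c_i < 0 or t_i < 0:
            raise ValueError("negative counts")
        c_sum += c_i
        total += c_i + t_i
    if total == 0:
        return float("nan")
    return c_sum / total


def fractional_methylation(per_site_levels: Iterable[float]) -> float:
    """Unweighted mean of per-site methylation ratios.

    Zero-coverage sites must already be excluded (NaN entries are
    ignored); an empty set gives NaN.
    """
    levels = [x for x in per_site_levels if not np.isnan(x)]
    if not levels:
        return float("nan")
    return float(np.mean(levels))


def methylation_levels(site_counts: pd.DataFrame) -> pd.DataFrame:
    """Weighted methylation per individual x allele x motif.

    Output is the long-format per-individual table (individual,
    allele, motif, level, n_sites, coverage); groups with zero
    coverage get a NaN level.
    """
    rows = []
    if site_counts.empty:
        return pd.DataFrame(
            columns=["individual", "allele", "motif", "level", "n_sites", "coverage"]
        )
    for (ind, allele, motif), grp in site_counts.groupby(
        ["individual", "allele", "context"], sort=True
    ):
        coverage = int((grp["n_meth"] + grp["n_unmeth"]).sum())
        level = weighted_methylation(zip(grp["n_meth"], grp["n_unmeth"]))
        rows.append(
            {
                "individual": ind,
                "allele": allele,
                "motif": motif,
                "level": level,
                "n_sites": len(grp),
                "coverage": coverage,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# External per-site methylation tables (mutant methylome comparison)
# ---------------------------------------------------------------------------


def ingest_sitetable(
    path: str | Path,
    chrom: str,
    start: int,
    end: int,
) -> pd.DataFrame:
    """Read a per-site methylation TSV restricted to one region.

    Expected columns (tab-separated, header optional):
    chromosome, 1-based position, context, methylated count, total
    count. Context accepts CpG/CHG/CHH or CpG/CpHpG/CpHpH spellings.
    Rows outside ``chrom:start..end`` (1-based inclusive) are dropped;
    malformed rows are skipped with a warning; duplicate positions keep
    the last row seen. Zero-coverage rows get a NaN level so the
    fractional mean skips them.
    """
    if end < start:
        raise ValueError(f"empty coordinate span {start}..{end}")
    by_pos: dict[int, dict] = {}
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            try:
                row_chrom = parts[0].strip()
                pos = int(parts[1])
                context = normalize_context(parts[2])
                n_meth = int(parts[3])
                total = int(parts[4])
                if context is None or n_meth < 0 or total < n_meth:
                    raise ValueError
            except (ValueError, IndexError):
                if lineno == 1:
                    continue  # header
                n_bad += 1
                continue
            if row_chrom != chrom or not start <= pos <= end:
                continue
            if pos in by_pos:
                logger.warning("%s: duplicate position %d, keeping last", path, pos)
            by_pos[pos] = {
                "chrom": row_chrom,
                "position": pos,
                "context": context,
                "n_meth": n_meth,
                "total": total,
                "level": n_meth / total if total > 0 else float("nan"),
            }
    if n_bad:
        logger.warning("%s: skipped %d malformed row(s)", path, n_bad)
    return pd.DataFrame(
        sorted(by_pos.values(), key=lambda r: r["position"]),
        columns=["chrom", "position", "context", "n_meth", "total", "level"],
    )


def region_fractional_levels(site_table: pd.DataFrame) -> dict[str, float]:
    """Fractional methylation per motif from an ingested site table."""
    out = {}
    for motif in CONTEXTS:
        grp = site_table.loc[site_table["context"] == motif, "level"]
        out[motif] = fractional_methylation(grp)
    return out
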