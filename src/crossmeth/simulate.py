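"""Seeded bisulfite amplicon read simulator for the full cross design.

The study's MiSeq reads are not deposited, so this generator emulates
their structure with known ground truth: two parental strains (Col,
Ler), reciprocal F1 populations, and four selfed F2 populations; two
amplicon regions per individual; per-allele per-motif methylation
probabilities; bisulfite conversion chemistry and sequencing error.

Model
-----
* Pedigree: parents are homozygous (CC or LL), every F1 individual is
  CL, and each F2 individual is drawn i.i.d. from the Mendelian
  (0.25, 0.5, 0.25) genotype distribution.
* Methylation: each individual x allele x motif receives one
  methylation probability drawn from a beta law whose mean and s.d.
  are population-level hyperparameters; that probability applies to
  every cytosine of that motif on that allele. In heterozygotes the
  two alleles' draws are coupled through a Gaussian copula whose
  correlation is calibrated (r = 2 sin(pi*rho/6)) so the population
  Spearman rank correlation equals ``rho`` exactly.
* Chemistry: an unmethylated C is read as T with probability
  ``conversion_efficiency`` (else C); a methylated C is read as C with
  probability ``methylated_protection`` (else T). Uniform substitution
  errors are applied at ``seq_error`` per base. Fragments span the
  whole amplicon; mates of ``read_length`` cover its two ends (R2 is
  reverse-complemented, Illumina style). Qualities are constant Q37
  except error-injected bases (Q12).

Methylation state is drawn independently per fragment per site; the
weighted methylation level aggregates counts and is insensitive to
within-molecule correlation, so no epihaplotype structure is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import COL, LER, CONTEXTS, Region

logger = logging.getLogger(__name__)

GENOTYPES = ("CC", "CL", "LL")
#: Mendelian F2 segregation probabilities for (CC, CL, LL).
SEGREGATION = (0.25, 0.5, 0.25)

_ALLELES_OF = {"CC": (COL,), "CL": (COL, LER), "LL": (LER,)}


class ConfigError(ValueError):
    """Invalid simulation design or hyperparameters."""


# ---------------------------------------------------------------------------
# Cross design (sample sizes of the amplicon-seq experiment)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Population:
    """One sampled population of the crossing experiment.

    ``maternal`` names the seed parent of an F1 cross; ``founder``
    names the F1 population whose selfed individual founded an F2
    population.
    """

    label: str
    generation: str  # P / F1 / F2
    n: int
    strain: str | None = None  # parental strain, P only
    maternal: str | None = None  # F1 only
    founder: str | None = None  # F2 only

    def __post_init__(self) -> None:
        if self.generation not in ("P", "F1", "F2"):
            raise ConfigError(f"unknown generation {self.generation!r}")
        if self.n < 1:
            raise ConfigError(f"population {self.label}: n must be >= 1")
        if self.generation == "P" and self.strain not in (COL, LER):
            raise ConfigError(f"parental population {self.label} needs strain Col/Ler")


@dataclass(frozen=True)
class CrossDesign:
    """The set of populations sampled for amplicon sequencing."""

    populations: tuple[Population, ...]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate population labels")
        f1_labels = {p.label for p in self.populations if p.generation == "F1"}
        for p in self.populations:
            if p.generation == "F2" and p.founder not in f1_labels:
                raise ConfigError(
                    f"F2 population {p.label} must reference an F1 founder"
                )

    @property
    def n_individuals(self) -> int:
        return sum(p.n for p in self.populations)

    def individuals(self) -> list[tuple[Population, str]]:
        """(population, individual_id) pairs in fixed design order."""
        out = []
        for pop in self.populations:
            for i in range(1, pop.n + 1):
                out.append((pop, f"{pop.label}_{i:02d}"))
        return out


def default_design() -> CrossDesign:
    """The study's sampling design: 2+2 parents, reciprocal F1 (18, 19),
    four selfed F2 populations (30, 28, 30, 30)."""
    return CrossDesign(
        populations=(
            Population("Col", "P", 2, strain=COL),
            Population("Ler", "P", 2, strain=LER),
            Population("F1_ColxLer", "F1", 18, maternal=COL),
            Population("F1_LerxCol", "F1", 19, maternal=LER),
            Population("F2_ColxLer_i2", "F2", 30, founder="F1_ColxLer"),
            Population("F2_ColxLer_i4", "F2", 28, founder="F1_ColxLer"),
            Population("F2_LerxCol_i3", "F2", 30, founder="F1_LerxCol"),
            Population("F2_LerxCol_i4", "F2", 30, founder="F1_LerxCol"),
        )
    )


# ---------------------------------------------------------------------------
# Methylation hyperparameters
# ---------------------------------------------------------------------------


def beta_shapes(mean: float, sd: float | None, point_nu: float = 1000.0):
    """Beta shape pair (alpha, beta) from a mean and standard deviation.

    ``sd=None`` (or 0) yields a near-point-mass law with concentration
    ``point_nu``, used for parental lines whose dispersion is not
    estimable from two individuals.
    """
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta mean {mean} outside (0, 1)")
    if sd is None or sd == 0.0:
        nu = point_nu
    else:
        var = sd * sd
        if var >= mean * (1 - mean):
            raise ConfigError(f"sd {sd} too large for mean {mean}")
        nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


@dataclass(frozen=True)
class MethylationProfile:
    """Population-level methylation hyperparameters for one region.

    ``levels`` maps (group, allele, motif) to a (mean, sd) pair, where
    group is one of P, F1, F2_CC, F2_CL, F2_LL and sd may be None for a
    near-fixed level. ``rho`` maps each motif to the heterozygote
    coupling in [-1, 1]: the Spearman rank correlation between the two
    alleles' individual-level draws.
    """

    region_id: str
    levels: Mapping[tuple[str, str, str], tuple[float, float | None]]
    rho: Mapping[str, float]

    def __post_init__(self) -> None:
        for motif, r in self.rho.items():
            if not -1.0 <= r <= 1.0:
                raise ConfigError(f"rho[{motif}]={r} outside [-1, 1]")
        for key, (mean, sd) in self.levels.items():
            beta_shapes(mean, sd)  # validates

    def shapes(self, group: str, allele: str, motif: str):
        mean, sd = self.levels[(group, allele, motif)]
        return beta_shapes(mean, sd)


def _grid(groups_alleles, motif_rows):
    """Expand {(group, allele): [(mean, sd) per motif]} to a levels dict."""
    levels = {}
    for (group, allele), rows in groups_alleles.items():
        for motif, ms in zip(CONTEXTS, rows):
            levels[(group, allele, motif)] = ms
    return levels


def default_profiles() -> dict[str, MethylationProfile]:
    """Default hyperparameters for the two regions.

    Means and standard deviations reproduce the per-population,
    per-allele, per-motif summary of the amplicon-seq experiment
    (CpG, CpHpG, CpHpH order). Region 1 is the labile NUMT whose
    methylation collapses in F1 and rediversifies in F2; region 2 is
    the stable one. Heterozygote coupling for region 1 follows the
    trans-allelic rank correlations observed in F2 heterozygotes
    (0.57 / 0.75 / 0.97); no correlation was reported for region 2.
    """
    region1 = _grid(
        {
            ("P", COL): [(0.67, None), (0.38, None), (0.18, None)],
            ("P", LER): [(0.01, None), (0.01, None), (0.01, None)],
            ("F1", COL): [(0.42, 0.070), (0.12, 0.043), (0.02, 0.007)],
            ("F1", LER): [(0.05, 0.031), (0.02, 0.014), (0.01, 0.003)],
            ("F2_CC", COL): [(0.80, 0.080), (0.45, 0.110), (0.28, 0.110)],
            ("F2_CL", COL): [(0.61, 0.150), (0.24, 0.130), (0.11, 0.097)],
            ("F2_CL", LER): [(0.28, 0.200), (0.16, 0.130), (0.10, 0.100)],
            ("F2_LL", LER): [(0.21, 0.240), (0.13, 0.170), (0.11, 0.140)],
        },
        CONTEXTS,
    )
    region2 = _grid(
        {
            ("P", COL): [(0.86, None), (0.51, None), (0.08, None)],
            ("P", LER): [(0.61, None), (0.24, None), (0.02, None)],
            ("F1", COL): [(0.90, 0.014), (0.52, 0.011), (0.07, 0.007)],
            ("F1", LER): [(0.79, 0.048), (0.41, 0.036), (0.04, 0.009)],
            ("F2_CC", COL): [(0.92, 0.013), (0.51, 0.032), (0.06, 0.008)],
            ("F2_CL", COL): [(0.92, 0.014), (0.50, 0.034), (0.07, 0.009)],
            ("F2_CL", LER): [(0.90, 0.029), (0.47, 0.038), (0.06, 0.008)],
            ("F2_LL", LER): [(0.91, 0.022), (0.47, 0.040), (0.06, 0.011)],
        },
        CONTEXTS,
    )
    return {
        "region1": MethylationProfile(
            "region1",
            region1,
            rho={"CpG": 0.57, "CpHpG": 0.75, "CpHpH": 0.97},
        ),
        "region2": MethylationProfile(
            "region2",
            region2,
            rho={"CpG": 0.0, "CpHpG": 0.0, "CpHpH": 0.0},
        ),
    }


# ---------------------------------------------------------------------------
# Simulation parameters and truth record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """Read-generation parameters.

    coverage
        Mean number of fragments per individual per region (Poisson).
        The experiment mapped over 40,000 reads per individual; the
        default mirrors that scale and tests dial it down.
    conversion_efficiency
        Probability that an unmethylated C is read as T.
    methylated_protection
        Probability that a methylated C is read as C.
    seq_error
        Per-base uniform substitution error rate.
    read_length
        Length of each mate (paired 150 x 2 by default).
    """

    coverage: float = 50_000
    conversion_efficiency: float = 0.99
    methylated_protection: float = 1.0
    seq_error: float = 0.001
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "methylated_protection", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if self.read_length < 1:
            raise ConfigError("read_length must be >= 1")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated reads.

    ``genotypes``: one row per individual (population, generation,
    genotype). ``profiles``: one row per individual x region x allele x
    motif with the drawn methylation probability. Every read id embeds
    its individual, region, fragment index and source allele, so each
    emitted read is traceable.
    """

    genotypes: pd.DataFrame
    profiles: pd.DataFrame
    seed: int

    def genotype_of(self, individual: str) -> str:
        row = self.genotypes.loc[self.genotypes["individual"] == individual]
        return row["genotype"].iloc[0]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.genotypes.to_csv(outdir / "truth_genotypes.tsv", sep="\t", index=False)
        self.profiles.to_csv(outdir / "truth_profiles.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pedigree and profile draws
# ---------------------------------------------------------------------------


def simulate_pedigree(
    design: CrossDesign, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw genotypes for every individual of the design.

    Parents are homozygous for their strain, F1 individuals are all CL,
    and each F2 individual is i.i.d. Mendelian (0.25, 0.5, 0.25).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for pop, ind in design.individuals():
        if pop.generation == "P":
            genotype = "CC" if pop.strain == COL else "LL"
        elif pop.generation == "F1":
            genotype = "CL"
        else:
            genotype = GENOTYPES[rng.choice(3, p=SEGREGATION)]
        rows.append(
            {
                "individual": ind,
                "population": pop.label,
                "generation": pop.generation,
                "genotype": genotype,
            }
        )
    return pd.DataFrame(rows)


def _group_of(generation: str, genotype: str) -> str:
    return generation if generation in ("P", "F1") else f"F2_{genotype}"


def draw_individual_profiles(
    generation: str,
    genotypes: Sequence[str],
    profile: MethylationProfile,
    seed: int | np.random.Generator,
) -> list[dict[str, dict[str, float]]]:
    """Draw per-individual, per-allele, per-motif methylation probabilities.

    Homozygotes receive one beta draw per motif for their single
    allele. Heterozygotes receive a coupled pair per motif: a Gaussian
    copula with correlation 2 sin(pi*rho/6) feeds the two alleles' beta
    marginals, so the rank correlation of the pair equals ``rho``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[dict[str, dict[str, float]]] = []
    for genotype in genotypes:
        group = _group_of(generation, genotype)
        drawn: dict[str, dict[str, float]] = {a: {} for a in _ALLELES_OF[genotype]}
        if genotype == "CL":
            for motif in CONTEXTS:
                rho = profile.rho[motif]
                r = 2.0 * np.sin(np.pi * rho / 6.0)
                z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]])
                u = stats.norm.cdf(z)
                for allele, ui in zip((COL, LER), u):
                    a, b = profile.shapes(group, allele, motif)
                    drawn[allele][motif] = float(stats.beta.ppf(ui, a, b))
        else:
            allele = _ALLELES_OF[genotype][0]
            for motif in CONTEXTS:
                a, b = profile.shapes(group, allele, motif)
                drawn[allele][motif] = float(rng.beta(a, b))
        out.append(drawn)
    return out


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(128, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b

QUAL_HIGH = chr(37 + 33)  # Q37
QUAL_ERR = chr(12 + 33)  # Q12


@dataclass(frozen=True)
class ReadPair:
    """One simulated fragment's mates (sequences plus Phred+33 quality)."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    allele: str


def _site_probability_vector(
    region: Region, allele: str, motif_probs: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based) of all Cs on the allele and their methylation
    probabilities. Cytosines whose context is unresolvable get probability
    0 (they behave as unmethylated)."""
    seq = region.allele_ref(allele).sequence
    c_pos = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("C"))
    prob_by_pos = {s.position - 1: motif_probs[s.context] for s in region.allele_sites(allele)}
    probs = np.array([prob_by_pos.get(int(i), 0.0) for i in c_pos])
    return c_pos, probs


def simulate_reads(
    individual: str,
    genotype: str,
    region: Region,
    motif_probs: Mapping[str, Mapping[str, float]],
    params: SimParams,
    rng: np.random.Generator,
) -> list[ReadPair]:
    """Generate paired bisulfite reads for one individual and one region.

    Each fragment picks an allele (uniformly for heterozygotes), draws
    a methylation state per cytosine, applies conversion chemistry and
    uniform sequencing errors, and is read from both ends. Reads longer
    than the amplicon are truncated to it.
    """
    amplicon_len = region.length
    read_len = params.read_length
    if read_len > amplicon_len:
        logger.warning(
            "%s/%s: read length %d exceeds amplicon length %d; reads truncated",
            individual,
            region.region_id,
            read_len,
            amplicon_len,
        )
        read_len = amplicon_len
    return _simulate_reads_clamped(
        individual, genotype, region, motif_probs, params, rng, read_len
    )


def _simulate_reads_clamped(
    individual: str,
    genotype: str,
    region: Region,
    motif_probs: Mapping[str, Mapping[str, float]],
    params: SimParams,
    rng: np.random.Generator,
    read_len: int,
) -> list[ReadPair]:
    amplicon_len = region.length

    alleles = _ALLELES_OF[genotype]
    n_frag = int(rng.poisson(params.coverage))
    if len(alleles) == 2:
        allele_idx = rng.integers(0, 2, size=n_frag)
    else:
        allele_idx = np.zeros(n_frag, dtype=np.int64)

    pairs: list[ReadPair] = []
    frag_no = np.arange(n_frag)
    for ai, allele in enumerate(alleles):
        sel = np.flatnonzero(allele_idx == ai)
        if sel.size == 0:
            continue
        n = sel.size
        ref_codes = np.frombuffer(
            region.allele_ref(allele).sequence.encode(), dtype=np.uint8
        )
        c_pos, c_probs = _site_probability_vector(region, allele, motif_probs[allele])

        frags = np.tile(ref_codes, (n, 1))
        if c_pos.size:
            meth = rng.random((n, c_pos.size)) < c_probs
            as_c = np.where(
                meth,
                rng.random((n, c_pos.size)) < params.methylated_protection,
                rng.random((n, c_pos.size)) >= params.conversion_efficiency,
            )
            frags[:, c_pos] = np.where(as_c, ord("C"), ord("T"))
        err = rng.random((n, amplicon_len)) < params.seq_error
        if err.any():
            # uniform substitution to one of the three other bases
            shift = rng.integers(1, 4, size=int(err.sum()))
            idx = (frags[err] == _BASES[:, None]).argmax(axis=0)
            frags[err] = _BASES[(idx + shift) % 4]

        r1 = frags[:, :read_len]
        r2 = frags[:, amplicon_len - read_len :][:, ::-1]
        r2 = _COMPLEMENT[r2]
        e1 = err[:, :read_len]
        e2 = err[:, amplicon_len - read_len :][:, ::-1]

        for row, (i1, i2, er1, er2) in enumerate(zip(r1, r2, e1, e2)):
            frag_id = frag_no[sel[row]]
            rid = f"{individual}:{region.region_id}:{frag_id:06d}:{allele}"
            pairs.append(
                ReadPair(
                    read_id=rid,
                    seq1=i1.tobytes().decode(),
                    qual1="".join(QUAL_ERR if e else QUAL_HIGH for e in er1),
                    seq2=i2.tobytes().decode(),
                    qual2="".join(QUAL_ERR if e else QUAL_HIGH for e in er2),
                    allele=allele,
                )
            )
    pairs.sort(key=lambda p: p.read_id)
    return pairs


def write_fastq_pair(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write mates to two Phred+33 FASTQ files."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def simulate_dataset(
    design: CrossDesign,
    regions: Sequence[Region],
    profiles: Mapping[str, MethylationProfile],
    params: SimParams,
    outdir: str | Path,
) -> SimTruth:
    """Simulate the whole experiment to FASTQ files plus ground truth.

    One R1/R2 FASTQ pair per individual (named
    ``<population>_<individual>_R{1,2}.fastq``) containing both
    regions' reads, exactly as a demultiplexed sample would. Fully
    deterministic for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    genotypes = simulate_pedigree(design, rng)

    read_len_by_region = {}
    for region in regions:
        rl = min(params.read_length, region.length)
        if rl < params.read_length:
            logger.warning(
                "%s: read length %d exceeds amplicon length %d; reads truncated",
                region.region_id,
                params.read_length,
                region.length,
            )
        read_len_by_region[region.region_id] = rl

    profile_rows = []
    geno_by_ind = dict(zip(genotypes["individual"], genotypes["genotype"]))
    for pop, ind in design.individuals():
        genotype = geno_by_ind[ind]
        pairs: list[ReadPair] = []
        for region in regions:
            drawn = draw_individual_profiles(
                pop.generation, [genotype], profiles[region.region_id], rng
            )[0]
            for allele, by_motif in drawn.items():
                for motif, p in by_motif.items():
                    profile_rows.append(
                        {
                            "individual": ind,
                            "region": region.region_id,
                            "allele": allele,
                            "motif": motif,
                            "probability": p,
                        }
                    )
            pairs.extend(
                _simulate_reads_clamped(
                    ind, genotype, region, drawn, params, rng,
                    read_len_by_region[region.region_id],
                )
            )
        write_fastq_pair(
            pairs, outdir / f"{ind}_R1.fastq", outdir / f"{ind}_R2.fastq"
        )
    truth = SimTruth(
        genotypes=genotypes,
        profiles=pd.DataFrame(profile_rows),
        seed=params.seed,
    )
    truth.write(outdir)
    return truth


def expected_observed_level(p: float, params: SimParams) -> float:
    """Expected apparent methylation of a site with true probability ``p``:
    methylated Cs survive with the protection rate and unmethylated Cs
    escape conversion at 1 - efficiency."""
    return p * params.methylated_protection + (1 - p) * (
        1 - params.conversion_efficiency
    )
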