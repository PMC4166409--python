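"""Seeded synthetic breeding-population generator.

Emulates the statistical structure the downstream analysis assumes: two
subpopulations of fully inbred advanced breeding lines (default n = 132 and
138), tens of thousands of biallelic SNPs with MAF above a floor, strong
within-panel relatedness, block LD that decays with physical distance, and a
handful of planted additive QTL acting on a bounded 1-5 chlorosis score.

LD is produced by a two-level haplotype-copying (mosaic) process.  Founder
haplotypes are piecewise-constant over haplotype blocks (block boundaries
placed at half the per-bp switch rate) with a small per-marker flip noise, so
markers inside a block are in strong LD on the founders themselves.  Each
line's single haplotype (doubled, since lines are inbred) is then a mosaic
over its subpopulation's founder pool, switching founders between adjacent
markers at the other half of the rate.  Subpopulation differentiation comes
from disjoint founder pools whose block frequencies are drawn around a shared
base frequency with a Balding-Nichols spread (F_ST-like parameter).  With the
default rate of 2.5e-7/bp this yields pairwise partial r^2 near 0.7 at
~500 kb, decaying monotonically with distance.

A companion generator builds a reference genome plus GFF3 gene models
(exon/intron/UTR/CDS on both strands, CDS translatable without internal
stops) for exercising the variant annotator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from idcgwas.genio import MARKER_COLUMNS, GenotypeMatrix, PhenotypeTable

_BASES = np.array(list("ACGT"))
# per-founder, per-marker probability of deviating from the block allele state;
# sets the within-block LD ceiling at roughly (1 - 2*rate)^2
FOUNDER_FLIP_RATE = 0.015
# purine<->purine / pyrimidine<->pyrimidine partner of each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic breeding panel.

    Defaults reproduce the target population: 132 + 138 lines, 20 chromosomes,
    ~34k post-filter markers, baseline IDC 2.76 on the 1-5 scale, residual SD
    0.30 IDC units, planted additive effects supplied via ``qtl_spec`` as
    (chromosome, position, additive effect[, variant-allele frequency]).
    """

    seed: int = 0
    n_per_subpop: tuple[int, int] = (132, 138)
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    n_markers: int = 34_000
    founder_haplotypes_per_subpop: int = 8
    copy_switch_rate_per_bp: float = 2.5e-7
    maf_floor: float = 0.05
    missing_rate: float = 0.10
    qtl_spec: list[tuple] = field(default_factory=list)
    subpop_shift: float = 0.10
    residual_sd: float = 0.30
    baseline: float = 2.76
    fst: float = 0.10

    def validate(self) -> None:
        for name in ("copy_switch_rate_per_bp", "maf_floor", "missing_rate", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        if min(self.n_per_subpop) < 1 or self.n_chromosomes < 1 or self.n_markers < 1:
            raise ValueError("population and marker counts must be positive")
        if self.founder_haplotypes_per_subpop < 2:
            raise ValueError("need at least 2 founder haplotypes per subpopulation")
        for q in self.qtl_spec:
            if not np.isfinite(q[2]):
                raise ValueError(f"non-finite QTL effect in {q}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthRecord:
    """Planted-QTL ground truth for parameter-recovery tests."""

    marker_id: str
    chrom: str
    pos: int
    effect: float
    freq_subpop_a: float
    freq_subpop_b: float


def _streams(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def chrom_name(i: int) -> str:
    return f"Gm{i + 1:02d}"


def marker_positions(config: SimConfig) -> dict[str, np.ndarray]:
    """Deterministic 1-based marker positions per chromosome for ``config``.

    Pure function of (seed, layout fields) so callers can place QTL on real
    marker positions before running :func:`simulate_population`.
    """
    config.validate()
    rng = _streams(config.seed)[0]
    base, extra = divmod(config.n_markers, config.n_chromosomes)
    positions: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        m_c = base + (1 if c < extra else 0)
        if m_c > config.chrom_length_bp:
            raise ValueError("chromosome too short for requested marker count")
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=m_c))
        while pos.size < m_c:  # top up duplicate draws
            more = rng.integers(1, config.chrom_length_bp + 1, size=m_c - pos.size)
            pos = np.unique(np.concatenate([pos, more]))
        positions[chrom_name(c)] = pos
    return positions


def nearest_marker_position(config: SimConfig, chrom: str, pos: int) -> int:
    """Marker position on ``chrom`` closest to ``pos`` (for placing QTL)."""
    p = marker_positions(config)[chrom]
    return int(p[np.argmin(np.abs(p - pos))])


# eight-QTL additive-effect profile at study scale: |effect| 0.13-0.19 IDC
# units, variant-allele frequency 0.2-0.5, one QTL per listed chromosome at
# study-like coordinates
STUDY_QTL_PROFILE = (
    ("Gm03", 45_030_000, -0.19, 0.39),
    ("Gm05", 8_880_000, 0.13, 0.46),
    ("Gm07", 6_400_000, -0.16, 0.26),
    ("Gm11", 530_000, 0.18, 0.20),
    ("Gm16", 27_300_000, 0.18, 0.27),
    ("Gm17", 25_860_000, 0.15, 0.35),
    ("Gm18", 28_140_000, 0.13, 0.23),
    ("Gm19", 40_190_000, -0.18, 0.44),
)


def study_qtl_spec(config: SimConfig) -> list[tuple]:
    """The eight-QTL study profile snapped to actual marker positions of ``config``."""
    positions = marker_positions(config)
    spec = []
    for chrom, approx, effect, freq in STUDY_QTL_PROFILE:
        if chrom not in positions:
            raise ValueError(f"config has no chromosome {chrom}")
        p = positions[chrom]
        snapped = int(p[np.argmin(np.abs(p - min(approx, config.chrom_length_bp)))])
        spec.append((chrom, snapped, effect, freq))
    return spec


def simulate_population(
    config: SimConfig, reference: dict[str, str] | None = None
) -> tuple[GenotypeMatrix, PhenotypeTable, list[TruthRecord]]:
    """Simulate genotypes, phenotypes and the planted-QTL truth list.

    All lines are fully inbred: dosages are 0 or 2 before missingness is
    applied.  Phenotype = baseline + subpop_shift * I(subpop B)
    + sum_i effect_i * (dosage_i - 1) + Normal(0, residual_sd), clipped to
    [1, 5] (half-difference coding: homozygous reference scores -effect,
    homozygous variant +effect).  If ``reference`` (chrom -> sequence) is
    given, REF alleles are taken from it so the panel can be annotated against
    that genome.
    """
    config.validate()
    _, rng_founder, rng_mosaic, rng_missing, rng_noise, rng_allele = _streams(config.seed, 8)[:6]
    positions = marker_positions(config)
    chroms = list(positions)
    n_a, n_b = config.n_per_subpop
    n = n_a + n_b
    n_f = config.founder_haplotypes_per_subpop

    qtl_by_chrom: dict[str, list[tuple[int, float, float | None]]] = {}
    for q in config.qtl_spec:
        chrom, pos, effect = q[0], int(q[1]), float(q[2])
        freq = float(q[3]) if len(q) > 3 else None
        if chrom not in positions or pos not in positions[chrom]:
            raise ValueError(
                f"QTL position {chrom}:{pos} does not match any simulated marker; "
                "use marker_positions()/nearest_marker_position() to place it"
            )
        qtl_by_chrom.setdefault(chrom, []).append((pos, effect, freq))

    dosage_cols, marker_rows = [], []
    truth: list[TruthRecord] = []
    genetic = np.zeros(n)
    half_rate = 0.5 * config.copy_switch_rate_per_bp
    for chrom in chroms:
        pos = positions[chrom]
        m_c = pos.size
        gaps = np.diff(pos).astype(float)
        # haplotype blocks: founder alleles are block-constant (plus flip noise)
        boundary = rng_founder.random(m_c - 1) < 1.0 - np.exp(-half_rate * gaps)
        block = np.concatenate([[0], np.cumsum(boundary)])
        n_blocks = int(block[-1]) + 1
        base_f = rng_founder.uniform(config.maf_floor, 1.0 - config.maf_floor, size=n_blocks)
        fst = config.fst
        if fst > 0:
            a = base_f * (1.0 - fst) / fst
            b = (1.0 - base_f) * (1.0 - fst) / fst
            f_pops = rng_founder.beta(a[None, :].repeat(2, 0), b[None, :].repeat(2, 0))
        else:
            f_pops = np.vstack([base_f, base_f])
        qtl_here = {p: (eff, fr) for p, eff, fr in qtl_by_chrom.get(chrom, [])}
        # founder pools: block states per founder, per-marker flip noise
        haps = []
        for k in range(2):
            S = (rng_founder.random((n_f, n_blocks)) < f_pops[k][None, :]).astype(np.int8)
            H = S[:, block]
            flips = rng_founder.random((n_f, m_c)) < FOUNDER_FLIP_RATE
            H = np.where(flips, 1 - H, H)
            haps.append(H)
        # planted QTL: founder columns at the exact target frequency in both
        # pools (shuffled), so the effect is estimable within each subpopulation
        for j, p in enumerate(pos):
            if p in qtl_here and qtl_here[p][1] is not None:
                count = int(np.clip(np.rint(qtl_here[p][1] * n_f), 1, n_f - 1))
                for k in range(2):
                    col = np.zeros(n_f, dtype=np.int8)
                    col[rng_founder.permutation(n_f)[:count]] = 1
                    haps[k][:, j] = col
        # mosaic copying within each subpopulation
        p_sw = 1.0 - np.exp(-half_rate * gaps)
        hap_lines = []
        for k, n_k in enumerate((n_a, n_b)):
            sw = np.empty((n_k, m_c), dtype=bool)
            sw[:, 0] = True
            sw[:, 1:] = rng_mosaic.random((n_k, m_c - 1)) < p_sw[None, :]
            choice = rng_mosaic.integers(0, n_f, size=(n_k, m_c))
            last = np.maximum.accumulate(
                np.where(sw, np.arange(m_c)[None, :], -1), axis=1
            )
            fid = np.take_along_axis(choice, last, axis=1)
            hap_lines.append(haps[k][fid, np.arange(m_c)[None, :]])
        hap = np.vstack(hap_lines)  # (n, m_c) in {0,1}
        dos = 2.0 * hap

        # alleles: REF from reference genome when given, ALT transition-biased
        if reference is not None:
            seq = reference[chrom]
            ref_alleles = np.array([seq[p - 1] for p in pos])
        else:
            ref_alleles = _BASES[rng_allele.integers(0, 4, size=m_c)]
        is_ts = rng_allele.random(m_c) < 0.625  # yields Ts/Tv near the GBS-typical ~1.67
        alt_alleles = np.empty(m_c, dtype=object)
        for j in range(m_c):
            r = ref_alleles[j]
            if is_ts[j]:
                alt_alleles[j] = _TRANSITION[r]
            else:
                tv = [b for b in "ACGT" if b != r and b != _TRANSITION[r]]
                alt_alleles[j] = tv[rng_allele.integers(0, 2)]

        for j, p in enumerate(pos):
            marker_rows.append((f"{chrom}_{p}", chrom, int(p), ref_alleles[j], alt_alleles[j]))
        # genetic values accumulate before missingness
        for j, p in enumerate(pos):
            if p in qtl_here:
                eff = qtl_here[p][0]
                genetic += eff * (dos[:, j] - 1.0)
                truth.append(
                    TruthRecord(
                        marker_id=f"{chrom}_{p}",
                        chrom=chrom,
                        pos=int(p),
                        effect=eff,
                        freq_subpop_a=float(dos[:n_a, j].mean() / 2.0),
                        freq_subpop_b=float(dos[n_a:, j].mean() / 2.0),
                    )
                )
        dosage_cols.append(dos)

    dosage = np.concatenate(dosage_cols, axis=1)
    if config.missing_rate > 0:
        mask = rng_missing.random(dosage.shape) < config.missing_rate
        dosage = dosage.copy()
        dosage[mask] = np.nan

    samples = np.array(
        [f"A{i + 1:03d}" for i in range(n_a)] + [f"B{i + 1:03d}" for i in range(n_b)],
        dtype=object,
    )
    pops = np.array(["popA"] * n_a + ["popB"] * n_b, dtype=object)
    y = (
        config.baseline
        + config.subpop_shift * (pops == "popB")
        + genetic
        + rng_noise.normal(0.0, config.residual_sd, size=n)
    )
    y = np.clip(y, 1.0, 5.0)

    g = GenotypeMatrix(
        samples=samples,
        markers=pd.DataFrame(marker_rows, columns=MARKER_COLUMNS),
        dosage=dosage,
    )
    pheno = PhenotypeTable(
        pd.DataFrame({"sample": samples, "population": pops, "idc_score": y})
    )
    return g, pheno, truth


def write_truth(truth: list[TruthRecord], path: str) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truth]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference genome + gene models for the annotator
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One single-transcript gene: genomic exon/CDS/UTR layout plus its CDS."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase) in genomic order
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) non-stop codons + TAA."""
    body = []
    while len(body) < n_codons - 2:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def _revcomp(s: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(s).reverse_complement())


def simulate_annotation(
    config: SimConfig, genes_per_chrom: int
) -> tuple[dict[str, str], list[GeneModel]]:
    """Reference sequences and non-overlapping two-exon gene models.

    Each gene has a 5'UTR, a CDS split across two exons at a non-codon
    boundary (exercising CDS phase), one intron and a 3'UTR; strands
    alternate.  CDS lengths are divisible by 3 and translate without internal
    stop codons by construction.
    """
    config.validate()
    if genes_per_chrom < 1:
        raise ValueError("genes_per_chrom must be >= 1")
    rng = _streams(config.seed, 8)[6]
    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    for c in range(config.n_chromosomes):
        chrom = chrom_name(c)
        seq = list(_random_seq(rng, config.chrom_length_bp))
        slot = config.chrom_length_bp // genes_per_chrom
        if slot < 4000:
            raise ValueError(
                f"chromosome length {config.chrom_length_bp} too short for "
                f"{genes_per_chrom} genes (need >= 4 kb per gene)"
            )
        for gidx in range(genes_per_chrom):
            utr5_len = int(rng.integers(80, 250))
            utr3_len = int(rng.integers(80, 250))
            n_codons = int(rng.integers(60, 180))
            cds_seq = _random_cds(rng, n_codons)
            cds_len = len(cds_seq)
            # split CDS off a codon boundary when possible
            cds1_len = int(rng.integers(1, cds_len - 1))
            if cds1_len % 3 == 0 and cds_len > 6:
                cds1_len += 1
            intron_len = int(rng.integers(100, 400))
            span = utr5_len + cds_len + intron_len + utr3_len
            lo = c_start = slot * gidx + 1 + int(rng.integers(0, max(1, slot - span - 10)))
            strand = "+" if (gidx + c) % 2 == 0 else "-"
            gid = f"{chrom}g{gidx + 1:03d}"
            utr5_seq = _random_seq(rng, utr5_len)
            utr3_seq = _random_seq(rng, utr3_len)
            cds1, cds2 = cds_seq[:cds1_len], cds_seq[cds1_len:]
            intron = _random_seq(rng, intron_len)
            if strand == "+":
                genomic = utr5_seq + cds1 + intron + cds2 + utr3_seq
                e1 = (lo, lo + utr5_len + cds1_len - 1)
                e2 = (e1[1] + intron_len + 1, lo + span - 1)
                cds_feats = [
                    (lo + utr5_len, e1[1], 0),
                    (e2[0], e2[0] + len(cds2) - 1, (3 - cds1_len % 3) % 3),
                ]
                utr5_f = [(lo, lo + utr5_len - 1)]
                utr3_f = [(e2[0] + len(cds2), e2[1])]
            else:
                # transcript 5' end sits at the genomic right edge
                genomic = _revcomp(utr5_seq + cds1 + intron + cds2 + utr3_seq)
                hi = lo + span - 1
                e1 = (hi - utr5_len - cds1_len + 1, hi)          # transcript exon 1
                e2 = (lo, lo + len(cds2) + utr3_len - 1)          # transcript exon 2
                cds_feats = [
                    (e2[0] + utr3_len, e2[1], (3 - cds1_len % 3) % 3),
                    (e1[0], hi - utr5_len, 0),
                ]
                utr5_f = [(hi - utr5_len + 1, hi)]
                utr3_f = [(lo, lo + utr3_len - 1)]
                e1, e2 = e2, e1  # store exons in genomic order
            seq[lo - 1 : lo - 1 + span] = list(genomic)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=lo,
                    end=lo + span - 1,
                    exons=sorted([e1, e2]),
                    cds=sorted(cds_feats),
                    utr5=utr5_f,
                    utr3=utr3_f,
                )
            )
        genomes[chrom] = "".join(seq)
    return genomes, genes


def write_fasta(genomes: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene > mRNA > exon/CDS/UTR hierarchy)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mrna = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\tidcgwas\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tidcgwas\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tidcgwas\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.exon{i};Parent={mrna}\n")
            for s, e in g.utr5:
                fh.write(f"{g.chrom}\tidcgwas\tfive_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.utr5;Parent={mrna}\n")
            for i, (s, e, phase) in enumerate(g.cds, 1):
                fh.write(f"{g.chrom}\tidcgwas\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                         f"ID={mrna}.cds;Parent={mrna}\n")
            for s, e in g.utr3:
                fh.write(f"{g.chrom}\tidcgwas\tthree_prime_UTR\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.utr3;Parent={mrna}\n")
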