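"""SNP effect annotation from GFF3 gene models + a reference FASTA.

Sites are classified hierarchically as coding > UTR > intron > intergenic.
Coding sites are resolved to synonymous or non-synonymous by splicing the CDS
in transcript orientation (reverse-complemented on the minus strand),
substituting the variant base into its codon and translating both codons;
start/stop gains and losses fold into non-synonymous.  Transitions
(purine<->purine, pyrimidine<->pyrimidine) and transversions are tabulated
with their ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from idcgwas.genio import GenotypeMatrix

CATEGORIES = ("coding", "utr5", "utr3", "intron", "intergenic")
_SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}  # lower = more severe
_PURINES = frozenset("AG")


@dataclass
class Transcript:
    """Spliced transcript model in genomic coordinates (1-based closed)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]      # genomic order
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


@dataclass
class VariantEffect:
    marker_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    category: str                   # coding/utr5/utr3/intron/intergenic
    coding_subtype: str = "none"    # synonymous/nonsynonymous/none
    ref_aa: str | None = None
    alt_aa: str | None = None
    gene_id: str | None = None
    substitution: str = ""          # transition / transversion


@dataclass
class AnnotationSummary:
    category_counts: dict[str, int]
    transitions: int
    transversions: int

    @property
    def ts_tv_ratio(self) -> float:
        if self.transversions == 0:
            return float("inf")
        return self.transitions / self.transversions


# ---------------------------------------------------------------------------
# Gene-model loading
# ---------------------------------------------------------------------------

def load_gene_models(gff3_path: str) -> list[Transcript]:
    """Parse a GFF3 into transcript models (gene > mRNA > exon/CDS/UTR)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    transcripts: list[Transcript] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(mrna.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        transcripts.append(
            Transcript(
                transcript_id=mrna.id,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                start=mrna.start,
                end=mrna.end,
                exons=sorted(exons),
                cds=sorted(cds),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
        )
    return sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))


def gene_frame(transcripts: list[Transcript]) -> pd.DataFrame:
    """Gene spans (gene_id, chrom, start, end) for region overlap queries."""
    rows = {}
    for t in transcripts:
        g = rows.setdefault(t.gene_id, [t.chrom, t.start, t.end])
        g[1], g[2] = min(g[1], t.start), max(g[2], t.end)
    return pd.DataFrame(
        [(gid, *v) for gid, v in rows.items()],
        columns=["gene_id", "chrom", "start", "end"],
    )


class ReferenceSequence:
    """Thin FASTA accessor (pyfaidx-backed for paths, dict-backed for in-memory)."""

    def __init__(self, source):
        if isinstance(source, dict):
            self._seqs = source
            self._fa = None
        else:
            from pyfaidx import Fasta

            self._fa = Fasta(str(source))
            self._seqs = None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based closed interval."""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1 : end].upper()
        return str(self._fa[chrom][start - 1 : end]).upper()


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def _within(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


class CDSLengthError(ValueError):
    """Spliced CDS length not divisible by 3."""


def _coding_effect(
    t: Transcript, pos: int, ref: str, alt: str, reference: ReferenceSequence
) -> tuple[str, str, str]:
    """(subtype, ref_aa, alt_aa) for a position inside one of t's CDS intervals."""
    parts = [reference.fetch(t.chrom, s, e) for s, e in t.cds]
    spliced = "".join(parts)
    if len(spliced) % 3 != 0:
        raise CDSLengthError(
            f"CDS of {t.transcript_id} has length {len(spliced)} not divisible by 3"
        )
    offset = 0
    idx = None
    for (s, e), part in zip(t.cds, parts):
        if s <= pos <= e:
            idx = offset + (pos - s)
            break
        offset += len(part)
    assert idx is not None
    if t.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
        idx = len(spliced) - 1 - idx
        sub = str(Seq(alt).reverse_complement())
    else:
        sub = alt
    codon_i, within = divmod(idx, 3)
    codon = spliced[3 * codon_i : 3 * codon_i + 3]
    alt_codon = codon[:within] + sub + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    subtype = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return subtype, ref_aa, alt_aa


def classify_site(
    marker_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    transcripts: list[Transcript],
    reference: ReferenceSequence,
) -> VariantEffect:
    """Classify one SNP; the REF allele must match the reference sequence.

    Overlapping transcripts are resolved to the most severe consequence
    (coding > UTR > intron), ties broken by lexicographic transcript id; for
    coding, nonsynonymous outranks synonymous.  A transcript whose spliced CDS
    length is not a multiple of 3 is skipped with a warning.
    """
    genome_base = reference.fetch(chrom, pos, pos)
    if genome_base != ref:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: VCF says {ref!r}, "
            f"genome says {genome_base!r}"
        )
    effect = VariantEffect(
        marker_id=marker_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        category="intergenic",
        substitution=substitution_class(ref, alt),
    )
    best_rank = _SEVERITY["intergenic"]
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        if t.chrom != chrom or not (t.start <= pos <= t.end):
            continue
        if _within(pos, t.cds):
            try:
                subtype, ref_aa, alt_aa = _coding_effect(t, pos, ref, alt, reference)
            except CDSLengthError as exc:
                warnings.warn(str(exc), stacklevel=2)
                continue
            rank = _SEVERITY["coding"]
            better = rank < best_rank or (
                rank == best_rank
                and subtype == "nonsynonymous"
                and effect.coding_subtype != "nonsynonymous"
            )
            if better:
                effect.category = "coding"
                effect.coding_subtype = subtype
                effect.ref_aa, effect.alt_aa = ref_aa, alt_aa
                effect.gene_id = t.gene_id
                best_rank = rank
        elif _within(pos, t.utr5):
            if _SEVERITY["utr5"] < best_rank:
                effect.category, effect.gene_id = "utr5", t.gene_id
                best_rank = _SEVERITY["utr5"]
        elif _within(pos, t.utr3):
            if _SEVERITY["utr3"] < best_rank:
                effect.category, effect.gene_id = "utr3", t.gene_id
                best_rank = _SEVERITY["utr3"]
        else:
            if _SEVERITY["intron"] < best_rank:
                effect.category, effect.gene_id = "intron", t.gene_id
                best_rank = _SEVERITY["intron"]
    return effect


def substitution_class(ref: str, alt: str) -> str:
    """Transition iff both alleles are purines or both pyrimidines."""
    return "transition" if (ref in _PURINES) == (alt in _PURINES) else "transversion"


def annotate(
    g: GenotypeMatrix,
    transcripts: list[Transcript],
    reference: ReferenceSequence,
) -> tuple[pd.DataFrame, AnnotationSummary]:
    """Classify every marker and tabulate categories and Ts/Tv counts."""
    effects = []
    for row in g.markers.itertuples(index=False):
        effects.append(
            classify_site(row.id, row.chrom, int(row.pos), row.ref, row.alt,
                          transcripts, reference)
        )
    frame = pd.DataFrame(
        {
            "id": [e.marker_id for e in effects],
            "chrom": [e.chrom for e in effects],
            "pos": [e.pos for e in effects],
            "category": [e.category for e in effects],
            "coding_subtype": [e.coding_subtype for e in effects],
            "ref_aa": [e.ref_aa for e in effects],
            "alt_aa": [e.alt_aa for e in effects],
            "gene_id": [e.gene_id for e in effects],
            "substitution": [e.substitution for e in effects],
        }
    )
    return frame, ts_tv(frame)


def ts_tv(effects: pd.DataFrame | None = None,
          ref: np.ndarray | None = None, alt: np.ndarray | None = None) -> AnnotationSummary:
    """Summary counts from an effect table, or from raw ref/alt allele arrays."""
    if effects is not None:
        subs = effects["substitution"].to_numpy()
        cats = effects["category"].value_counts().to_dict()
    else:
        if ref is None or alt is None:
            raise ValueError("supply an effect table or ref+alt allele arrays")
        subs = np.array([substitution_class(r, a) for r, a in zip(ref, alt)])
        cats = {}
    return AnnotationSummary(
        category_counts={c: int(cats.get(c, 0)) for c in CATEGORIES},
        transitions=int(np.sum(subs == "transition")),
        transversions=int(np.sum(subs == "transversion")),
    )
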