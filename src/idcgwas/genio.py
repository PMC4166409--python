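"""Genotype/phenotype I/O, MAF filtering, mode imputation and LS-mean phenotype adjustment.

The central container is :class:`GenotypeMatrix`: a samples x markers matrix of
variant-allele dosages (0/1/2, NaN for missing) with per-marker metadata
(chromosome, 1-based position, REF/ALT alleles, id).  Every downstream stage of
the pipeline consumes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]
_VALID_ALLELES = frozenset("ACGT")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """Samples x markers variant-allele dosage matrix with marker metadata.

    Attributes
    ----------
    samples : ndarray of str, shape (n,)
    markers : DataFrame with columns id, chrom, pos (1-based int), ref, alt,
        sorted by (chrom, pos), positions unique within chromosome.
    dosage : float ndarray, shape (n, m); values in {0, 1, 2} or NaN (missing).
    """

    samples: np.ndarray
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        self.markers = self.markers.reset_index(drop=True)
        self._validate_markers()

    def _validate_markers(self) -> None:
        mk = self.markers
        missing_cols = set(MARKER_COLUMNS) - set(mk.columns)
        if missing_cols:
            raise DataError(f"marker table lacks columns {sorted(missing_cols)}")
        for col in ("ref", "alt"):
            bad = ~mk[col].isin(_VALID_ALLELES)
            if bad.any():
                raise DataError(f"non-ACGT {col} allele at marker {mk.loc[bad, 'id'].iloc[0]}")
        dup = mk.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = mk[dup].iloc[0]
            raise DataError(f"duplicate position {row.chrom}:{row.pos}")
        order = mk.sort_values(["chrom", "pos"], kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(len(mk))):
            raise DataError("markers must be sorted by (chromosome, position)")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by positional index (order preserved)."""
        return GenotypeMatrix(
            samples=self.samples,
            markers=self.markers.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, computed on non-missing calls."""
        d = self.dosage
        called = 2.0 * np.sum(~np.isnan(d), axis=0)
        alt = np.nansum(d, axis=0)
        # minor count before division keeps MAF == cutoff comparisons exact
        with np.errstate(invalid="ignore"):
            return np.minimum(alt, called - alt) / called

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def summary(self) -> pd.DataFrame:
        """Per-marker summary: MAF, missing fraction, call count."""
        return pd.DataFrame(
            {
                "id": self.markers["id"],
                "maf": self.maf(),
                "missing_fraction": self.missing_fraction(),
                "call_count": np.sum(~np.isnan(self.dosage), axis=0).astype(int),
            }
        )


@dataclass
class PhenotypeTable:
    """Per-sample IDC scores (1-5 visual scale) with population labels.

    ``adjusted`` holds least-squares-mean adjusted scores (populations shifted
    to the grand mean); it equals ``raw`` until :func:`adjust_phenotype` runs.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("sample", "population", "idc_score")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise DataError(f"phenotype table lacks column {col!r}")
        if "adjusted" not in t.columns:
            t = t.assign(adjusted=t["idc_score"].astype(float))
        scores = t["idc_score"].to_numpy(dtype=float)
        if np.any(scores < 1.0) or np.any(scores > 5.0):
            raise DataError("IDC scores must lie on the 1-5 scale")
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> np.ndarray:
        return self.table["sample"].to_numpy(dtype=object)

    def aligned_to(self, g: GenotypeMatrix) -> "PhenotypeTable":
        """Reorder/subset to match ``g.samples``; error on samples absent from the table."""
        t = self.table.set_index("sample")
        missing = [s for s in g.samples if s not in t.index]
        if missing:
            raise DataError(f"phenotypes missing for samples {missing[:5]}")
        return PhenotypeTable(t.loc[list(g.samples)].reset_index())


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_genotypes(path: str, multiallelic: str = "error") -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of the ALT allele per sample; missing genotypes become
    NaN.  ``multiallelic`` is ``"error"`` or ``"skip"`` (skip logs a warning).
    """
    import cyvcf2

    if multiallelic not in ("error", "skip"):
        raise ValueError("multiallelic must be 'error' or 'skip'")
    try:
        vcf = cyvcf2.VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    samples = np.asarray(vcf.samples, dtype=object)
    rows, dosages = [], []
    n_skipped = 0
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if multiallelic == "skip":
                n_skipped += 1
                continue
            raise DataError(
                f"record {lineno} ({var.CHROM}:{var.POS}) is not a biallelic SNP"
            )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
        dosages.append(dos)
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d non-biallelic record(s)", n_skipped)
    if not rows:
        raise DataError(f"no biallelic SNP records in {path}")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    dosage = np.asarray(dosages, dtype=float).T
    order = markers.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(samples, markers.iloc[order], dosage[:, order])


def write_genotypes(g: GenotypeMatrix, path: str,
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 (GT field only)."""
    mk = g.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=idcgwas\n")
        for chrom in pd.unique(mk["chrom"]):
            length = (contig_lengths or {}).get(
                chrom, int(mk.loc[mk["chrom"] == chrom, "pos"].max())
            )
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.samples)) + "\n")
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(g.n_markers):
            row = mk.iloc[j]
            calls = [
                "./." if np.isnan(d) else gt_code[d] for d in g.dosage[:, j]
            ]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_phenotypes(path: str) -> PhenotypeTable:
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str, "population": str})
    return PhenotypeTable(t)


def write_phenotypes(p: PhenotypeTable, path: str) -> None:
    p.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Filtering / imputation / adjustment
# ---------------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, cutoff: float = 0.05) -> GenotypeMatrix:
    """Retain markers with MAF strictly greater than ``cutoff`` (non-missing calls).

    The strict inequality follows the post-filter marker count being described
    as "MAF > 0.05"; it removes monomorphic markers at any positive cutoff.
    """
    if not 0.0 <= cutoff <= 0.5:
        raise ValueError("MAF cutoff must be in [0, 0.5]")
    keep = np.flatnonzero(g.maf() > cutoff)
    if keep.size == 0:
        raise DataError(
            f"MAF filter at cutoff {cutoff} removed all {g.n_markers} markers; "
            "lower the cutoff"
        )
    return g.take_markers(keep)


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker's most frequent observed dosage.

    Ties between equally frequent dosages resolve to the *lower* dosage.  This
    is a declared simple stand-in for haplotype-cluster imputation; it never
    touches observed calls.
    """
    d = g.dosage.copy()
    miss = np.isnan(d)
    if not miss.any():
        return replace(g, dosage=d)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        ids = g.markers.loc[fully_missing, "id"].tolist()
        raise DataError(f"markers with no observed calls cannot be imputed: {ids[:10]}")
    for j in np.flatnonzero(miss.any(axis=0)):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        values, counts = np.unique(obs, return_counts=True)
        mode = values[counts == counts.max()].min()  # tie -> lower dosage
        col[np.isnan(col)] = mode
    return replace(g, dosage=d)


def adjust_phenotype(p: PhenotypeTable) -> PhenotypeTable:
    """Least-squares-mean adjustment: shift each population to the grand mean.

    adjusted_i = raw_i - mean(population of i) + grand mean.  Within-population
    deviations (and ranks) are preserved; the grand mean is unchanged.  With a
    single population, or any population of fewer than two samples, the raw
    scores pass through unchanged.
    """
    t = p.table.copy()
    if t["population"].isna().any():
        raise DataError("unknown (missing) population label in phenotype table")
    sizes = t.groupby("population")["idc_score"].size()
    if len(sizes) < 2 or (sizes < 2).any():
        t["adjusted"] = t["idc_score"].astype(float)
        return PhenotypeTable(t)
    grand = t["idc_score"].mean()
    pop_mean = t.groupby("population")["idc_score"].transform("mean")
    t["adjusted"] = t["idc_score"] - pop_mean + grand
    return PhenotypeTable(t)
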