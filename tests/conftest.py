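import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from idcgwas import genio, simdata
from idcgwas.genio import GenotypeMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_genotypes(dosage, chrom="Gm01", positions=None, ref="A", alt="G", samples=None):
    """Build a small GenotypeMatrix from a dosage array (helper for fixtures)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    refs = [ref] * m if isinstance(ref, str) else list(ref)
    alts = [alt] * m if isinstance(alt, str) else list(alt)
    markers = pd.DataFrame(
        {
            "id": [f"{c}_{p}" for c, p in zip(chroms, positions)],
            "chrom": chroms,
            "pos": list(positions),
            "ref": refs,
            "alt": alts,
        }
    )
    samples = samples if samples is not None else [f"S{i:03d}" for i in range(n)]
    return GenotypeMatrix(np.asarray(samples, dtype=object), markers, dosage)


@pytest.fixture(scope="session")
def breeding_panel():
    """A structured two-subpopulation panel with planted QTL, filtered and imputed."""
    cfg = simdata.SimConfig(seed=42, n_markers=1500, missing_rate=0.05)
    cfg = cfg.replace(qtl_spec=simdata.study_qtl_spec(cfg))
    g, pheno, truth = simdata.simulate_population(cfg)
    g = genio.filter_maf(genio.impute_mode(g), 0.05)
    pheno = genio.adjust_phenotype(pheno)
    return {"config": cfg, "genotypes": g, "phenotypes": pheno, "truth": truth}


@pytest.fixture(scope="session")
def annotation_fixture(tmp_path_factory):
    """Small genome + gene models + a marker panel with genome-consistent REF alleles."""
    cfg = simdata.SimConfig(
        seed=9, n_chromosomes=3, chrom_length_bp=80_000, n_markers=120, missing_rate=0.0
    )
    genomes, genes = simdata.simulate_annotation(cfg, 4)
    g, pheno, _ = simdata.simulate_population(cfg, reference=genomes)
    d = tmp_path_factory.mktemp("annot")
    fasta, gff = d / "ref.fa", d / "genes.gff3"
    simdata.write_fasta(genomes, fasta)
    simdata.write_gff3(genes, gff)
    return {
        "config": cfg,
        "genomes": genomes,
        "genes": genes,
        "genotypes": g,
        "fasta": fasta,
        "gff3": gff,
    }
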