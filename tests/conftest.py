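import dataclasses

import pytest
from hypothesis import settings

import regratio as rr

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory):
    """A small but complete synthetic fixture set (default study conditions)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    cfg = rr.SyntheticConfig(n_genes=400, seed=1729)
    return rr.simulate(cfg, outdir)


@pytest.fixture(scope="session")
def sim_genes(sim_paths):
    return rr.load_gene_annotation(
        sim_paths["gtf"],
        isoform_table=sim_paths["isoforms"],
        fpkm_table=sim_paths["fpkm"],
        protein_table=sim_paths["protein"],
    )


@pytest.fixture(scope="session")
def sim_peaks(sim_paths):
    atac = rr.filter_significant(
        rr.load_narrowpeak(sim_paths["atac"], source="atac"), method="use_q"
    )
    pop = rr.filter_significant(
        rr.load_bed(sim_paths["pop"], source="pop", pvalue_col=7), method="bh_on_p"
    )
    return atac, pop


@pytest.fixture(scope="session")
def sim_profiles(sim_genes, sim_peaks):
    atac, pop = sim_peaks
    return rr.build_profiles(sim_genes, atac, pop)


def make_gene(gene_id="G1", chrom="chr1", start=1000, end=2000, strand="+", **kw):
    return rr.GeneRecord(gene_id=gene_id, chrom=chrom, start=start, end=end,
                         strand=strand, **kw)


def make_peakset(intervals, source="atac", chrom="chr1"):
    """PeakSet from (start, end) pairs or (chrom, start, end) triples."""
    peaks = []
    for i, iv in enumerate(intervals):
        c, s, e = iv if len(iv) == 3 else (chrom, *iv)
        peaks.append(rr.PeakRecord(chrom=c, start=s, end=e, name=f"pk{i}", source=source))
    return rr.PeakSet(source=source, peaks=peaks)
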