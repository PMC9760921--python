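import pandas as pd
import pytest

from genecov.annotation import GeneCatalog, GeneRecord
from genecov.quant_io import QuantTable

GTF_FIXTURE = """\
##description: hand-built three-gene annotation fixture
chr18\tHAVANA\tgene\t1000\t9000\t.\t+\t.\tgene_id "ENSG00000001.5"; gene_type "protein_coding"; gene_name "ALPHA";
chr18\tHAVANA\ttranscript\t1000\t5000\t.\t+\t.\tgene_id "ENSG00000001.5"; transcript_id "ENST00000001.1";
chr18\tHAVANA\ttranscript\t1000\t9000\t.\t+\t.\tgene_id "ENSG00000001.5"; transcript_id "ENST00000002.1";
chr18\tHAVANA\tgene\t20000\t21200\t.\t-\t.\tgene_id "ENSG00000002.2"; gene_type "protein_coding"; gene_name "BETA";
chr18\tHAVANA\ttranscript\t20000\t21200\t.\t-\t.\tgene_id "ENSG00000002.2"; transcript_id "ENST00000003.1";
chr18\tHAVANA\tgene\t30000\t31000\t.\t+\t.\tgene_id "ENSG00000003.1"; gene_type "lincRNA"; gene_name "LNC1";
chr18_random\tHAVANA\tgene\t100\t500\t.\t+\t.\tgene_id "ENSG00000004.1"; gene_type "protein_coding"; gene_name "SCAF";
chrM\tHAVANA\tgene\t100\t500\t.\t+\t.\tgene_id "ENSG00000005.1"; gene_type "protein_coding"; gene_name "MITO";
"""


@pytest.fixture
def gtf_file(tmp_path):
    p = tmp_path / "fixture.gtf"
    p.write_text(GTF_FIXTURE)
    return p


def make_catalog(genes_by_chromosome):
    """Catalog from {chromosome: [gene_id, ...]}."""
    records = [
        GeneRecord(g, g, chrom, "protein_coding", 2000)
        for chrom, genes in genes_by_chromosome.items()
        for g in genes
    ]
    return GeneCatalog(records)


def make_quant(platform, abundances, ct=None, donor="sample"):
    """QuantTable from {gene_id: abundance} (+ optional {gene_id: ct})."""
    unit = {"illumina": "FPKM", "ont": "TPM", "qpcr": "copies_per_cell"}[platform]
    df = pd.DataFrame(
        {
            "gene_id": list(abundances),
            "abundance": list(abundances.values()),
        }
    )
    if ct is not None:
        df["ct"] = [ct[g] for g in abundances]
    return QuantTable(platform=platform, donor=donor, unit=unit, df=df)


@pytest.fixture
def chr18_catalog():
    return make_catalog({"18": [f"G{i}" for i in range(1, 11)]})
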