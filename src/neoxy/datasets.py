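"""Bundled reference tables.

The protein-coding Y-linked gene catalogue of *Basiliscus vittatus* — gene
name, pairwise X/Y dS, whether the Y copy amplifies in *Corytophanes
hernandesii* (the second corytophanid clade), the published stratum, and
orthologue placements — is shipped as a small TSV.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dating import GametologueRecord, classify_stratum


def load_y_gene_catalogue() -> pd.DataFrame:
    """The B. vittatus protein-coding Y gene table (dS may be NA)."""
    with resources.files("neoxy.data").joinpath("basiliscus_y_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    return df


def y_gene_records() -> list[GametologueRecord]:
    """Catalogue rows as GametologueRecords with strata assigned by the
    evidence rule (outgroup presence authoritative, dS threshold provisional)."""
    df = load_y_gene_catalogue()
    records = []
    for _, row in df.iterrows():
        rec = GametologueRecord(
            gene_id=row["gene"],
            ds=None if pd.isna(row["ds"]) else float(row["ds"]),
            outgroup_presence=row["y_in_corytophanes"] == "Yes",
        )
        records.append(classify_stratum(rec))
    return records
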