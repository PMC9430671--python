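"""Shared fixtures: small hand-buildable genes and cohort files on disk."""

from __future__ import annotations

import numpy as np
import pytest

from dualysin.sequence_io import GeneRecord, translate_cds, write_cohort


def gene_from_cds(cds: str, gene_id: str = "g1", genus: str = "Streptococcus",
                  family: str = "endolysin") -> GeneRecord:
    """A consistent GeneRecord whose protein is the translation of *cds*."""
    return GeneRecord(
        gene_id=gene_id,
        cds=cds,
        protein=translate_cds(cds),
        host_genus=genus,
        family=family,
    )


def plain_backbone(n_codons: int, filler: str = "GCT") -> str:
    """A CDS of *n_codons* filler codons (no starts, no SD motifs) + stop."""
    return "ATG" + filler * (n_codons - 1) + "TAA"


def plant_codon(cds: str, codon_index: int, codon: str = "ATG") -> str:
    """Overwrite the codon at a 1-based index."""
    i = 3 * (codon_index - 1)
    return cds[:i] + codon + cds[i + 3 :]


def plant_sd(cds: str, codon_index: int, spacing: int = 7,
             motif: str = "AGGAGG") -> str:
    """Write an SD motif *spacing* nt upstream of the start at *codon_index*."""
    s0 = 3 * (codon_index - 1)
    ms = s0 - spacing - len(motif)
    assert ms >= 0
    return cds[:ms] + motif + cds[ms + len(motif) :]


@pytest.fixture
def toy_cohort_dir(tmp_path):
    """Three consistent records written out in the on-disk cohort layout."""
    genes = [
        gene_from_cds(plain_backbone(30), "g1", "Streptococcus"),
        gene_from_cds(
            plant_codon(plain_backbone(40), 15), "g2", "Lactococcus"
        ),
        gene_from_cds(plain_backbone(25, "AAA"), "g3", "Enterococcus"),
    ]
    write_cohort(genes, tmp_path)
    return tmp_path, genes


@pytest.fixture
def rng():
    return np.random.default_rng(20177)
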