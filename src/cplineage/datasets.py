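"""Packaged reference tables for the water-chestnut cpINDEL marker system.

Three small text tables ship with the package:

* the 19-locus chloroplast INDEL marker panel for *Trapa* (primers, core
  variation alignments, motif annotation and amplicon coordinates on the
  *T. maximowiczii* KY705084 frame). The core alignment of cpINDEL1 is not
  available in machine-readable form and is replaced by a constructed,
  representative single-nucleotide-repeat core; it is flagged
  ``core_source == "synthetic"`` and excluded from fixture-vs-annotation
  comparisons at the caller's discretion.
* the published nine-locus genotype matrix of 79 accessions (four *Trapa*
  species collected in China and Japan), one row per plastid-type lineage
  and collection region with per-species accession counts.
* the flow-cytometry peak table (sample peak, internal rice peak) used for
  genome-size estimation, with the rice internal standard 1C size of
  373,245,519 bp.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: 1C genome size of the Oryza sativa cv. Nipponbare internal standard (bp)
RICE_1C_BP = 373_245_519

#: the nine polymorphic loci scored in the published genotype matrix
GENOTYPED_LOCI = ("cpINDEL2", "cpINDEL3", "cpINDEL7", "cpINDEL9", "cpINDEL10",
                  "cpINDEL12", "cpINDEL13", "cpINDEL17", "cpINDEL19")

SPECIES = ("T. incisa", "T. japonica", "T. natans", "T. bispinosa")


def _path(name: str):
    return resources.files("cplineage.data").joinpath(name)


def load_marker_panel() -> pd.DataFrame:
    """The 19-row cpINDEL marker panel (locus, primers, core alignment,
    motif annotation, amplicon start/end/length)."""
    with resources.as_file(_path("cpindel_markers.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def load_genotype_table() -> pd.DataFrame:
    """The published plastid-type table: one row per (lineage label,
    region) with the nine-locus code vector and per-species counts."""
    with resources.as_file(_path("plastid_genotypes.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def load_flow_peaks() -> pd.DataFrame:
    """Flow-cytometry peak pairs for eight accessions with the rice
    internal standard."""
    with resources.as_file(_path("flow_peaks.csv")) as p:
        df = pd.read_csv(p)
    return df
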