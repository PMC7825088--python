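"""Bundled study metadata: the 24 published high-quality cyanobacterial
draft genomes (scaffold counts, fragmented/complete BGC counts, genus, NCBI
accession). All 24 have at least 98% CheckM completeness; 0.98 is recorded
here as a conservative lower bound. The seven genomes flagged ``rare`` were
singletons in the published whole-genome Mash comparison against the NCBI
cyanobacterial database.
"""

from __future__ import annotations

from .binning import GenomeRecord

# (genome_id, n_scaffolds, bgc_fragmented, bgc_complete, genus, accession, rare)
_STUDY_GENOMES = (
    ("SIOISBB",   3,   0, 11, "Leptolyngbya",  "JAAHII01", True),
    ("SIOASIH",   25,  5, 41, "Moorena",       "JAAHIH01", False),
    ("SIO1I7",    110, 5, 12, "Okeania",       "JAAHGF01", False),
    ("SIO3A2",    132, 23, 8, "Moorena",       "JAAHHC01", False),
    ("SIO3A5",    164, 17, 11, "Moorena",      "JAAHHD01", False),
    ("SIO1A7",    183, 6, 8,  "Oscillatoria",  "JAAHFN01", True),
    ("SIO2C2",    184, 8, 6,  "Okeania",       "JAAHGM01", False),
    ("SIO1H4",    192, 11, 3, "Okeania",       "JAAHGB01", False),
    ("SIO1F9",    198, 5, 6,  "Okeania",       "JAAHFW01", False),
    ("SIO1G6",    205, 20, 12, "Moorena",      "JAAHFZ01", False),
    ("SIO1C2",    246, 16, 11, "Symploca",     "JAAHFP01", False),
    ("SIO2B3",    250, 14, 2, "Okeania",       "JAAHGH01", False),
    ("SIO1H5",    263, 13, 3, "Okeania",       "JAAHGC01", False),
    ("SIO1H2",    279, 11, 2, "Okeania",       "JAAHGA01", False),
    ("SIO3C6",    290, 6, 11, "Symploca",      "JAAHHJ01", False),
    ("SIO2C9",    318, 14, 8, "Okeania",       "JAAHGO01", True),
    ("SIO2F5",    334, 18, 1, "Okeania",       "JAAHGU01", False),
    ("SIO2G4",    339, 16, 3, "Okeania",       "JAAHGW01", False),
    ("SIO2E9",    384, 16, 5, "Symploca",      "JAAHGS01", True),
    ("SIO3E8",    387, 23, 7, "Moorena",       "JAAHHM01", False),
    ("SIO3F7",    399, 22, 7, "Moorena",       "JAAHHP01", False),
    ("SIO3F2",    454, 10, 0, "Spirulina",     "JAAHHN01", True),
    ("SIO2C1",    471, 25, 4, "Symploca",      "JAAHGL01", True),
    ("SIO1E4_02", 12,  3, 17, "Leptolyngbya",  "JAAHFU01", True),
)


def study_genomes() -> list[GenomeRecord]:
    """The 24 published genome records as :class:`GenomeRecord` objects."""
    return [
        GenomeRecord(id=gid, taxon_label=genus, n_scaffolds=n_scaf,
                     completeness=0.98, bgc_fragmented=frag,
                     bgc_complete=comp)
        for gid, n_scaf, frag, comp, genus, _acc, _rare in _STUDY_GENOMES
    ]


def study_accessions() -> dict[str, str]:
    """Genome id -> NCBI accession for the 24 published genomes."""
    return {row[0]: row[5] for row in _STUDY_GENOMES}


def study_rare_genomes() -> list[str]:
    """Genome ids flagged as Mash singletons in the published comparison."""
    return [gid for gid, *_mid, rare in _STUDY_GENOMES if rare]
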