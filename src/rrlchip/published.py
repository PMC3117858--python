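"""Published composition and performance of the chicken 60K SNP array.

The printed tables of the original 60K chicken BeadChip design are used as
fixed inputs for bookkeeping reproductions: the origin composition of the
panel (a spaced chromosome selection of 59,581 SNPs plus add-ons on
unplaced contigs, chr_random bins and the mitochondrion, 60,800 in all)
and the four-class performance counts per SNP origin group.

The origin table's strata overlap: 41,895 SNPs came from the public SNP
database (17,545 previously validated in an earlier genotyping assay and
24,350 not) and 26,551 from the RRL sequencing discovery, 7,793 of which
were also present in the database.  ``published_panel_manifest`` realises
one allocation consistent with every printed marginal total (the 7,793
shared SNPs are placed in the not-previously-validated database stratum;
the 147 SNPs in neither printed stratum are labelled 'other').
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .panel_design import CandidateSnp, PanelManifest, assemble_manifest

__all__ = [
    "PERFORMANCE_COUNTS",
    "PANEL_CATEGORY_COUNTS",
    "published_panel_manifest",
]

#: Per-group performance counts (failed design, excluded, monomorphic,
#: polymorphic) of the 60,800 array SNPs, by origin of discovery.
PERFORMANCE_COUNTS: Dict[str, Tuple[int, int, int, int]] = {
    "all": (3164, 1116, 2227, 54293),
    "dbsnp_confirmed": (893, 64, 27, 16629),
    "dbsnp_random": (886, 764, 1581, 14087),
    "illumina_sequencing": (1431, 285, 618, 24356),
}

#: Panel provenance categories and their published sizes.
PANEL_CATEGORY_COUNTS: Dict[str, int] = {
    "chromosome_selected": 59_581,
    "unplaced_contig": 790,
    "chr_random": 421,
    "mito": 8,
}

#: Origin strata sizes consistent with the published origin table
#: (stratum -> (source label, validated flag, count)).
_ORIGIN_STRATA = [
    ("db_validated", "known_db", True, 17_545),
    ("db_unvalidated", "known_db", False, 24_350 - 7_793),
    ("rrl_and_db", "rrl_and_db", False, 7_793),
    ("rrl_novel", "rrl_novel", False, 18_758),
    ("legacy_other", "other", False, 147),
]

#: Add-on category sizes taken from specific strata (contig SNPs are RRL
#: discoveries on novel sequence; chr_random and mito SNPs are database
#: content).
_ADDON_SOURCES = {
    "unplaced_contig": ("rrl_novel", 790),
    "chr_random": ("db_unvalidated", 421),
    "mito": ("db_unvalidated", 8),
}


def published_panel_manifest() -> PanelManifest:
    """Assemble a manifest with the published category and origin totals.

    Entries are synthetic placeholders (ids, positions) carrying the real
    counts; only the bookkeeping — category totals, origin marginals and
    the grand total — is meaningful.
    """
    remaining = {name: n for name, _, _, n in _ORIGIN_STRATA}
    meta = {name: (src, val) for name, src, val, _ in _ORIGIN_STRATA}

    def mk(stratum: str, category: str, n: int) -> List[CandidateSnp]:
        src, validated = meta[stratum]
        remaining[stratum] -= n
        return [
            CandidateSnp(
                f"{category}_{stratum}_{i}",
                f"{category}_chrom",
                i,
                ("A", "G"),
                1.0,
                validated=validated,
                source=src,
            )
            for i in range(n)
        ]

    addons = {
        cat: mk(stratum, cat, n) for cat, (stratum, n) in _ADDON_SOURCES.items()
    }
    chromosome_selected: List[CandidateSnp] = []
    for name, _, _, _ in _ORIGIN_STRATA:
        chromosome_selected.extend(mk(name, "sel", remaining[name]))
    manifest = assemble_manifest(chromosome_selected, addons)
    assert manifest.total == sum(PANEL_CATEGORY_COUNTS.values())
    return manifest
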